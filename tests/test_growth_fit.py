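import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from freepol import growth_fit, synthetic_data as synth
from freepol.growth_fit import (
    MILLER_COEFFICIENT,
    OnpgKinetics,
    find_exponential_window,
    fit_exponential_phase,
    fit_onpg_kinetics,
    miller_units,
    onpg_model,
)
from freepol.plate_io import Condition, PlateWell


def _exp_well(mu_dbl_h=1.0, conc=500.0, offset=0.0, od0=0.005, n=120, dt=7.0):
    t = np.arange(n) * dt
    od = od0 * 2 ** (mu_dbl_h * t / 60.0)
    return PlateWell("A1", Condition(), t, od, {"GFP": conc * od + offset})


class TestWindowSelection:
    def test_fixed_window_is_the_thresholded_range(self):
        """Fixed mode returns exactly the samples with OD in [lo, hi]."""
        well = _exp_well(od0=0.005, n=130)
        win = find_exponential_window(well, od_lo=0.02, od_hi=0.2, mode="fixed")
        od = well.od610
        inside = np.flatnonzero((od >= 0.02) & (od <= 0.2))
        assert win.start == inside[0]
        assert win.stop == inside[-1] + 1

    def test_flat_curve_has_no_window(self):
        t = np.arange(20) * 7.0
        well = PlateWell("A1", Condition(), t, np.full(20, 0.01), {"GFP": np.zeros(20)})
        with pytest.raises(ValueError, match="window too short"):
            find_exponential_window(well, od_lo=0.02, od_hi=0.2, mode="fixed")

    def test_auto_window_tracks_the_near_exponential_region(self):
        """On a noiseless logistic curve the max-R^2 window stays where the
        local doubling rate is close to mu, so the fitted slope is within
        5% of the simulated growth rate."""
        truth = synth.noiseless(synth.SimulationTruth(seed=0))
        wells, rec = synth.simulate_plate_reader(
            truth, constructs=["P5"], media=["M9-glu"], cm_grid=[0.0], include_blanks=False
        )
        well = wells[0]
        win = find_exponential_window(well, mode="auto", r2_floor=0.9999)
        est = fit_exponential_phase(well, win, "GFP")
        mu_true = rec["conditions"][0]["mu"]
        assert abs(est.mu / mu_true - 1.0) < 0.05
        # the window's upper OD stays well below the carrying capacity
        assert well.od610[win.slice].max() < 0.2 * truth.carrying_capacity


class TestExponentialFit:
    def test_exact_slopes_on_pure_exponential(self):
        """OD doubling every 60 min with GFP = 500*OD gives mu = 1 dbl/h,
        conc = 500 RFU/OD and gpr = 500 RFU/OD/h."""
        well = _exp_well(mu_dbl_h=1.0, conc=500.0)
        win = find_exponential_window(well, 0.02, 0.2)
        est = fit_exponential_phase(well, win, "GFP")
        assert est.mu == pytest.approx(1.0, rel=1e-10)
        assert est.reporter_conc == pytest.approx(500.0, rel=1e-10)
        assert est.gpr == pytest.approx(500.0, rel=1e-10)

    def test_constant_channel_offset_does_not_move_the_concentration(self):
        base = _exp_well(conc=500.0, offset=0.0)
        shifted = _exp_well(conc=500.0, offset=20.0)
        win = find_exponential_window(base, 0.02, 0.2)
        a = fit_exponential_phase(base, win, "GFP")
        b = fit_exponential_phase(shifted, win, "GFP")
        assert b.reporter_conc == pytest.approx(a.reporter_conc, rel=1e-12)

    @given(scale=st.floats(1e-3, 1e3))
    def test_mu_invariant_under_od_rescaling(self, scale):
        """Multiplying OD by any positive constant leaves the log-slope."""
        well = _exp_well()
        win = find_exponential_window(well, 0.02, 0.2)
        mu_ref = fit_exponential_phase(well, win, "GFP").mu
        scaled = PlateWell(
            "A1", Condition(), well.time, scale * well.od610,
            {"GFP": well.channels["GFP"]},
        )
        mu_scaled = fit_exponential_phase(scaled, win, "GFP").mu
        assert mu_scaled == pytest.approx(mu_ref, rel=1e-9)

    def test_gpr_identity_holds_exactly(self):
        well = _exp_well(mu_dbl_h=0.8, conc=300.0)
        win = find_exponential_window(well, 0.02, 0.2)
        est = fit_exponential_phase(well, win, "GFP")
        assert est.gpr == est.reporter_conc * est.mu

    def test_nonpositive_od_in_window_raises(self):
        t = np.arange(10) * 7.0
        od = np.linspace(0.0, 0.2, 10)
        well = PlateWell("A1", Condition(), t, od, {"GFP": od})
        win = growth_fit.ExpWindow(start=0, stop=10, od_lo=0.001, od_hi=0.3)
        with pytest.raises(ValueError, match="non-positive OD"):
            fit_exponential_phase(well, win, "GFP")

    def test_parameter_recovery_under_noise(self):
        """mu = 0.8, conc = 300 with 2% multiplicative noise: medians over
        200 seeded replicates land within 2% / 3% of truth."""
        mus, concs = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            well = _exp_well(mu_dbl_h=0.8, conc=300.0)
            sigma = np.sqrt(np.log1p(0.02**2))
            noisy = PlateWell(
                "A1",
                Condition(),
                well.time,
                well.od610 * rng.lognormal(0, sigma, well.n_samples),
                {"GFP": well.channels["GFP"] * rng.lognormal(0, sigma, well.n_samples)},
            )
            win = find_exponential_window(noisy, 0.02, 0.2)
            est = fit_exponential_phase(noisy, win, "GFP")
            mus.append(est.mu)
            concs.append(est.reporter_conc)
        assert abs(np.median(mus) / 0.8 - 1.0) < 0.02
        assert abs(np.median(concs) / 300.0 - 1.0) < 0.03


class TestOnpgKinetics:
    def test_linear_limit_recovers_slope_and_zero_gamma(self):
        t = np.arange(0.0, 60.0, 2.0)
        kin = fit_onpg_kinetics(t, 0.002 * t)
        assert kin.amp == pytest.approx(0.002, rel=1e-6)
        assert kin.gamma < 1e-6

    def test_noiseless_self_consistency(self):
        t = np.arange(0.0, 120.0, 3.0)
        y = onpg_model(t, 0.003, 0.01)
        kin = fit_onpg_kinetics(t, y)
        assert kin.amp == pytest.approx(0.003, rel=1e-4)
        assert kin.gamma == pytest.approx(0.01, rel=1e-4)

    def test_recovery_under_additive_noise(self):
        """1% additive noise, 100 seeds: median amplitude within 5%."""
        t = np.arange(0.0, 120.0, 3.0)
        clean = onpg_model(t, 0.003, 0.01)
        amps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            kin = fit_onpg_kinetics(t, clean + rng.normal(0, 0.01 * clean.max(), t.size))
            amps.append(kin.amp)
        assert abs(np.median(amps) / 0.003 - 1.0) < 0.05

    def test_small_gamma_curve_matches_linear_formula(self):
        t = np.linspace(0.0, 100.0, 50)[1:]
        np.testing.assert_allclose(onpg_model(t, 1.0, 1e-8), t, rtol=1e-4)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_onpg_kinetics([0, 1, 2, 3], [0, 1, 2, 3])


class TestMillerUnits:
    def test_coefficient_expands_to_two_million(self):
        assert MILLER_COEFFICIENT == 2e6

    def test_zero_amplitude_gives_zero_activity(self):
        assert miller_units(OnpgKinetics(amp=0.0, gamma=0.0, od610_ref=0.4)) == 0.0

    def test_worked_arithmetic(self):
        kin = OnpgKinetics(amp=5e-4, gamma=0.0, od610_ref=0.2)
        assert miller_units(kin) == pytest.approx(5000.0)

    def test_nonpositive_od_raises(self):
        with pytest.raises(ValueError, match="od610_ref"):
            miller_units(OnpgKinetics(amp=1e-3, gamma=0.0, od610_ref=0.0))
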