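import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from freepol import synthetic_data as synth
from freepol.rnap_ppgpp import (
    HillParams,
    PpgppLaw,
    RatioConstants,
    RnapLaw,
    decompose_rates,
    fit_ratio_constants,
    gpr_ratio_model,
    growth_law_eval,
    growth_law_fit,
    hill_inhibition,
    invert_ratio_to_cf,
    ppgpp_inhibition_effect,
    promoter_activity,
)

RC = RatioConstants(a=10.5, k5=90.0, k_ltet=2000.0, k1=90.0)


class TestPromoterActivity:
    def test_half_saturation(self):
        assert promoter_activity(90.0, 90.0) == pytest.approx(0.5)

    def test_zero_rnap_means_zero_activity(self):
        assert promoter_activity(0.0, 90.0) == 0.0

    def test_worked_value(self):
        assert promoter_activity(450.0, 90.0) == pytest.approx(450.0 / 540.0)

    def test_bounded_by_scaling_factor(self):
        cf = np.logspace(-2, 6, 50)
        tr = promoter_activity(cf, 90.0, a=10.5)
        assert np.all(tr >= 0) and np.all(tr < 10.5)


class TestRatioModel:
    def test_saturation_limit_is_a(self):
        assert gpr_ratio_model(1e12, RC) == pytest.approx(RC.a, rel=1e-8)

    def test_zero_rnap_limit(self):
        assert gpr_ratio_model(0.0, RC) == pytest.approx(10.5 * 90.0 / 2000.0)

    def test_worked_value_at_cf_450(self):
        assert gpr_ratio_model(450.0, RC) == pytest.approx(10.5 * 540.0 / 2450.0)

    def test_strictly_increasing_in_cf(self):
        cf = np.logspace(-3, 5, 200)
        r = gpr_ratio_model(cf, RC)
        assert np.all(np.diff(r) > 0)

    def test_closed_form_inversion_roundtrip(self):
        cf = invert_ratio_to_cf(10.5 * 540.0 / 2450.0, RC)
        assert cf == pytest.approx(450.0, rel=1e-12)

    @given(log_cf=st.floats(-3, 6))
    def test_inversion_is_the_exact_inverse(self, log_cf):
        cf = 10.0**log_cf
        assert invert_ratio_to_cf(gpr_ratio_model(cf, RC), RC) == pytest.approx(
            cf, rel=1e-10
        )

    @pytest.mark.parametrize("bad", [10.5, 10.5 * 90 / 2000, 0.1, 11.0])
    def test_out_of_range_ratio_raises(self, bad):
        with pytest.raises(ValueError, match="ratio outside model range"):
            invert_ratio_to_cf(bad, RC)


class TestGrowthLaws:
    def test_rnap_law_approaches_one_at_vanishing_growth(self):
        assert growth_law_eval("rnap", 1e-6, RnapLaw()) == pytest.approx(1.0, abs=1e-6)

    def test_rnap_law_printed_constants(self):
        """A = 6.82, mu_r = 0.11 at mu = 1 gives c_f ~ 450 molecules/um^3."""
        cf = growth_law_eval("rnap", 1.0, RnapLaw(a_log=6.82, mu_r=0.11))
        assert cf == pytest.approx(math.exp(6.82 * math.exp(-0.11)), rel=1e-12)
        assert cf == pytest.approx(450.2, abs=0.1)

    def test_ppgpp_law_intercept(self):
        assert growth_law_eval("ppgpp", 0.0, PpgppLaw(cp0=55.0, mu_p=1.2)) == 55.0

    def test_monotonicity(self):
        mu = np.linspace(0.2, 3.0, 100)
        cf = growth_law_eval("rnap", mu, RnapLaw())
        cp = growth_law_eval("ppgpp", mu, PpgppLaw(cp0=55.0, mu_p=1.2))
        assert np.all(np.diff(cf) > 0)
        assert np.all(np.diff(cp) < 0)

    def test_rnap_law_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            growth_law_eval("rnap", 0.0, RnapLaw())


class TestGrowthLawFit:
    MU = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])

    def test_noiseless_rnap_recovery(self):
        law = RnapLaw(a_log=6.82, mu_r=0.11)
        fit = growth_law_fit("rnap", self.MU, growth_law_eval("rnap", self.MU, law))
        assert fit.law.a_log == pytest.approx(6.82, rel=1e-4)
        assert fit.law.mu_r == pytest.approx(0.11, rel=1e-4)
        assert fit.residual_sd < 1e-8

    def test_noiseless_ppgpp_recovery(self):
        law = PpgppLaw(cp0=55.0, mu_p=1.2)
        fit = growth_law_fit("ppgpp", self.MU, growth_law_eval("ppgpp", self.MU, law))
        assert fit.law.cp0 == pytest.approx(55.0, rel=1e-10)
        assert fit.law.mu_p == pytest.approx(1.2, rel=1e-10)

    def test_two_points_violate_precondition(self):
        with pytest.raises(ValueError, match=">= 3"):
            growth_law_fit("rnap", [1.0, 2.0], [100.0, 400.0])


class TestRatioConstantFit:
    def test_noiseless_self_consistency(self):
        truth = synth.noiseless(synth.SimulationTruth())
        data = synth.simulate_ratio_dataset(truth, mu_grid=(0.4, 0.8, 1.2, 1.8, 2.5))
        fit = fit_ratio_constants(data[:, 0], data[:, 1], truth.rnap_law, k_ltet=2000.0)
        assert fit.constants.a == pytest.approx(10.5, rel=1e-3)
        assert fit.constants.k5 == pytest.approx(90.0, rel=1e-3)

    def test_delta_e_linkage_recovers_both_constants(self):
        """With K_Ltet tied to K5 through a binding-energy gap the fit
        still identifies (a, K5) and reports the implied K_Ltet."""
        truth = synth.noiseless(synth.SimulationTruth())
        data = synth.simulate_ratio_dataset(truth, mu_grid=(0.4, 0.8, 1.2, 1.8, 2.5))
        de = math.log(2000.0 / 90.0)
        fit = fit_ratio_constants(data[:, 0], data[:, 1], truth.rnap_law, delta_e=de)
        assert fit.constants.k5 == pytest.approx(90.0, rel=1e-3)
        assert fit.constants.k_ltet == pytest.approx(2000.0, rel=1e-3)

    def test_single_pair_violates_precondition(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_ratio_constants([1.0], [2.0], RnapLaw(), k_ltet=2000.0)


class TestHill:
    H = HillParams(b=2.0, k_p=40.0, n=2.0)

    def test_no_ppgpp_gives_maximal_effect(self):
        assert hill_inhibition(0.0, self.H, mode="eval") == pytest.approx(2.0)

    def test_half_inhibition_point(self):
        assert hill_inhibition(40.0, self.H, mode="eval") == pytest.approx(1.0)

    @pytest.mark.parametrize("factor", [0.1, 1.0, 10.0])
    def test_invert_undoes_eval(self, factor):
        cp = factor * self.H.k_p
        eff = hill_inhibition(cp, self.H, mode="eval")
        assert hill_inhibition(eff, self.H, mode="invert") == pytest.approx(cp, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, 2.0, 5.0])
    def test_invert_rejects_effects_outside_open_range(self, bad):
        with pytest.raises(ValueError):
            hill_inhibition(bad, self.H, mode="invert")

    def test_fit_recovers_noiseless_parameters(self):
        cp = np.array([5.0, 20.0, 40.0, 80.0, 160.0, 320.0])
        eff = hill_inhibition(cp, self.H, mode="eval")
        fitted = hill_inhibition((cp, eff), mode="fit")
        assert fitted.b == pytest.approx(2.0, rel=1e-6)
        assert fitted.k_p == pytest.approx(40.0, rel=1e-6)
        assert fitted.n == pytest.approx(2.0, rel=1e-6)

    def test_fit_needs_four_pairs(self):
        with pytest.raises(ValueError, match=">= 4"):
            hill_inhibition((np.arange(3.0), np.ones(3)), mode="fit")


class TestPpgppEffect:
    def test_equal_affinities_reduce_to_the_gpr_ratio(self):
        assert ppgpp_inhibition_effect(3.0, 4.0, 450.0, 90.0, 90.0) == pytest.approx(0.75)

    def test_forward_model_roundtrip(self):
        """Gpr(P1) built as 0.6 x P1 activity with shared translation
        yields an estimated effect of exactly 0.6."""
        cf, k1, k5 = 450.0, 150.0, 90.0
        gpr_p1 = 0.6 * promoter_activity(cf, k1) * 7.0
        gpr_p5 = promoter_activity(cf, k5) * 7.0
        assert ppgpp_inhibition_effect(gpr_p1, gpr_p5, cf, k1, k5) == pytest.approx(0.6)

    def test_no_inhibition_baseline(self):
        assert ppgpp_inhibition_effect(5.0, 5.0, 450.0, 90.0, 90.0) == pytest.approx(1.0)


class TestDecomposition:
    def test_forward_consistency_gives_zero_residuals(self):
        cf, t = 450.0, 7.0
        gprs = {
            "P5": promoter_activity(cf, RC.k5) * t,
            "PLtet": promoter_activity(cf, RC.k_ltet, RC.a) * t,
            "P1": promoter_activity(cf, RC.k1) * t,
        }
        dec = decompose_rates(gprs, cf, RC)
        assert dec.translation_rate == pytest.approx(7.0)
        for name in gprs:
            assert dec.residuals[name] == pytest.approx(0.0, abs=1e-12)

    def test_perturbation_propagates_only_to_the_perturbed_promoter(self):
        cf, t = 450.0, 7.0
        gprs = {
            "P5": promoter_activity(cf, RC.k5) * t,
            "PLtet": promoter_activity(cf, RC.k_ltet, RC.a) * t * 1.1,
        }
        dec = decompose_rates(gprs, cf, RC)
        assert dec.residuals["PLtet"] == pytest.approx(0.1, rel=1e-10)
        assert dec.residuals["P5"] == pytest.approx(0.0, abs=1e-12)

    def test_translation_rate_scales_by_the_analytic_activity_factor(self):
        cf, t = 450.0, 7.0
        gprs = {"P5": promoter_activity(cf, RC.k5) * t}
        dec1 = decompose_rates(gprs, cf, RC)
        dec2 = decompose_rates(gprs, 2 * cf, RC)
        factor = promoter_activity(cf, RC.k5) / promoter_activity(2 * cf, RC.k5)
        assert dec2.translation_rate / dec1.translation_rate == pytest.approx(
            factor, rel=1e-12
        )

    def test_missing_anchor_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            decompose_rates({"PLtet": 1.0}, 450.0, RC)
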