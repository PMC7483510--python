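"""Exponential-phase growth and reporter-expression fitting.

The growth rate mu (doublings/hour) is the least-squares slope of
log2(OD610) versus time inside an exponential window defined by OD
thresholds. The reporter concentration (RFU per OD unit) is the slope of
background-subtracted fluorescence versus OD over the same window, and
the production rate Gpr is their product — the per-OD synthesis flux of
the reporter.

beta-galactosidase activity is quantified from ONPG hydrolysis kinetics:
OD450(t) = A (1 - exp(-gamma t)) / gamma, where the decay factor gamma
accounts for the volatility of the reaction product o-nitrophenol, and
converted to Miller units normalized by culture OD610.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from freepol.plate_io import PlateWell

__all__ = [
    "ExpWindow",
    "GrowthEstimate",
    "OnpgKinetics",
    "MILLER_COEFFICIENT",
    "find_exponential_window",
    "fit_exponential_phase",
    "fit_onpg_kinetics",
    "onpg_model",
    "miller_units",
]

#: Default OD thresholds bounding the exponential phase.
DEFAULT_OD_LO = 0.02
DEFAULT_OD_HI = 0.2

#: Miller-unit conversion: 1,000 x (1 / 0.01 ml) x 20 (assay dilution),
#: applied to the ONPG amplitude per unit culture OD610.
MILLER_COEFFICIENT = 1_000.0 * (1.0 / 0.01) * 20.0


@dataclass(frozen=True)
class ExpWindow:
    """Contiguous index range [start, stop) marking the exponential phase."""

    start: int
    stop: int
    od_lo: float
    od_hi: float

    def __post_init__(self) -> None:
        if self.stop - self.start < 4:
            raise ValueError("window too short: fewer than 4 samples")
        if not (0 < self.od_lo < self.od_hi):
            raise ValueError(f"need 0 < od_lo < od_hi, got ({self.od_lo}, {self.od_hi})")

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class GrowthEstimate:
    """Exponential-window fit for one well and channel.

    mu is in doublings/hour, reporter_conc in RFU per OD unit. The
    production rate gpr = reporter_conc * mu (RFU/OD/h) is a derived
    property, so the identity holds exactly by construction.
    """

    mu: float
    reporter_conc: float
    window: ExpWindow
    r_squared: float
    residual_sd: float

    @property
    def gpr(self) -> float:
        return self.reporter_conc * self.mu


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, stop) of the longest contiguous run of True; (0, 0) if none."""
    best = (0, 0)
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and mask.size - start > best[1] - best[0]:
        best = (start, mask.size)
    return best


def find_exponential_window(
    well: PlateWell,
    od_lo: float = DEFAULT_OD_LO,
    od_hi: float = DEFAULT_OD_HI,
    mode: str = "fixed",
    min_samples: int = 4,
    r2_floor: float = 0.999,
    min_od: float = 0.005,
) -> ExpWindow:
    """Locate the exponential-phase window of a growth curve.

    In ``fixed`` mode the window is the longest contiguous run of samples
    with OD in [od_lo, od_hi] — the thresholded definition used when
    windows are set manually. In ``auto`` mode an exhaustive sliding
    window search returns the longest contiguous window (OD > min_od)
    whose log2(OD)-vs-time regression has a positive slope and
    R^2 >= r2_floor, a stand-in for automated linear-range detection.

    Raises
    ------
    ValueError
        "window too short" when fewer than ``min_samples`` samples
        qualify.
    """
    od = well.od610
    if mode == "fixed":
        mask = (od >= od_lo) & (od <= od_hi)
        start, stop = _longest_true_run(mask)
        if stop - start < min_samples:
            raise ValueError(
                f"window too short: {stop - start} samples with OD in [{od_lo}, {od_hi}]"
            )
        return ExpWindow(start=start, stop=stop, od_lo=od_lo, od_hi=od_hi)

    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    valid = od > min_od
    t = well.time
    n = od.size
    # prefix sums over valid region for O(1) regression statistics per window
    y = np.where(valid, np.log2(np.where(valid, od, 1.0)), 0.0)
    best: tuple[int, int, float] | None = None  # (start, stop, r2)
    vstart, vstop = _longest_true_run(valid)
    tt = t[vstart:vstop]
    yy = y[vstart:vstop]
    m = tt.size
    if m < min_samples:
        raise ValueError("window too short: curve never rises above min_od")
    c_t = np.concatenate(([0.0], np.cumsum(tt)))
    c_y = np.concatenate(([0.0], np.cumsum(yy)))
    c_tt = np.concatenate(([0.0], np.cumsum(tt * tt)))
    c_yy = np.concatenate(([0.0], np.cumsum(yy * yy)))
    c_ty = np.concatenate(([0.0], np.cumsum(tt * yy)))
    for i in range(m - min_samples + 1):
        for j in range(i + min_samples, m + 1):
            k = j - i
            st = c_t[j] - c_t[i]
            sy = c_y[j] - c_y[i]
            stt = c_tt[j] - c_tt[i]
            syy = c_yy[j] - c_yy[i]
            sty = c_ty[j] - c_ty[i]
            var_t = stt - st * st / k
            var_y = syy - sy * sy / k
            cov = sty - st * sy / k
            if var_t <= 0 or var_y <= 0 or cov <= 0:
                continue
            r2 = cov * cov / (var_t * var_y)
            if r2 < r2_floor:
                continue
            cand = (i + vstart, j + vstart, r2)
            if best is None or (cand[1] - cand[0], cand[2]) > (best[1] - best[0], best[2]):
                best = cand
    if best is None:
        raise ValueError(
            f"window too short: no window of >= {min_samples} samples reaches R^2 {r2_floor}"
        )
    start, stop, _ = best
    return ExpWindow(
        start=start, stop=stop, od_lo=float(od[start:stop].min()), od_hi=float(od[start:stop].max())
    )


def fit_exponential_phase(well: PlateWell, window: ExpWindow, channel: str) -> GrowthEstimate:
    """Fit mu and reporter concentration inside an exponential window.

    mu is the OLS slope of log2(OD) vs time converted to doublings/hour;
    reporter_conc is the OLS slope of the (background-subtracted)
    channel vs OD, which makes it invariant to any constant channel
    offset. Non-positive OD inside the window or a constant OD (singular
    regression) raise ``ValueError``.
    """
    sl = window.slice
    t = well.time[sl]
    od = well.od610[sl]
    signal = well.channel(channel)[sl]
    if np.any(od <= 0):
        raise ValueError(f"well {well.well_id}: non-positive OD inside the window")
    if np.ptp(od) == 0:
        raise ValueError(f"well {well.well_id}: constant OD, growth slope is singular")
    y = np.log2(od)
    slope_per_min, intercept = np.polyfit(t, y, 1)
    mu = slope_per_min * 60.0  # doublings/hour
    resid = y - (slope_per_min * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r_squared = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    conc_slope, conc_icpt = np.polyfit(od, signal, 1)
    conc_resid = signal - (conc_slope * od + conc_icpt)
    residual_sd = float(np.std(conc_resid, ddof=2)) if od.size > 2 else 0.0
    return GrowthEstimate(
        mu=float(mu),
        reporter_conc=float(conc_slope),
        window=window,
        r_squared=r_squared,
        residual_sd=residual_sd,
    )


# ---------------------------------------------------------------------------
# ONPG / Miller units


@dataclass(frozen=True)
class OnpgKinetics:
    """ONPG hydrolysis fit: amplitude A (OD450/min) and decay gamma (1/min)."""

    amp: float
    gamma: float
    od610_ref: float | None = None
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amp < 0 or self.gamma < 0:
            raise ValueError("amp and gamma must be non-negative")


def onpg_model(t: np.ndarray, amp: float, gamma: float) -> np.ndarray:
    """OD450(t) = A (1 - exp(-gamma t)) / gamma, with the gamma -> 0 limit A t."""
    t = np.asarray(t, dtype=float)
    if gamma < 1e-12:
        return amp * t
    return amp * (-np.expm1(-gamma * t)) / gamma


def fit_onpg_kinetics(
    times: Sequence[float],
    od450: Sequence[float],
    od610_ref: float | None = None,
) -> OnpgKinetics:
    """Nonlinear least-squares fit of the ONPG product curve.

    Initialized at (amp = initial linear slope, gamma = 1e-3 / min) with
    both parameters bounded below by zero; when the best gamma is
    (numerically) zero the fit coincides with the linear-slope limit.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od450, dtype=float)
    if t.size < 5:
        raise ValueError(f"need >= 5 timepoints, got {t.size}")
    span = np.ptp(t)
    slope0 = max((y[-1] - y[0]) / span if span > 0 else 0.0, 1e-12)
    try:
        popt, _ = curve_fit(
            onpg_model,
            t,
            y,
            p0=(slope0, 1e-3),
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise RuntimeError(f"ONPG kinetics fit did not converge: {exc}") from exc
    amp, gamma = float(popt[0]), float(popt[1])
    resid = y - onpg_model(t, amp, gamma)
    return OnpgKinetics(
        amp=amp,
        gamma=gamma,
        od610_ref=od610_ref,
        residual_sd=float(np.std(resid, ddof=min(2, t.size - 1))),
    )


def miller_units(kin: OnpgKinetics) -> float:
    """beta-galactosidase activity in Miller units: 2e6 * A / OD610."""
    if kin.od610_ref is None or kin.od610_ref <= 0:
        raise ValueError("od610_ref must be positive to compute Miller units")
    return MILLER_COEFFICIENT * kin.amp / kin.od610_ref
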