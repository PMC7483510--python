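"""Free-RNAP and ppGpp inference from constitutive-reporter ratios.

Transcription initiation at a constitutive promoter is Michaelis-Menten
in the free RNA-polymerase concentration c_f (molecules per cubic
micron): promoter binding is fast relative to the downstream
isomerization steps, so the relative transcription rate is

    TR = a * c_f / (c_f + K)

with K the RNAP-promoter dissociation constant and a the initiation
(promoter-escape) scaling factor. Because the GFP translation rate is
assumed identical across constructs, it cancels from production-rate
ratios, and the ratio of GFP production rates from a low-affinity
(PLtet) and a high-affinity (P5) constitutive promoter,

    Gpr(PLtet)/Gpr(P5) = a (K5 + c_f) / (K_Ltet + c_f),

is a monotone reporter of c_f that can be inverted in closed form.
Anchoring the no-drug ratios to literature free-RNAP levels, described
by the double-exponential growth law log c_f = A exp(-mu_r / mu), fixes
the constants a and K5; the same inversion then yields c_f under
chloramphenicol.

ppGpp inhibition of the rRNA promoter P1 is quantified as the P1/P5
production-rate ratio divided by the ratio of their promoter activities
(which removes the shared c_f dependence) and modeled as a Hill function
of the ppGpp concentration, itself tied to growth rate by
c_p = c_p0 exp(-mu / mu_p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from freepol import growth_fit, plate_io
from freepol.plate_io import PlateWell

__all__ = [
    "RnapLaw",
    "PpgppLaw",
    "HillParams",
    "RatioConstants",
    "promoter_activity",
    "gpr_ratio_model",
    "invert_ratio_to_cf",
    "growth_law_eval",
    "growth_law_fit",
    "fit_ratio_constants",
    "ppgpp_inhibition_effect",
    "hill_inhibition",
    "hill_eval",
    "hill_invert",
    "hill_fit",
    "decompose_rates",
    "RateDecomposition",
    "estimate_free_rnap",
]


@dataclass(frozen=True)
class RnapLaw:
    """Growth-rate law for free RNAP: c_f(mu) = exp(a_log * exp(-mu_r / mu)).

    a_log is the asymptotic log-concentration (log molecules/um^3) and
    mu_r a growth-rate scale in doublings/hour. The reference fit to
    literature data gives a_log = 6.82 and mu_r = 0.11.
    """

    a_log: float = 6.82
    mu_r: float = 0.11

    def __post_init__(self) -> None:
        if self.mu_r <= 0:
            raise ValueError("mu_r must be > 0")


@dataclass(frozen=True)
class PpgppLaw:
    """Growth-rate law for ppGpp: c_p(mu) = cp0 * exp(-mu / mu_p)."""

    cp0: float
    mu_p: float

    def __post_init__(self) -> None:
        if self.cp0 <= 0 or self.mu_p <= 0:
            raise ValueError("cp0 and mu_p must be > 0")


@dataclass(frozen=True)
class HillParams:
    """Hill inhibition curve: effect(c_p) = b * k_p^n / (k_p^n + c_p^n)."""

    b: float
    k_p: float
    n: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.k_p <= 0 or self.n <= 0:
            raise ValueError("b, k_p and n must all be > 0")


@dataclass(frozen=True)
class RatioConstants:
    """Constants of the PLtet/P5 production-rate ratio model.

    a is the PLtet initiation scaling; K5, K_Ltet (and optionally K1 for
    the rRNA promoter) are dissociation constants in molecules/um^3.
    PLtet binds RNAP more weakly than P5, so K_Ltet > K5.
    """

    a: float = 10.5
    k5: float = 90.0
    k_ltet: float = 2000.0
    k1: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.k5 <= 0 or self.k_ltet <= 0:
            raise ValueError("a, K5 and K_Ltet must be > 0")
        if self.k_ltet <= self.k5:
            raise ValueError("K_Ltet must exceed K5 (PLtet is the lower-affinity promoter)")
        if self.k1 is not None and self.k1 <= 0:
            raise ValueError("K1 must be > 0 when given")


def promoter_activity(c_f, k: float, a: float = 1.0):
    """Relative transcription rate TR = a * c_f / (c_f + K) in [0, a)."""
    c_f = np.asarray(c_f, dtype=float)
    if np.any(c_f < 0):
        raise ValueError("c_f must be >= 0")
    if k <= 0:
        raise ValueError("K must be > 0")
    out = a * c_f / (c_f + k)
    return float(out) if out.ndim == 0 else out


def gpr_ratio_model(c_f, rc: RatioConstants):
    """PLtet/P5 production-rate ratio: a (K5 + c_f) / (K_Ltet + c_f).

    Strictly increasing in c_f (K_Ltet > K5), from a*K5/K_Ltet at
    c_f = 0 to a at saturation.
    """
    c_f = np.asarray(c_f, dtype=float)
    if np.any(c_f < 0):
        raise ValueError("c_f must be >= 0")
    out = rc.a * (rc.k5 + c_f) / (rc.k_ltet + c_f)
    return float(out) if out.ndim == 0 else out


def invert_ratio_to_cf(ratio, rc: RatioConstants):
    """Closed-form inversion of the ratio model to free-RNAP concentration.

    c_f = (a K5 - R K_Ltet) / (R - a), defined for ratios strictly
    inside the model's open range (a K5 / K_Ltet, a).
    """
    ratio = np.asarray(ratio, dtype=float)
    lo = rc.a * rc.k5 / rc.k_ltet
    if np.any(ratio <= lo) or np.any(ratio >= rc.a):
        raise ValueError(
            f"ratio outside model range ({lo:.6g}, {rc.a:.6g}); no finite c_f exists"
        )
    out = (rc.a * rc.k5 - ratio * rc.k_ltet) / (ratio - rc.a)
    return float(out) if out.ndim == 0 else out


def growth_law_eval(kind: str, mu, params):
    """Evaluate a growth-rate law.

    ``kind='rnap'``: c_f = exp(a_log * exp(-mu_r / mu)), increasing in
    mu and approaching 1 as mu -> 0+ (requires mu > 0).
    ``kind='ppgpp'``: c_p = cp0 * exp(-mu / mu_p), decreasing in mu
    (mu >= 0 allowed; c_p(0) = cp0).
    """
    mu = np.asarray(mu, dtype=float)
    if kind == "rnap":
        if np.any(mu <= 0):
            raise ValueError("mu must be > 0 for the RNAP law")
        out = np.exp(params.a_log * np.exp(-params.mu_r / mu))
    elif kind == "ppgpp":
        if np.any(mu < 0):
            raise ValueError("mu must be >= 0 for the ppGpp law")
        out = params.cp0 * np.exp(-mu / params.mu_p)
    else:
        raise ValueError(f"unknown law kind {kind!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LawFit:
    """Result of a growth-law fit: the law plus log-space residuals."""

    law: RnapLaw | PpgppLaw
    residuals: np.ndarray

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.residuals, ddof=min(2, self.residuals.size - 1)))


def growth_law_fit(kind: str, mu: Sequence[float], concentration: Sequence[float]) -> LawFit:
    """Fit a growth-rate law by least squares on log-concentration.

    Residuals are taken on log(c), matching the multiplicative error
    structure of concentration measurements. Needs >= 3 pairs with
    mu > 0 and concentration > 0.
    """
    mu = np.asarray(mu, dtype=float)
    conc = np.asarray(concentration, dtype=float)
    if mu.size != conc.size:
        raise ValueError("mu and concentration must have equal length")
    if mu.size < 3:
        raise ValueError(f"need >= 3 (mu, concentration) pairs, got {mu.size}")
    if np.any(mu <= 0) or np.any(conc <= 0):
        raise ValueError("mu and concentration must be positive")
    logc = np.log(conc)
    if kind == "rnap":

        def model(m, a_log, mu_r):
            return a_log * np.exp(-mu_r / m)

        try:
            popt, _ = curve_fit(
                model,
                mu,
                logc,
                p0=(float(logc.max()), 0.1),
                bounds=([0.0, 1e-6], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover
            raise RuntimeError(f"RNAP growth-law fit did not converge: {exc}") from exc
        law: RnapLaw | PpgppLaw = RnapLaw(a_log=float(popt[0]), mu_r=float(popt[1]))
        resid = logc - model(mu, *popt)
    elif kind == "ppgpp":
        # log c_p = log cp0 - mu / mu_p is linear in mu: closed-form OLS
        slope, intercept = np.polyfit(mu, logc, 1)
        if slope >= 0:
            raise RuntimeError("ppGpp law fit failed: concentration does not decay with mu")
        law = PpgppLaw(cp0=float(np.exp(intercept)), mu_p=float(-1.0 / slope))
        resid = logc - (slope * mu + intercept)
    else:
        raise ValueError(f"unknown law kind {kind!r}")
    return LawFit(law=law, residuals=resid)


@dataclass(frozen=True)
class RatioFit:
    """Fitted ratio-model constants plus log-space residuals."""

    constants: RatioConstants
    residuals: np.ndarray

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.residuals, ddof=min(2, self.residuals.size - 1)))


def fit_ratio_constants(
    mu: Sequence[float],
    ratios: Sequence[float],
    law: RnapLaw,
    k_ltet: float | None = None,
    delta_e: float | None = None,
) -> RatioFit:
    """Fit (a, K5) of the production-rate ratio model.

    c_f at each growth rate comes from the RNAP growth law; the ratio
    model is then fit in log space by bounded nonlinear least squares,
    started deterministically at a = max observed ratio and K5 = median
    c_f. K_Ltet is either supplied directly or linked to K5 through a
    binding-energy difference, K_Ltet = K5 * exp(delta_e).
    """
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if mu.size != r.size:
        raise ValueError("mu and ratios must have equal length")
    if mu.size < 3:
        raise ValueError(f"need >= 3 (mu, ratio) pairs, got {mu.size}")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    if (k_ltet is None) == (delta_e is None):
        raise ValueError("supply exactly one of k_ltet or delta_e")
    c_f = growth_law_eval("rnap", mu, law)
    log_r = np.log(r)

    def ltet(k5: float) -> float:
        return k_ltet if k_ltet is not None else k5 * float(np.exp(delta_e))

    def resid(theta: np.ndarray) -> np.ndarray:
        a, k5 = theta
        return np.log(a * (k5 + c_f) / (ltet(k5) + c_f)) - log_r

    x0 = np.array([float(r.max()), float(np.median(c_f))])
    sol = least_squares(resid, x0=x0, bounds=([1e-9, 1e-9], [np.inf, np.inf]))
    if not sol.success:  # pragma: no cover - least_squares rarely reports failure
        raise RuntimeError(f"ratio-constant fit did not converge: {sol.message}")
    a_hat, k5_hat = map(float, sol.x)
    constants = RatioConstants(
        a=a_hat, k5=k5_hat, k_ltet=ltet(k5_hat), k1=None
    )
    return RatioFit(constants=constants, residuals=resid(sol.x))


def ppgpp_inhibition_effect(
    gpr_p1: float, gpr_p5: float, c_f: float, k1: float, k5: float
) -> float:
    """Relative ppGpp effect on P1 transcription.

    The P1/P5 production-rate ratio divided by the ratio of their
    promoter activities: (Gpr1/Gpr5) * (c_f + K1) / (c_f + K5). With no
    inhibition and equal initiation factors the effect is 1.
    """
    for label, v in (("gpr_p1", gpr_p1), ("gpr_p5", gpr_p5), ("c_f", c_f), ("k1", k1), ("k5", k5)):
        if v <= 0:
            raise ValueError(f"{label} must be > 0, got {v}")
    return (gpr_p1 / gpr_p5) * (c_f + k1) / (c_f + k5)


def hill_eval(c_p, params: HillParams):
    """Hill inhibition effect b * k_p^n / (k_p^n + c_p^n)."""
    c_p = np.asarray(c_p, dtype=float)
    if np.any(c_p < 0):
        raise ValueError("c_p must be >= 0")
    kn = params.k_p**params.n
    out = params.b * kn / (kn + c_p**params.n)
    return float(out) if out.ndim == 0 else out


def hill_invert(effect, params: HillParams):
    """Unique c_p giving the stated effect; requires 0 < effect < b."""
    effect = np.asarray(effect, dtype=float)
    if np.any(effect <= 0) or np.any(effect >= params.b):
        raise ValueError(f"effect must lie strictly inside (0, b={params.b})")
    out = params.k_p * ((params.b - effect) / effect) ** (1.0 / params.n)
    return float(out) if out.ndim == 0 else out


def hill_fit(c_p: Sequence[float], effect: Sequence[float]) -> HillParams:
    """Least-squares Hill parameters from >= 4 (c_p, effect) pairs."""
    c_p = np.asarray(c_p, dtype=float)
    eff = np.asarray(effect, dtype=float)
    if c_p.size != eff.size:
        raise ValueError("c_p and effect must have equal length")
    if c_p.size < 4:
        raise ValueError(f"need >= 4 (c_p, effect) pairs, got {c_p.size}")

    def model(c, b, k_p, n):
        return b * k_p**n / (k_p**n + c**n)

    p0 = (float(eff.max()), float(np.median(c_p[c_p > 0])) or 1.0, 1.0)
    try:
        popt, _ = curve_fit(
            model, c_p, eff, p0=p0, bounds=([1e-9] * 3, [np.inf] * 3), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    return HillParams(b=float(popt[0]), k_p=float(popt[1]), n=float(popt[2]))


def hill_inhibition(value, params: HillParams | None = None, mode: str = "eval"):
    """Dispatcher over the Hill curve: evaluate, invert, or fit.

    ``eval``: value = c_p -> effect. ``invert``: value = effect -> c_p.
    ``fit``: value = (c_p array, effect array) -> :class:`HillParams`.
    """
    if mode == "eval":
        if params is None:
            raise ValueError("eval mode needs HillParams")
        return hill_eval(value, params)
    if mode == "invert":
        if params is None:
            raise ValueError("invert mode needs HillParams")
        return hill_invert(value, params)
    if mode == "fit":
        c_p, effect = value
        return hill_fit(c_p, effect)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# transcription / translation decomposition


@dataclass(frozen=True)
class RateDecomposition:
    """Per-promoter transcription rates and the shared translation rate.

    Residuals are fractional: gpr_observed / gpr_predicted - 1, zero for
    the anchor promoter by construction.
    """

    translation_rate: float
    transcription_rates: dict[str, float]
    predicted_gpr: dict[str, float]
    residuals: dict[str, float]


def _promoter_constants(rc: RatioConstants) -> dict[str, tuple[float, float]]:
    consts = {"P5": (rc.k5, 1.0), "PLtet": (rc.k_ltet, rc.a)}
    if rc.k1 is not None:
        consts["P1"] = (rc.k1, 1.0)
    return consts


def decompose_rates(
    gprs: Mapping[str, float], c_f: float, rc: RatioConstants, anchor: str = "P5"
) -> RateDecomposition:
    """Split production rates into transcription and translation parts.

    The GFP translation rate is assumed promoter-independent, so the
    anchor promoter (P5) fixes it: translation = Gpr(anchor)/TR(anchor).
    Every other promoter's predicted Gpr is TR_i * translation; the
    fractional residual flags where the shared-translation assumption
    breaks down.
    """
    if c_f <= 0:
        raise ValueError("c_f must be > 0")
    if anchor not in gprs:
        raise ValueError(f"anchor promoter {anchor!r} missing from gprs")
    consts = _promoter_constants(rc)
    unknown = set(gprs) - set(consts)
    if unknown:
        raise ValueError(
            f"no dissociation constant for promoters {sorted(unknown)}; "
            "set RatioConstants.k1 or restrict to P5/PLtet/P1"
        )
    tr = {name: promoter_activity(c_f, *consts[name]) for name in gprs}
    translation = gprs[anchor] / tr[anchor]
    predicted = {name: tr[name] * translation for name in gprs}
    residuals = {name: gprs[name] / predicted[name] - 1.0 for name in gprs}
    return RateDecomposition(
        translation_rate=float(translation),
        transcription_rates={k: float(v) for k, v in tr.items()},
        predicted_gpr={k: float(v) for k, v in predicted.items()},
        residuals={k: float(v) for k, v in residuals.items()},
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline: plate wells -> free RNAP per condition


def estimate_free_rnap(
    wells: Iterable[PlateWell],
    rc: RatioConstants,
    channel: str = "GFP",
    numerator: str = "PLtet",
    denominator: str = "P5",
    blank_strain: str = "BW25113",
    od_lo: float = growth_fit.DEFAULT_OD_LO,
    od_hi: float = growth_fit.DEFAULT_OD_HI,
    window_mode: str = "fixed",
) -> pd.DataFrame:
    """Estimate free RNAP per condition from a reporter plate.

    For every (medium, cm_um) condition the pipeline subtracts the
    per-medium autofluorescence fitted from blank-strain wells, fits the
    exponential window of each reporter well, forms the
    numerator/denominator production-rate ratio, and inverts it to c_f.
    Conditions whose ratio falls outside the model's range get NaN.

    Returns a DataFrame with columns medium, cm_um, mu, gpr_num,
    gpr_den, ratio, c_f.
    """
    wells = list(wells)
    blanks_by_medium: dict[str, list[PlateWell]] = {}
    for w in wells:
        if w.condition.strain == blank_strain:
            blanks_by_medium.setdefault(w.condition.medium, []).append(w)
    af_models = {
        medium: plate_io.AutofluorModel.from_blank_wells(group, channel, medium=medium)
        for medium, group in blanks_by_medium.items()
    }

    estimates: dict[tuple[str, float], dict[str, growth_fit.GrowthEstimate]] = {}
    for w in wells:
        strain = w.condition.strain
        if strain == blank_strain or strain not in (numerator, denominator):
            continue
        model = af_models.get(w.condition.medium, plate_io.AutofluorModel.zero())
        corrected = plate_io.subtract_autofluorescence(w, model, channel)
        window = growth_fit.find_exponential_window(
            corrected, od_lo=od_lo, od_hi=od_hi, mode=window_mode
        )
        est = growth_fit.fit_exponential_phase(corrected, window, channel)
        estimates.setdefault((w.condition.medium, w.condition.cm_um), {})[strain] = est

    rows = []
    for (medium, cm_um), by_strain in sorted(estimates.items()):
        if numerator not in by_strain or denominator not in by_strain:
            continue
        num, den = by_strain[numerator], by_strain[denominator]
        ratio = num.gpr / den.gpr
        try:
            c_f = invert_ratio_to_cf(ratio, rc)
        except ValueError:
            c_f = float("nan")
        rows.append(
            {
                "medium": medium,
                "cm_um": cm_um,
                "mu": 0.5 * (num.mu + den.mu),
                "gpr_num": num.gpr,
                "gpr_den": den.gpr,
                "ratio": ratio,
                "c_f": c_f,
            }
        )
    return pd.DataFrame(rows, columns=["medium", "cm_um", "mu", "gpr_num", "gpr_den", "ratio", "c_f"])
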