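"""Seeded synthetic plate-reader and ratio datasets.

The generator emulates the measurement process the analysis assumes: a
96-well plate sampled every 7 minutes for 30 hours, logistic OD curves
(exponential growth saturating at a carrying capacity so that window
selection is non-trivial), reporter fluorescence proportional to OD on
top of a medium-specific autofluorescence background, and multiplicative
lognormal measurement noise with a small additive read-noise floor.

Reporter levels are scaled across the 4-media x 4-Cm condition grid by
the forward model itself: free RNAP follows the double-exponential
growth law, each construct's transcription rate follows Michaelis-
Menten promoter activity, and the chloramphenicol completion
probability attenuates translation of the reporter gene. Ground truth
is returned alongside the wells so recovery can be scored exactly.

Everything is a pure function of (truth, seed): identical seeds give
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from freepol.plate_io import Condition, PlateWell
from freepol.processivity import GeneSpec, TranslationParams, completion_probability
from freepol.rnap_ppgpp import RatioConstants, RnapLaw, growth_law_eval, gpr_ratio_model, promoter_activity

__all__ = [
    "BLANK_STRAIN",
    "DEFAULT_MEDIA_MU",
    "DEFAULT_CM_GRID",
    "SimulationTruth",
    "default_mu_vs_cm",
    "simulate_plate_reader",
    "simulate_ratio_dataset",
    "noiseless",
]

#: Non-fluorescent wild-type strain used for autofluorescence blanks.
BLANK_STRAIN = "BW25113"

#: Doubling rates (doublings/hour) of the four reference media at Cm = 0.
DEFAULT_MEDIA_MU: dict[str, float] = {
    "M9-gly": 0.65,
    "M9-glu": 0.95,
    "cAA-gly": 1.35,
    "cAA-glu": 1.75,
}

#: Chloramphenicol grid (uM) of the reference experiment.
DEFAULT_CM_GRID: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)

#: Autofluorescence per medium: (offset RFU, slope RFU per OD unit).
DEFAULT_AUTOFLUOR: dict[str, tuple[float, float]] = {
    "M9-gly": (25.0, 220.0),
    "M9-glu": (20.0, 180.0),
    "cAA-gly": (35.0, 300.0),
    "cAA-glu": (30.0, 260.0),
}


def default_mu_vs_cm(mu0: float, cm_um: float) -> float:
    """Sublethal growth inhibition: linear slowdown, ~50% at 8 uM Cm.

    Stand-in for a user-supplied mu(Cm) mapping; replace via
    ``SimulationTruth.mu_vs_cm`` when a mechanistic dose-response is
    available.
    """
    return mu0 * max(0.15, 1.0 - 0.06 * cm_um)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of one simulated experiment.

    Defaults mirror the reference study conditions: the 4-media x 4-Cm
    grid, sampling every 7 min for 30 h, lognormal noise CV 2%,
    logistic carrying capacity 1.0 OD. ``carrying_capacity=np.inf``
    selects pure exponential growth (no saturation).
    """

    media_growth_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIA_MU)
    )
    cm_grid: tuple[float, ...] = DEFAULT_CM_GRID
    ratio_constants: RatioConstants = field(
        default_factory=lambda: RatioConstants(a=10.5, k5=90.0, k_ltet=2000.0, k1=90.0)
    )
    rnap_law: RnapLaw = field(default_factory=RnapLaw)
    translation: TranslationParams = field(default_factory=TranslationParams)
    gene: GeneSpec = field(default_factory=lambda: GeneSpec("gfpmut2", 238))
    base_expression: float = 2000.0  # RFU/OD at unit promoter activity, full completion
    noise_cv: float = 0.02
    od_read_sd: float = 0.002
    rfu_read_sd: float = 5.0
    carrying_capacity: float = 1.0
    od0: float = 0.002
    interval_min: float = 7.0
    duration_h: float = 30.0
    autofluor: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AUTOFLUOR)
    )
    mu_vs_cm: Callable[[float, float], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(mu <= 0 for mu in self.media_growth_rates.values()):
            raise ValueError("media growth rates must be > 0")
        if any(cm < 0 for cm in self.cm_grid):
            raise ValueError("cm_grid must be non-negative")
        if self.noise_cv < 0 or self.od_read_sd < 0 or self.rfu_read_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.interval_min <= 0 or self.duration_h <= 0:
            raise ValueError("sampling interval and duration must be > 0")
        if self.od0 <= 0 or self.carrying_capacity <= self.od0:
            raise ValueError("need 0 < od0 < carrying_capacity")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be > 0")

    def realized_mu(self, medium: str, cm_um: float) -> float:
        mu0 = self.media_growth_rates[medium]
        f = self.mu_vs_cm or default_mu_vs_cm
        return f(mu0, cm_um)

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h * 60.0 + 0.5 * self.interval_min, self.interval_min)

    def od_curve(self, mu: float, time_min: np.ndarray) -> np.ndarray:
        """Logistic OD(t) with exponential rate lambda = mu ln2 / 60 per min."""
        lam = mu * np.log(2.0) / 60.0
        if not np.isfinite(self.carrying_capacity):
            return self.od0 * np.exp(lam * time_min)
        k, od0 = self.carrying_capacity, self.od0
        e = np.exp(lam * time_min)
        return k * od0 * e / (k + od0 * (e - 1.0))

    def reporter_concentration(self, construct: str, medium: str, cm_um: float) -> float:
        """Forward-model RFU/OD for one construct in one condition."""
        rc = self.ratio_constants
        consts = {"P5": (rc.k5, 1.0), "PLtet": (rc.k_ltet, rc.a)}
        if rc.k1 is not None:
            consts["P1"] = (rc.k1, 1.0)
        if construct not in consts:
            raise ValueError(f"unknown construct {construct!r}")
        mu = self.realized_mu(medium, cm_um)
        c_f = growth_law_eval("rnap", mu, self.rnap_law)
        k, a = consts[construct]
        tr = promoter_activity(c_f, k, a)
        completion = completion_probability(self.gene, cm_um, self.translation)
        return self.base_expression * tr * completion


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-unbiased multiplicative noise; exactly 1 when cv = 0."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_plate_reader(
    truth: SimulationTruth,
    constructs: Sequence[str] = ("P5", "PLtet"),
    media: Sequence[str] | None = None,
    cm_grid: Sequence[float] | None = None,
    include_blanks: bool = True,
    channel: str = "GFP",
) -> tuple[list[PlateWell], dict]:
    """Simulate a reporter plate over a conditions x constructs grid.

    Returns the wells plus a ground-truth record: per-condition realized
    growth rate and free-RNAP concentration, and per-construct reporter
    concentrations (RFU/OD).
    """
    rng = np.random.default_rng(truth.seed)
    media = list(media if media is not None else truth.media_growth_rates)
    cms = list(cm_grid if cm_grid is not None else truth.cm_grid)
    time = truth.time_grid()
    n = time.size

    wells: list[PlateWell] = []
    record: dict = {"conditions": [], "seed": truth.seed}
    idx = 0

    def next_well_id() -> str:
        nonlocal idx
        row, col = divmod(idx, 12)
        idx += 1
        return f"{chr(ord('A') + row % 8)}{col + 1}{'' if idx <= 96 else '.' + str(idx // 96)}"

    for medium in media:
        af_offset, af_slope = truth.autofluor.get(medium, (0.0, 0.0))
        for cm in cms:
            mu = truth.realized_mu(medium, cm)
            c_f = growth_law_eval("rnap", mu, truth.rnap_law)
            od = truth.od_curve(mu, time)
            cond_record = {
                "medium": medium,
                "cm_um": cm,
                "mu": mu,
                "c_f": c_f,
                "concentrations": {},
            }
            strains = list(constructs) + ([BLANK_STRAIN] if include_blanks else [])
            for strain in strains:
                if strain == BLANK_STRAIN:
                    conc = 0.0
                else:
                    conc = truth.reporter_concentration(strain, medium, cm)
                    cond_record["concentrations"][strain] = conc
                fluor = af_offset + af_slope * od + conc * od
                od_meas = od * _lognormal_factor(rng, truth.noise_cv, n)
                fluor_meas = fluor * _lognormal_factor(rng, truth.noise_cv, n)
                if truth.od_read_sd > 0:
                    od_meas = np.clip(od_meas + rng.normal(0.0, truth.od_read_sd, n), 0.0, None)
                if truth.rfu_read_sd > 0:
                    fluor_meas = fluor_meas + rng.normal(0.0, truth.rfu_read_sd, n)
                wells.append(
                    PlateWell(
                        well_id=next_well_id(),
                        condition=Condition(medium=medium, cm_um=cm, strain=strain),
                        time=time.copy(),
                        od610=od_meas,
                        channels={channel: fluor_meas},
                    )
                )
            record["conditions"].append(cond_record)
    return wells, record


def simulate_ratio_dataset(
    truth: SimulationTruth,
    mu_grid: Sequence[float] = (0.4, 0.8, 1.2, 1.6, 2.0, 2.5),
    n_rep: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate (mu, Gpr-ratio) pairs for ratio-constant fitting.

    Each pair is the forward ratio model evaluated at the growth-law
    free-RNAP concentration, degraded by multiplicative lognormal noise
    of the truth's CV; ``n_rep`` replicates per growth rate. Returns an
    (n_rep * len(mu_grid), 2) array; empty when n_rep = 0.
    """
    if n_rep < 0:
        raise ValueError("n_rep must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mu = np.asarray(mu_grid, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu_grid must be positive (RNAP-law domain)")
    mus = np.repeat(mu, n_rep)
    if mus.size == 0:
        return np.empty((0, 2))
    c_f = growth_law_eval("rnap", mus, truth.rnap_law)
    r = gpr_ratio_model(c_f, truth.ratio_constants)
    r = np.asarray(r, dtype=float) * _lognormal_factor(rng, truth.noise_cv, mus.size)
    return np.column_stack([mus, r])


def noiseless(truth: SimulationTruth) -> SimulationTruth:
    """Copy of the truth with every noise source switched off."""
    return replace(truth, noise_cv=0.0, od_read_sd=0.0, rfu_read_sd=0.0)
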