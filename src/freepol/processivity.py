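"""Translation-processivity models under chloramphenicol.

Chloramphenicol (Cm) binds translating ribosomes with rate constant
k_on * [Cm]; a ribosome traversing a gene of length L amino acids at
elongation rate v is exposed for L / v minutes, so the probability of
being hit before finishing is

    P_hit = 1 - exp(-k_on [Cm] L / v).

A stalled ribosome triggers 5'->3' mRNA degradation that also stops
the other ribosomes on the transcript, so long genes — and genes
downstream in an operon — lose expression disproportionately. On top of
the drug effect there is a baseline per-codon stall probability beta0,
giving the completion probability

    P_complete = exp(-(beta0 + k_on [Cm] / v) * L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TranslationParams",
    "GeneSpec",
    "OperonConstruct",
    "Beta0Fit",
    "p_hit",
    "completion_probability",
    "fit_beta0",
    "length_ratio_curve",
    "operon_expression_ratio",
]


@dataclass(frozen=True)
class TranslationParams:
    """Kinetic parameters of the stalling model.

    k_on : Cm-ribosome binding constant, 1/(uM min); default 0.034.
    v : translation elongation rate, aa/min; default 1050 (17.5 aa/s),
        consistent with the fast-growth regime. v depends on the
        RNA/protein mass ratio in vivo; pass a condition-specific value
        where that matters.
    beta0 : baseline stall probability per amino acid; default 3e-4.
    """

    k_on: float = 0.034
    v: float = 1050.0
    beta0: float = 3e-4

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.v <= 0:
            raise ValueError("v must be > 0")
        if self.beta0 < 0:
            raise ValueError("beta0 must be >= 0")


@dataclass(frozen=True)
class GeneSpec:
    """A gene identified by its protein length in amino acids."""

    name: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError(f"gene {self.name}: length_aa must be >= 1")

    @classmethod
    def from_nt(cls, name: str, length_nt: int) -> "GeneSpec":
        """Build from a nucleotide length (floor division by 3)."""
        return cls(name=name, length_aa=length_nt // 3)


@dataclass(frozen=True)
class OperonConstruct:
    """An ordered (upstream -> downstream) reporter operon.

    ``terminator_efficiency`` y in [0, 1] applies between consecutive
    genes (scalar, or one value per junction). The normalization
    constant C absorbs RBS-strength and maturation differences between
    the reporters and is fit at Cm = 0.
    """

    genes: tuple[GeneSpec, ...]
    terminator_efficiency: float | tuple[float, ...] = 0.0
    norm_constant: float = 1.0

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("an operon construct needs >= 2 genes")
        ys = self.terminator_efficiencies
        if len(ys) != len(self.genes) - 1:
            raise ValueError("need one terminator efficiency per gene junction")
        if any(not (0.0 <= y <= 1.0) for y in ys):
            raise ValueError("terminator efficiency must lie in [0, 1]")
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be > 0")

    @property
    def terminator_efficiencies(self) -> tuple[float, ...]:
        y = self.terminator_efficiency
        if isinstance(y, (int, float)):
            return (float(y),) * (len(self.genes) - 1)
        return tuple(float(v) for v in y)


def p_hit(gene: GeneSpec, cm_um, tp: TranslationParams):
    """Probability a ribosome is Cm-bound before completing the gene.

    P_hit = 1 - exp(-k_on [Cm] L / v), in [0, 1), monotone increasing
    in both gene length and drug concentration.
    """
    cm = np.asarray(cm_um, dtype=float)
    if np.any(cm < 0):
        raise ValueError("cm_um must be >= 0")
    out = -np.expm1(-tp.k_on * cm * gene.length_aa / tp.v)
    return float(out) if out.ndim == 0 else out


def completion_probability(gene: GeneSpec, cm_um, tp: TranslationParams):
    """Probability a ribosome finishes the gene: baseline times drug survival.

    P_complete = exp(-beta0 L) * (1 - P_hit)
               = exp(-(beta0 + k_on [Cm] / v) * L).
    """
    cm = np.asarray(cm_um, dtype=float)
    if np.any(cm < 0):
        raise ValueError("cm_um must be >= 0")
    out = np.exp(-(tp.beta0 + tp.k_on * cm / tp.v) * gene.length_aa)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Beta0Fit:
    """Baseline stall-rate fit with residual diagnostics.

    ``degenerate`` marks designs that cannot identify beta0 (all gene
    lengths equal); the residual SD flags inconsistent replicate
    activities either way.
    """

    beta0: float
    residual_sd: float
    degenerate: bool = False


def fit_beta0(data: Sequence[tuple[float, float]]) -> Beta0Fit:
    """Fit beta0 from relative activities of length variants.

    The model is activity(L) / activity(L_ref) = exp(-beta0 (L - L_ref))
    with L_ref the shortest (wild-type) length, solved by least squares
    through the origin in log space and floored at zero (beta0 is a
    probability per residue).
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (length_aa, relative_activity) pairs")
    lengths, acts = arr[:, 0], arr[:, 1]
    if np.any(acts <= 0):
        raise ValueError("activities must be positive")
    l_ref = lengths.min()
    dl = lengths - l_ref
    log_act = np.log(acts)
    denom = float(np.sum(dl * dl))
    if denom == 0.0:
        resid = log_act - log_act.mean()
        return Beta0Fit(
            beta0=0.0,
            residual_sd=float(np.sqrt(np.mean(resid**2))),
            degenerate=True,
        )
    beta0 = max(0.0, float(-np.sum(dl * log_act) / denom))
    resid = log_act + beta0 * dl
    return Beta0Fit(beta0=beta0, residual_sd=float(np.sqrt(np.mean(resid**2))))


def length_ratio_curve(
    short: GeneSpec, long: GeneSpec, cm_grid: Sequence[float], tp: TranslationParams
) -> np.ndarray:
    """Short/long expression ratio along a Cm gradient, normalized at Cm = 0.

    ratio(Cm) = [P_complete(short) / P_complete(long)] / [same at 0]
              = exp(k_on Cm (L_long - L_short) / v):
    the baseline stall rate beta0 cancels exactly, so the normalized
    curve isolates the drug effect. Strictly increasing in Cm when the
    long gene is longer.
    """
    cm = np.asarray(cm_grid, dtype=float)
    if not np.any(cm == 0.0):
        raise ValueError("cm_grid must include 0 (the normalization point)")
    raw = completion_probability(short, cm, tp) / completion_probability(long, cm, tp)
    ref = completion_probability(short, 0.0, tp) / completion_probability(long, 0.0, tp)
    return raw / ref


def operon_expression_ratio(
    construct: OperonConstruct, cm_um, tp: TranslationParams
):
    """Downstream/upstream expression ratio of an operon construct.

    A stall anywhere in the upstream genes degrades the transcript and
    abolishes downstream expression, and each intergenic terminator
    passes RNAP with probability (1 - y), so

        ratio = C * prod(1 - y_j) * prod_upstream P_complete(gene, Cm).

    Decreasing in Cm and in y; at Cm = 0 with y = 0 and beta0 = 0 the
    ratio equals C. The normalized ratio(Cm)/ratio(0) is independent of
    y and C (both cancel), so the fractional drug response is
    terminator-independent.
    """
    upstream = construct.genes[:-1]
    passthrough = float(np.prod([1.0 - y for y in construct.terminator_efficiencies]))
    completion = np.prod(
        [completion_probability(g, cm_um, tp) for g in upstream], axis=0
    )
    out = construct.norm_constant * passthrough * completion
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out
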