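"""Thermodynamic promoter scoring (Berg-von Hippel style).

A sigma70 promoter is scored by summing per-position mismatch penalties
over its -35 and -10 hexamers relative to the consensus TTGACA / TATAAT,
plus a penalty for suboptimal spacer length between them. The energy E
is dimensionless (units of the penalty matrix) and defined so that the
consensus promoter with optimal spacer has E = 0; only energy
*differences* are ever used downstream, via

    K_j = K_i * exp(E_j - E_i)

which converts a known RNAP-promoter dissociation constant K_i into the
one for a second promoter of known relative binding energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "CONSENSUS_MINUS35",
    "CONSENSUS_MINUS10",
    "PromoterAnnotation",
    "EnergyParams",
    "PromoterModel",
    "score_promoter_energy",
    "scale_dissociation_constant",
    "read_promoter_annotations",
    "load_energy_params",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONSENSUS_MINUS35 = "TTGACA"
CONSENSUS_MINUS10 = "TATAAT"


@dataclass(frozen=True)
class PromoterAnnotation:
    """A promoter sequence with annotated -35 and -10 hexamer positions.

    Offsets are 0-based on the given sequence. For minus-strand
    annotations the sequence is reverse-complemented (and the offsets
    mirrored) before scoring, so scoring always happens in promoter
    orientation.
    """

    name: str
    sequence: str
    minus35_start: int
    minus10_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"promoter {self.name}: non-ACGT characters {sorted(bad)}")
        for label, start in (("-35", self.minus35_start), ("-10", self.minus10_start)):
            if not (0 <= start and start + 6 <= len(seq)):
                raise ValueError(f"promoter {self.name}: {label} hexamer outside sequence")
        if self.spacer_length < 0:
            raise ValueError(
                f"promoter {self.name}: -10 hexamer overlaps or precedes the -35 hexamer"
            )

    @property
    def spacer_length(self) -> int:
        # in promoter orientation the -35 box precedes the -10 box; on the
        # minus strand the given coordinates run the other way
        if self.strand == "+":
            return self.minus10_start - (self.minus35_start + 6)
        return self.minus35_start - (self.minus10_start + 6)

    def oriented(self) -> "PromoterAnnotation":
        """Return the annotation in promoter (plus-strand) orientation."""
        if self.strand == "+":
            return self
        n = len(self.sequence)
        rc = self.sequence.translate(_COMPLEMENT)[::-1]
        return PromoterAnnotation(
            name=self.name,
            sequence=rc,
            minus35_start=n - (self.minus35_start + 6),
            minus10_start=n - (self.minus10_start + 6),
            strand="+",
        )

    @property
    def minus35(self) -> str:
        return self.sequence[self.minus35_start : self.minus35_start + 6]

    @property
    def minus10(self) -> str:
        return self.sequence[self.minus10_start : self.minus10_start + 6]


@dataclass
class EnergyParams:
    """Penalty matrices and spacer table for promoter scoring.

    ``minus35_matrix`` and ``minus10_matrix`` are (6, 4) arrays of
    non-negative penalties indexed by (position, base A/C/G/T), with
    zeros at the consensus base of each position. ``spacer_penalty``
    maps spacer length (nt) to a penalty; lengths outside the table get
    ``spacer_default``. The default parameterization is the simplified
    discrimination rule: a uniform penalty of 2 energy units per
    non-consensus base, spacer optimum at 17 nt.
    """

    minus35_matrix: np.ndarray
    minus10_matrix: np.ndarray
    spacer_penalty: dict[int, float] = field(default_factory=lambda: {17: 0.0, 16: 2.0, 18: 2.0})
    spacer_default: float = 4.0
    consensus_minus35: str = CONSENSUS_MINUS35
    consensus_minus10: str = CONSENSUS_MINUS10

    def __post_init__(self) -> None:
        self.minus35_matrix = np.asarray(self.minus35_matrix, dtype=float)
        self.minus10_matrix = np.asarray(self.minus10_matrix, dtype=float)
        for label, mat, cons in (
            ("-35", self.minus35_matrix, self.consensus_minus35),
            ("-10", self.minus10_matrix, self.consensus_minus10),
        ):
            if mat.shape != (6, 4):
                raise ValueError(f"{label} matrix must be 6x4, got {mat.shape}")
            if np.any(mat < 0):
                raise ValueError(f"{label} matrix has negative penalties")
            for pos, base in enumerate(cons):
                if mat[pos, _BASE_INDEX[base]] != 0.0:
                    raise ValueError(f"{label} matrix: consensus entry at position {pos} != 0")
        if min(self.spacer_penalty.values()) != 0.0:
            raise ValueError("spacer table must reach 0 at its optimum")
        optima = [k for k, v in self.spacer_penalty.items() if v == 0.0]
        if len(optima) != 1:
            raise ValueError("spacer table must have a unique minimum")
        if any(v < 0 for v in self.spacer_penalty.values()) or self.spacer_default < 0:
            raise ValueError("spacer penalties must be non-negative")

    @classmethod
    def default(cls, mismatch_penalty: float = 2.0) -> "EnergyParams":
        """Uniform mismatch penalty matrices (consensus rows zero)."""

        def matrix(consensus: str) -> np.ndarray:
            mat = np.full((6, 4), mismatch_penalty, dtype=float)
            for pos, base in enumerate(consensus):
                mat[pos, _BASE_INDEX[base]] = 0.0
            return mat

        return cls(
            minus35_matrix=matrix(CONSENSUS_MINUS35),
            minus10_matrix=matrix(CONSENSUS_MINUS10),
        )

    def spacer_cost(self, length: int) -> float:
        return self.spacer_penalty.get(length, self.spacer_default)


@dataclass(frozen=True)
class PromoterModel:
    """A promoter's binding energy, dissociation constant, and initiation factor.

    K is in molecules per cubic micron; a rescales transcription
    initiation frequency (promoter escape) relative to the reference
    promoter and is independent of RNAP concentration.
    """

    name: str
    energy: float
    k: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"promoter {self.name}: K must be > 0")
        if self.a <= 0:
            raise ValueError(f"promoter {self.name}: a must be > 0")


def _hexamer_energy(hexamer: str, matrix: np.ndarray) -> float:
    return float(sum(matrix[pos, _BASE_INDEX[base]] for pos, base in enumerate(hexamer)))


def score_promoter_energy(ann: PromoterAnnotation, params: EnergyParams) -> float:
    """Total binding energy: -35 penalties + -10 penalties + spacer penalty.

    Additive by construction; E = 0 iff both hexamers are consensus and
    the spacer length is optimal.
    """
    ann = ann.oriented()
    return (
        _hexamer_energy(ann.minus35, params.minus35_matrix)
        + _hexamer_energy(ann.minus10, params.minus10_matrix)
        + params.spacer_cost(ann.spacer_length)
    )


def scale_dissociation_constant(k_ref: float, e_ref: float, e_new: float) -> float:
    """K_new = K_ref * exp(E_new - E_ref).

    Exponential mapping from binding-energy differences to
    dissociation-constant ratios; a higher energy (weaker binding) gives
    a strictly larger K.
    """
    if k_ref <= 0:
        raise ValueError(f"K_ref must be > 0, got {k_ref}")
    return k_ref * float(np.exp(e_new - e_ref))


# ---------------------------------------------------------------------------
# file I/O


def read_promoter_annotations(
    fasta_path: str | Path, table_path: str | Path
) -> list[PromoterAnnotation]:
    """Read promoter sequences (FASTA) and hexamer positions (CSV).

    The CSV columns ``minus35_start_1based`` and ``minus10_start_1based``
    follow the 1-based inclusive convention common to promoter tables
    and are converted to 0-based offsets on read.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(table_path)
    required = {"name", "minus35_start_1based", "minus10_start_1based"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    anns = []
    for row in df.itertuples():
        name = str(row.name)
        if name not in seqs:
            raise ValueError(f"promoter {name!r} not present in FASTA")
        anns.append(
            PromoterAnnotation(
                name=name,
                sequence=seqs[name],
                minus35_start=int(row.minus35_start_1based) - 1,
                minus10_start=int(row.minus10_start_1based) - 1,
                strand=str(getattr(row, "strand", "+")),
            )
        )
    return anns


def load_energy_params(path: str | Path) -> EnergyParams:
    """Load an :class:`EnergyParams` override from a YAML config.

    Recognized keys: ``mismatch_penalty`` (scalar, builds uniform
    matrices), ``minus35_matrix`` / ``minus10_matrix`` (6x4 nested
    lists, base order ACGT), ``spacer_penalty`` (mapping length ->
    penalty), ``spacer_default``.
    """
    import yaml

    with open(path) as fh:
        cfg: Mapping = yaml.safe_load(fh) or {}
    base = EnergyParams.default(float(cfg.get("mismatch_penalty", 2.0)))
    m35 = np.asarray(cfg["minus35_matrix"], dtype=float) if "minus35_matrix" in cfg else base.minus35_matrix
    m10 = np.asarray(cfg["minus10_matrix"], dtype=float) if "minus10_matrix" in cfg else base.minus10_matrix
    spacer = (
        {int(k): float(v) for k, v in cfg["spacer_penalty"].items()}
        if "spacer_penalty" in cfg
        else base.spacer_penalty
    )
    return EnergyParams(
        minus35_matrix=m35,
        minus10_matrix=m10,
        spacer_penalty=spacer,
        spacer_default=float(cfg.get("spacer_default", base.spacer_default)),
    )
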