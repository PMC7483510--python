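"""Plate-reader I/O and autofluorescence correction.

A plate-reader run is a set of wells, each carrying a time series of
optical density (OD610) and one or more fluorescence channels (RFU).
Cells themselves fluoresce weakly; before any reporter quantification the
autofluorescence of a non-fluorescent reference strain, measured at the
same OD in the same medium, is subtracted from each fluorescent well.

Two CSV layouts are supported:

* wide — one ``time_min`` column plus one column per well and channel,
  named ``<well>_<channel>`` (e.g. ``A1_OD610``, ``A1_GFP``);
* long — tidy columns ``time_min, well_id, channel, value``.

Condition metadata (medium, chloramphenicol concentration in uM, strain)
lives in a separate table keyed by well id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KNOWN_MEDIA",
    "OD_CHANNEL",
    "Condition",
    "PlateWell",
    "AutofluorModel",
    "PlateParseError",
    "PlateValidationError",
    "read_plate_table",
    "write_plate_table",
    "read_condition_table",
    "write_condition_table",
    "subtract_autofluorescence",
]

#: Growth media used in the reference condition grid.
KNOWN_MEDIA = ("M9-gly", "M9-glu", "cAA-gly", "cAA-glu")

#: Column-name suffix under which optical density is stored.
OD_CHANNEL = "OD610"


class PlateParseError(ValueError):
    """A plate CSV does not follow the expected layout."""


class PlateValidationError(ValueError):
    """A well's series violate a structural invariant."""


@dataclass(frozen=True)
class Condition:
    """Growth condition of one well.

    Parameters
    ----------
    medium : str
        Growth medium name (e.g. ``"M9-glu"``); free text is accepted.
    cm_um : float
        Chloramphenicol concentration in uM, >= 0.
    strain : str
        Strain / reporter-construct label (e.g. ``"P5"``, ``"PLtet"``).
    """

    medium: str = "unknown"
    cm_um: float = 0.0
    strain: str = ""

    def __post_init__(self) -> None:
        if self.cm_um < 0:
            raise PlateValidationError(f"cm_um must be >= 0, got {self.cm_um}")


@dataclass
class PlateWell:
    """One well's time series plus its condition metadata.

    ``time`` is in minutes and strictly increasing; ``od610`` is
    non-negative; every fluorescence channel has the same length as
    ``time``. Fluorescence values may be negative after background
    subtraction and are preserved as-is.
    """

    well_id: str
    condition: Condition
    time: np.ndarray
    od610: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od610 = np.asarray(self.od610, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = self.time.size
        if self.od610.size != n:
            raise PlateValidationError(
                f"well {self.well_id}: od610 length {self.od610.size} != time length {n}"
            )
        for name, series in self.channels.items():
            if series.size != n:
                raise PlateValidationError(
                    f"well {self.well_id}: channel {name!r} length {series.size} != {n}"
                )
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise PlateValidationError(f"well {self.well_id}: time is not strictly increasing")
        if np.any(self.od610 < 0):
            raise PlateValidationError(f"well {self.well_id}: negative OD610 values")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def channel(self, name: str) -> np.ndarray:
        if name == OD_CHANNEL:
            return self.od610
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"well {self.well_id} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None

    def with_channel(self, name: str, values: np.ndarray) -> "PlateWell":
        """Return a copy with ``name`` replaced by ``values``."""
        channels = dict(self.channels)
        channels[name] = np.asarray(values, dtype=float)
        return replace(self, channels=channels)


@dataclass
class AutofluorModel:
    """Autofluorescence as a function of OD for one medium.

    Piecewise-linear interpolation through reference points measured on a
    non-fluorescent strain, clamped to the end values outside the fitted
    OD range. Predictions are floored at zero (fluorescence backgrounds
    are physical intensities).
    """

    od_grid: np.ndarray
    rfu: np.ndarray
    medium: str = "unknown"

    def __post_init__(self) -> None:
        self.od_grid = np.asarray(self.od_grid, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.od_grid.size != self.rfu.size:
            raise PlateValidationError("autofluorescence grids have different lengths")
        if self.od_grid.size == 0:
            raise PlateValidationError("autofluorescence model needs at least one point")
        if self.od_grid.size > 1 and not np.all(np.diff(self.od_grid) > 0):
            raise PlateValidationError("autofluorescence OD grid must be strictly increasing")

    def predict(self, od: np.ndarray) -> np.ndarray:
        """Background RFU at the given OD values (clamped, non-negative)."""
        return np.clip(np.interp(np.asarray(od, dtype=float), self.od_grid, self.rfu), 0.0, None)

    @classmethod
    def zero(cls, medium: str = "unknown") -> "AutofluorModel":
        return cls(od_grid=np.array([0.0]), rfu=np.array([0.0]), medium=medium)

    @classmethod
    def from_blank_wells(
        cls, wells: Iterable[PlateWell], channel: str, medium: str = "unknown"
    ) -> "AutofluorModel":
        """Fit the model from one or more non-fluorescent-strain wells.

        Points are pooled, sorted by OD, and duplicate OD values averaged
        so that the interpolation grid is strictly increasing.
        """
        ods, rfus = [], []
        for w in wells:
            ods.append(w.od610)
            rfus.append(w.channel(channel))
        if not ods:
            raise PlateValidationError("no blank wells supplied")
        od = np.concatenate(ods)
        rfu = np.concatenate(rfus)
        grid, inverse = np.unique(od, return_inverse=True)
        mean_rfu = np.bincount(inverse, weights=rfu) / np.bincount(inverse)
        return cls(od_grid=grid, rfu=mean_rfu, medium=medium)


def subtract_autofluorescence(
    well: PlateWell, model: AutofluorModel, channel: str
) -> PlateWell:
    """Subtract the OD-matched background from one fluorescence channel.

    The operation is linear in the channel: adding ``model.predict(od)``
    back restores the input exactly. Negative residuals (measurement
    noise around zero signal) are preserved, not clipped.
    """
    values = well.channel(channel)  # raises KeyError for unknown channels
    return well.with_channel(channel, values - model.predict(well.od610))


# ---------------------------------------------------------------------------
# CSV layouts


def _wells_to_long(wells: Iterable[PlateWell]) -> pd.DataFrame:
    rows = []
    for w in wells:
        rows.append(
            pd.DataFrame(
                {"time_min": w.time, "well_id": w.well_id, "channel": OD_CHANNEL, "value": w.od610}
            )
        )
        for name, series in w.channels.items():
            rows.append(
                pd.DataFrame(
                    {"time_min": w.time, "well_id": w.well_id, "channel": name, "value": series}
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_plate_table(wells: Iterable[PlateWell], path: str | Path, layout: str = "long") -> None:
    """Write wells to CSV in ``wide`` or ``long`` layout.

    Floats are serialized with 17 significant digits so that a
    write/read roundtrip reproduces the binary values exactly.
    """
    wells = list(wells)
    if layout == "long":
        _wells_to_long(wells).to_csv(path, index=False, float_format="%.17g")
    elif layout == "wide":
        if not wells:
            raise ValueError("no wells to write")
        time = wells[0].time
        data: dict[str, np.ndarray] = {"time_min": time}
        for w in wells:
            if w.time.shape != time.shape or not np.array_equal(w.time, time):
                raise PlateValidationError(
                    "wide layout requires all wells to share one time grid"
                )
            data[f"{w.well_id}_{OD_CHANNEL}"] = w.od610
            for name, series in w.channels.items():
                data[f"{w.well_id}_{name}"] = series
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_condition_table(path: str | Path) -> dict[str, Condition]:
    """Read a metadata CSV with columns well_id, strain, medium, cm_um."""
    df = pd.read_csv(path)
    required = {"well_id", "strain", "medium", "cm_um"}
    missing = required - set(df.columns)
    if missing:
        raise PlateParseError(f"metadata table lacks columns {sorted(missing)}")
    return {
        str(row.well_id): Condition(
            medium=str(row.medium), cm_um=float(row.cm_um), strain=str(row.strain)
        )
        for row in df.itertuples()
    }


def write_condition_table(conditions: Mapping[str, Condition], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"well_id": wid, "strain": c.strain, "medium": c.medium, "cm_um": c.cm_um}
            for wid, c in conditions.items()
        ]
    ).to_csv(path, index=False)


def _resolve_metadata(
    metadata: str | Path | pd.DataFrame | Mapping[str, Condition] | None,
) -> dict[str, Condition]:
    if metadata is None:
        return {}
    if isinstance(metadata, Mapping):
        return dict(metadata)
    if isinstance(metadata, pd.DataFrame):
        import io

        buf = io.StringIO()
        metadata.to_csv(buf, index=False)
        buf.seek(0)
        return read_condition_table(buf)  # type: ignore[arg-type]
    return read_condition_table(metadata)


def _condition_for(well_id: str, meta: Mapping[str, Condition]) -> Condition:
    if well_id in meta:
        return meta[well_id]
    warnings.warn(
        f"well {well_id!r} missing from metadata; condition set to unknown", stacklevel=3
    )
    return Condition(medium="unknown", cm_um=0.0, strain="")


def read_plate_table(
    path: str | Path,
    layout: str = "wide",
    metadata: str | Path | pd.DataFrame | Mapping[str, Condition] | None = None,
) -> list[PlateWell]:
    """Read a plate CSV into a list of :class:`PlateWell`.

    Parameters
    ----------
    path : path
        CSV file in the requested layout.
    layout : {"wide", "long"}
        Wide tables need a first column ``time_min`` and per-well
        columns ``<well>_<channel>``; long tables need columns
        ``time_min, well_id, channel, value``.
    metadata : optional
        Condition table (path, DataFrame, or ``{well_id: Condition}``).
        Wells absent from it are flagged with a warning and read with an
        unknown condition.
    """
    meta = _resolve_metadata(metadata)
    df = pd.read_csv(path, float_precision="round_trip")

    if layout == "wide":
        if df.columns.size == 0 or df.columns[0] != "time_min":
            raise PlateParseError("wide plate CSV must start with a 'time_min' column")
        time = df["time_min"].to_numpy(dtype=float)
        per_well: dict[str, dict[str, np.ndarray]] = {}
        for col in df.columns[1:]:
            well_id, sep, chan = str(col).rpartition("_")
            if not sep or not well_id:
                raise PlateParseError(
                    f"column {col!r} is not of the form '<well>_<channel>'"
                )
            per_well.setdefault(well_id, {})[chan] = df[col].to_numpy(dtype=float)
        wells = []
        for well_id, chans in per_well.items():
            if OD_CHANNEL not in chans:
                raise PlateParseError(f"well {well_id!r} has no {OD_CHANNEL} column")
            od = chans.pop(OD_CHANNEL)
            wells.append(
                PlateWell(
                    well_id=well_id,
                    condition=_condition_for(well_id, meta),
                    time=time,
                    od610=od,
                    channels=chans,
                )
            )
        return wells

    if layout == "long":
        required = {"time_min", "well_id", "channel", "value"}
        missing = required - set(df.columns)
        if missing:
            raise PlateParseError(f"long plate CSV lacks columns {sorted(missing)}")
        wells = []
        for well_id, group in df.groupby("well_id", sort=False):
            wide = group.pivot_table(
                index="time_min", columns="channel", values="value", sort=True
            )
            if OD_CHANNEL not in wide.columns:
                raise PlateParseError(f"well {well_id!r} has no {OD_CHANNEL} series")
            chans = {
                str(c): wide[c].to_numpy(dtype=float)
                for c in wide.columns
                if c != OD_CHANNEL
            }
            wells.append(
                PlateWell(
                    well_id=str(well_id),
                    condition=_condition_for(str(well_id), meta),
                    time=wide.index.to_numpy(dtype=float),
                    od610=wide[OD_CHANNEL].to_numpy(dtype=float),
                    channels=chans,
                )
            )
        return wells

    raise ValueError(f"unknown layout {layout!r}")
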