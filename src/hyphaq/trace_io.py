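"""Data model and TSV I/O for hyphal traces, intensity profiles and ring profiles.

The measurements this package works on are one-dimensional: a time series of
hyphal length (one value per 15-min frame) and, per frame and fluorescence
channel, an intensity profile sampled along a line laid down the hypha.
Ring-circumference profiles are the analogous 1-D measurement taken around
the circumference of a single Z-ring.  Everything is stored long-format in
plain TSV so that cohorts can be produced either by microscopy-software
export or by :mod:`hyphaq.synthgen`.

File schemas (tab-delimited, UTF-8, ``.`` decimal separator, header row
mandatory):

``traces.tsv``
    ``strain  hypha_id  frame  time_min  length_um``
``profiles.tsv``
    ``hypha_id  frame  channel  position_um  intensity_au  background_au``
``rings.tsv``
    ``strain  ring_id  arc_position_um  intensity_au``
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "IntensityProfile",
    "FrameRecord",
    "HyphaTrace",
    "RingProfile",
    "SchemaError",
    "ValidationError",
    "ReferenceError_",
    "read_cohort",
    "write_cohort",
    "read_ring_profiles",
    "write_ring_profiles",
]

#: Default frame interval of the time-lapse acquisition, minutes.
DEFAULT_FRAME_INTERVAL_MIN = 15.0

#: Largest tolerated frame-to-frame length decrease (measurement noise), µm.
DEFAULT_LENGTH_DECREASE_TOL_UM = 1.0

_TRACE_COLUMNS = ["strain", "hypha_id", "frame", "time_min", "length_um"]
_PROFILE_COLUMNS = [
    "hypha_id",
    "frame",
    "channel",
    "position_um",
    "intensity_au",
    "background_au",
]
_RING_COLUMNS = ["strain", "ring_id", "arc_position_um", "intensity_au"]

#: Minimum number of circumference samples for a usable ring profile.
MIN_RING_SAMPLES = 16


class SchemaError(ValueError):
    """A TSV file does not have the expected columns."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class ReferenceError_(ValueError):
    """Profiles refer to hypha ids absent from the trace table."""


class Channel(str, enum.Enum):
    """Fluorescence channels.  Closed set; unknown channels are rejected."""

    FTSZ = "FTSZ"
    PARA = "PARA"
    DNA = "DNA"

    @classmethod
    def parse(cls, name: str) -> "Channel":
        try:
            return cls(str(name).upper())
        except ValueError:
            raise ValidationError(f"unknown channel {name!r}; expected one of "
                                  f"{[c.value for c in cls]}") from None


@dataclass
class IntensityProfile:
    """Fluorescence sampled along a line (hypha axis), arbitrary units.

    ``background_au`` is the matched background level; it is stored separately
    so that raw values are preserved and background subtraction happens in the
    analysis code.
    """

    channel: Channel
    positions_um: np.ndarray
    intensities_au: np.ndarray
    background_au: float = 0.0

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)

    def validate(self, length_um: float | None = None, where: str = "") -> None:
        p, v = self.positions_um, self.intensities_au
        if p.shape != v.shape or p.ndim != 1:
            raise ValidationError(f"{where}: positions/intensities shape mismatch")
        if p.size and np.any(np.diff(p) <= 0):
            raise ValidationError(f"{where}: profile positions not strictly ascending")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{where}: non-finite intensities")
        if self.background_au < 0:
            raise ValidationError(f"{where}: negative background")
        if length_um is not None and p.size and (p[0] < -1e-9 or p[-1] > length_um + 1e-9):
            raise ValidationError(
                f"{where}: profile positions outside [0, {length_um}] µm")


@dataclass
class FrameRecord:
    """One time point of one hypha."""

    frame_index: int
    time_min: float
    length_um: float
    profiles: dict[Channel, IntensityProfile] = field(default_factory=dict)


@dataclass
class HyphaTrace:
    """One hypha's full time series, t = 0 at branch emergence."""

    hypha_id: str
    strain: str
    frames: list[FrameRecord] = field(default_factory=list)

    @property
    def times_min(self) -> np.ndarray:
        return np.array([f.time_min for f in self.frames], dtype=float)

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([f.length_um for f in self.frames], dtype=float)

    @property
    def frame_interval_min(self) -> float:
        t = self.times_min
        if t.size < 2:
            return DEFAULT_FRAME_INTERVAL_MIN
        return float(t[1] - t[0])

    def validate(self, length_tol_um: float = DEFAULT_LENGTH_DECREASE_TOL_UM) -> None:
        """Check the trace invariants; raise :class:`ValidationError` naming
        the hypha on the first violation."""
        hid = self.hypha_id
        t = self.times_min
        if t.size == 0:
            raise ValidationError(f"hypha {hid}: empty trace")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"hypha {hid}: frame times not strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            raise ValidationError(f"hypha {hid}: frame interval not constant")
        lengths = self.lengths_um
        if np.any(lengths < 0):
            raise ValidationError(f"hypha {hid}: negative length")
        if lengths.size > 1 and np.any(np.diff(lengths) < -length_tol_um):
            raise ValidationError(
                f"hypha {hid}: length decrease exceeds tolerance {length_tol_um} µm")
        for fr in self.frames:
            for ch, prof in fr.profiles.items():
                prof.validate(length_um=fr.length_um,
                              where=f"hypha {hid} frame {fr.frame_index} {ch.value}")


@dataclass
class RingProfile:
    """Fluorescence around the circumference of one Z-ring.

    Arc positions are circular: the last sample is adjacent to the first.
    """

    ring_id: str
    strain: str
    arc_positions_um: np.ndarray
    intensities_au: np.ndarray

    def __post_init__(self) -> None:
        self.arc_positions_um = np.asarray(self.arc_positions_um, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)

    def validate(self) -> None:
        p, v = self.arc_positions_um, self.intensities_au
        if p.shape != v.shape or p.ndim != 1:
            raise ValidationError(f"ring {self.ring_id}: shape mismatch")
        if p.size < MIN_RING_SAMPLES:
            raise ValidationError(
                f"ring {self.ring_id}: {p.size} samples < minimum {MIN_RING_SAMPLES}")
        if np.any(np.diff(p) <= 0):
            raise ValidationError(f"ring {self.ring_id}: arc positions not ascending")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"ring {self.ring_id}: non-finite intensities")


Cohort = dict[str, list[HyphaTrace]]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"hypha_id": str, "strain": str})


def read_cohort(trace_path, profile_path=None,
                length_tol_um: float = DEFAULT_LENGTH_DECREASE_TOL_UM) -> Cohort:
    """Read traces (and optionally profiles) into a strain → traces mapping.

    Raises
    ------
    SchemaError
        if a file lacks required columns.
    ValidationError
        if any trace violates an invariant (the offending hypha is named).
    ReferenceError_
        if the profile table refers to hypha ids not present in the traces.
    """
    tdf = _read_tsv(trace_path)
    _require_columns(tdf, _TRACE_COLUMNS, trace_path)

    profiles_by_hypha: dict[str, pd.DataFrame] = {}
    if profile_path is not None:
        pdf = _read_tsv(profile_path)
        _require_columns(pdf, _PROFILE_COLUMNS, profile_path)
        known = set(tdf["hypha_id"].astype(str))
        unknown = set(pdf["hypha_id"].astype(str)) - known
        if unknown:
            raise ReferenceError_(
                f"{profile_path}: profiles for unknown hypha ids {sorted(unknown)}")
        profiles_by_hypha = {hid: g for hid, g in pdf.groupby("hypha_id", sort=False)}

    cohort: Cohort = {}
    for (strain, hid), g in tdf.groupby(["strain", "hypha_id"], sort=False):
        g = g.sort_values("frame")
        frames = [
            FrameRecord(frame_index=int(r.frame), time_min=float(r.time_min),
                        length_um=float(r.length_um))
            for r in g.itertuples()
        ]
        trace = HyphaTrace(hypha_id=str(hid), strain=str(strain), frames=frames)
        by_index = {f.frame_index: f for f in trace.frames}
        pg = profiles_by_hypha.get(str(hid))
        if pg is not None:
            for (fr, ch), block in pg.groupby(["frame", "channel"], sort=False):
                fr = int(fr)
                if fr not in by_index:
                    raise ReferenceError_(
                        f"hypha {hid}: profile at frame {fr} has no trace row")
                channel = Channel.parse(ch)
                block = block.sort_values("position_um")
                by_index[fr].profiles[channel] = IntensityProfile(
                    channel=channel,
                    positions_um=block["position_um"].to_numpy(),
                    intensities_au=block["intensity_au"].to_numpy(),
                    background_au=float(block["background_au"].iloc[0]),
                )
        trace.validate(length_tol_um=length_tol_um)
        cohort.setdefault(str(strain), []).append(trace)
    return cohort


_FLOAT_FMT = "%.12g"


def write_cohort(cohort: Cohort, trace_path, profile_path=None) -> None:
    """Write a cohort back to the TSV schemas (inverse of :func:`read_cohort`)."""
    trows = []
    prows = []
    for strain in cohort:
        for trace in cohort[strain]:
            for fr in trace.frames:
                trows.append((strain, trace.hypha_id, fr.frame_index,
                              fr.time_min, fr.length_um))
                for ch in sorted(fr.profiles, key=lambda c: c.value):
                    prof = fr.profiles[ch]
                    for pos, val in zip(prof.positions_um, prof.intensities_au):
                        prows.append((trace.hypha_id, fr.frame_index, ch.value,
                                      pos, val, prof.background_au))
    tdf = pd.DataFrame(trows, columns=_TRACE_COLUMNS)
    Path(trace_path).parent.mkdir(parents=True, exist_ok=True)
    tdf.to_csv(trace_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if profile_path is not None:
        pdf = pd.DataFrame(prows, columns=_PROFILE_COLUMNS)
        pdf.to_csv(profile_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ring_profiles(path) -> list[RingProfile]:
    """Read ring-circumference profiles from ``rings.tsv``."""
    df = _read_tsv(path)
    _require_columns(df, _RING_COLUMNS, path)
    rings = []
    for (strain, rid), g in df.groupby(["strain", "ring_id"], sort=False):
        g = g.sort_values("arc_position_um")
        ring = RingProfile(ring_id=str(rid), strain=str(strain),
                           arc_positions_um=g["arc_position_um"].to_numpy(),
                           intensities_au=g["intensity_au"].to_numpy())
        ring.validate()
        rings.append(ring)
    return rings


def write_ring_profiles(rings: list[RingProfile], path) -> None:
    rows = [
        (r.strain, r.ring_id, pos, val)
        for r in rings
        for pos, val in zip(r.arc_positions_um, r.intensities_au)
    ]
    df = pd.DataFrame(rows, columns=_RING_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
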