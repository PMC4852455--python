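"""Growth kinetics and fluorescence-rise event detection.

The timing backbone of the analysis: every event offset is reported relative
to growth cessation, with the sign convention *negative = before cessation*.

Growth cessation is found with a continuous two-segment least-squares fit —
linear with non-negative slope up to a breakpoint, constant after it —
searched exhaustively over all candidate breakpoint frames.  The extension
rate is the ordinary least-squares slope of length vs time over the growth
segment (reported in µm/h).  Fluorescence rises are detected with a relative
threshold rule: the first frame whose background-subtracted mean intensity
exceeds the trailing-window baseline by more than ``rel_threshold`` (default
10%), sustained for ``persistence`` consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_io import Channel, HyphaTrace

__all__ = [
    "GrowthFit",
    "RiseEvent",
    "EventTiming",
    "detect_cessation",
    "fit_growth",
    "growth_rate",
    "mean_intensity_series",
    "detect_rise",
    "event_offsets",
]


@dataclass(frozen=True)
class GrowthFit:
    """Two-segment growth fit for one hypha."""

    rate_um_per_h: float
    cessation_time_min: float
    final_length_um: float
    cessation_frame: int
    sse: float

    @property
    def extension_time_min(self) -> float:
        # t = 0 at branch emergence, so extension time equals cessation time
        return self.cessation_time_min


@dataclass(frozen=True)
class RiseEvent:
    """First frame at which a channel's fluorescence rise is detected."""

    channel: Channel
    time_min: float
    frame_index: int


def detect_cessation(trace: HyphaTrace, min_plateau_frames: int = 3
                     ) -> tuple[int, float]:
    """Locate the growth-cessation frame of a hypha.

    Fits, for every candidate breakpoint ``b``, the continuous model
    ``length(t) = a + s·min(t, t_b)`` with slope ``s ≥ 0`` (linear growth up
    to frame ``b``, constant plateau after), and returns the breakpoint
    minimising the total squared error, with at least ``min_plateau_frames``
    frames after it.  Ties break toward the earliest frame.  An all-constant
    trace yields frame 0.

    Returns ``(cessation_frame, sse)``.
    """
    t = trace.times_min
    y = trace.lengths_um
    n = t.size
    if n < 6:
        raise ValueError(f"hypha {trace.hypha_id}: need >= 6 frames, got {n}")
    if min_plateau_frames < 1:
        raise ValueError("min_plateau_frames must be >= 1")
    best_b, best_sse = 0, np.inf
    for b in range(0, n - min_plateau_frames):
        _, _, sse = _two_segment_fit(t, y, b)
        if sse < best_sse - 1e-12:
            best_b, best_sse = b, sse
    return best_b, float(best_sse)


def _two_segment_fit(t: np.ndarray, y: np.ndarray, b: int
                     ) -> tuple[float, float, float]:
    """Least-squares ``(intercept, slope, sse)`` of ``y = a + s·min(t, t[b])``
    with ``s`` clamped to be non-negative."""
    x = np.minimum(t, t[b])
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx <= 0:
        s = 0.0
    else:
        s = float(((x - xm) * (y - ym)).sum() / sxx)
        if s < 0:
            s = 0.0
    a = ym - s * xm
    r = y - (a + s * x)
    return a, s, float((r ** 2).sum())


def growth_rate(trace: HyphaTrace, cessation_frame: int) -> float:
    """OLS slope of length vs time over frames ``[0, cessation_frame]``,
    in µm/h."""
    if cessation_frame < 2:
        raise ValueError("cessation_frame must be >= 2 to fit a slope")
    t = trace.times_min[: cessation_frame + 1]
    y = trace.lengths_um[: cessation_frame + 1]
    sxx = float(((t - t.mean()) ** 2).sum())
    if sxx <= 0:
        raise ValueError("degenerate trace: all times equal")
    slope_per_min = float(((t - t.mean()) * (y - y.mean())).sum() / sxx)
    return slope_per_min * 60.0


def fit_growth(trace: HyphaTrace, min_plateau_frames: int = 3) -> GrowthFit:
    """Convenience wrapper: cessation detection + rate + final length.

    A cessation at frame 0 or 1 (no growth segment to regress on) is
    reported with rate 0.
    """
    b, sse = detect_cessation(trace, min_plateau_frames=min_plateau_frames)
    rate = growth_rate(trace, b) if b >= 2 else 0.0
    final_len = float(np.median(trace.lengths_um[b:]))
    return GrowthFit(rate_um_per_h=max(rate, 0.0),
                     cessation_time_min=float(trace.times_min[b]),
                     final_length_um=max(final_len, 0.0),
                     cessation_frame=b, sse=sse)


def mean_intensity_series(trace: HyphaTrace, channel: Channel | str
                          ) -> pd.Series:
    """Per-frame mean background-subtracted intensity of one channel.

    Frames lacking the channel (or with an empty profile) are gaps (NaN),
    not zeros.  The series is indexed by frame time in minutes.
    """
    channel = Channel.parse(channel) if not isinstance(channel, Channel) else channel
    times, values = [], []
    seen = False
    for fr in trace.frames:
        prof = fr.profiles.get(channel)
        times.append(fr.time_min)
        if prof is None or prof.intensities_au.size == 0:
            values.append(np.nan)
        else:
            seen = True
            values.append(float(prof.intensities_au.mean() - prof.background_au))
    if not seen:
        raise ValueError(
            f"hypha {trace.hypha_id}: channel {channel.value} absent from all frames")
    return pd.Series(values, index=pd.Index(times, name="time_min"),
                     name=channel.value)


def detect_rise(series: pd.Series, rel_threshold: float = 0.10,
                window: int = 4, persistence: int = 2,
                channel: Channel | None = None) -> RiseEvent | None:
    """Detect the first sustained fluorescence rise in a per-frame series.

    Returns the first frame ``t`` such that, for ``persistence`` consecutive
    frames starting at ``t``, the value exceeds ``(1 + rel_threshold)`` times
    the mean of the ``window`` frames preceding each frame.  ``None`` if the
    rule never fires.

    Raises
    ------
    ValueError
        if the series is too short, or a needed baseline mean is not
        positive (relative thresholds are undefined on a ≤ 0 baseline).
    """
    v = series.to_numpy(dtype=float)
    n = v.size
    if n < window + persistence:
        raise ValueError(f"need >= {window + persistence} frames, got {n}")
    ok = np.zeros(n, dtype=bool)
    for i in range(window, n):
        base = v[i - window: i]
        if np.isnan(base).any() or np.isnan(v[i]):
            continue
        m = base.mean()
        if m <= 0:
            raise ValueError(
                f"baseline mean {m:.3g} <= 0 at frame {i}: undefined baseline")
        ok[i] = v[i] > (1.0 + rel_threshold) * m
    for i in range(window, n - persistence + 1):
        if ok[i: i + persistence].all():
            return RiseEvent(channel=channel or Channel.FTSZ,
                             time_min=float(series.index[i]), frame_index=i)
    return None


@dataclass(frozen=True)
class EventTiming:
    """Event times of one hypha and their offsets vs growth cessation.

    All absolute times are minutes since branch emergence; offsets are
    signed, negative = before cessation.  Derived durations satisfy their
    defining identities exactly.
    """

    cessation_time_min: float
    t_ftsz_rise: float | None
    t_ring_appear: float | None
    t_ring_disappear: float | None
    t_spore_sep: float | None

    def __post_init__(self) -> None:
        a, d, s = self.t_ring_appear, self.t_ring_disappear, self.t_spore_sep
        if a is not None and d is not None and d < a:
            raise ValueError("ring disappearance precedes appearance")
        if d is not None and s is not None and s < d:
            raise ValueError("spore separation precedes ring disappearance")

    def _off(self, t: float | None) -> float | None:
        return None if t is None else t - self.cessation_time_min

    @property
    def ftsz_rise_offset_min(self) -> float | None:
        return self._off(self.t_ftsz_rise)

    @property
    def ring_appear_offset_min(self) -> float | None:
        return self._off(self.t_ring_appear)

    @property
    def ring_lifetime_min(self) -> float | None:
        if self.t_ring_appear is None or self.t_ring_disappear is None:
            return None
        return self.t_ring_disappear - self.t_ring_appear

    @property
    def maturation_min(self) -> float | None:
        if self.t_ring_disappear is None or self.t_spore_sep is None:
            return None
        return self.t_spore_sep - self.t_ring_disappear

    @property
    def total_sporulation_min(self) -> float | None:
        return self._off(self.t_spore_sep)

    @property
    def total_differentiation_min(self) -> float | None:
        return self.t_spore_sep


def event_offsets(trace: HyphaTrace, fit: GrowthFit,
                  rise: RiseEvent | None,
                  ring_interval: tuple[float | None, float | None],
                  t_spore_sep: float | None) -> EventTiming:
    """Assemble the per-hypha event timing record.

    ``ring_interval`` is ``(t_appear, t_disappear)`` from
    :func:`hyphaq.rings.ring_interval`; ``t_spore_sep`` is the observed spore
    separation time (supplied by the experimenter or the generator truth —
    no fluorescence channel marks it directly).
    """
    t_appear, t_gone = ring_interval
    return EventTiming(
        cessation_time_min=fit.cessation_time_min,
        t_ftsz_rise=None if rise is None else rise.time_min,
        t_ring_appear=t_appear,
        t_ring_disappear=t_gone,
        t_spore_sep=t_spore_sep,
    )
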