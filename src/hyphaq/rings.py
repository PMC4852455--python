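"""Z-ring ladder analysis along hyphae and ring-circumference uniformity.

Two views of the same structures: along the hypha, a ladder of regularly
spaced Z-rings shows up as peaks in the FtsZ fluorescence profile; around a
single ring (super-resolution data), the circumferential intensity profile
reveals whether the ring is uniform or broken.

Ladder statistics follow the field convention of summarising ring
fluorescence as the mean of the seven highest profile peaks.  Broken rings
are operationalised as a contiguous circular arc of at least
``min_arc_fraction`` of the circumference whose (mean-scaled) intensity
falls below ``low_level`` × the ring median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .trace_io import Channel, HyphaTrace, IntensityProfile, RingProfile

__all__ = [
    "PeakSet",
    "LadderMetrics",
    "UniformityMetrics",
    "GroupComparison",
    "find_ring_peaks",
    "ladder_intensity",
    "ring_interval",
    "ring_spacings",
    "ladder_metrics",
    "circumference_metrics",
    "compare_uniformity",
]


@dataclass(frozen=True)
class PeakSet:
    """Qualifying ring peaks of one profile (background-subtracted units)."""

    frame_index: int
    positions_um: np.ndarray
    heights_au: np.ndarray
    prominences_au: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(self.positions_um.size)


@dataclass(frozen=True)
class LadderMetrics:
    """Summary of one ladder: top-7 peak intensity and spacing statistics."""

    top7_mean_au: float          # NaN if no peaks (flagged undefined)
    n_peaks: int
    spacings_um: np.ndarray
    spacing_cv: float            # NaN if < 2 spacings


def find_ring_peaks(profile: IntensityProfile,
                    min_prominence_rel: float = 0.5,
                    min_separation_um: float = 0.5) -> PeakSet:
    """Detect qualifying ring peaks in a background-subtracted profile.

    Local maxima with prominence at least ``min_prominence_rel`` times the
    background-subtracted profile mean, thinned greedily so that any two
    kept peaks are at least ``min_separation_um`` apart (higher peak wins,
    ties go to the leftmost).  An empty peak set is a valid result.
    """
    x = profile.positions_um
    v = profile.intensities_au - profile.background_au
    if v.size < 5:
        raise ValueError("need >= 5 samples for peak detection")
    thr = max(min_prominence_rel * float(v.mean()), 0.0)
    idx, props = signal.find_peaks(v, prominence=max(thr, 1e-12))
    prom = props["prominences"]
    # greedy separation filter: descending height, leftmost on ties
    order = sorted(range(idx.size), key=lambda k: (-v[idx[k]], x[idx[k]]))
    kept: list[int] = []
    for k in order:
        if all(abs(x[idx[k]] - x[idx[j]]) >= min_separation_um for j in kept):
            kept.append(k)
    kept.sort(key=lambda k: x[idx[k]])
    return PeakSet(frame_index=-1,
                   positions_um=x[idx[kept]].astype(float) if kept else np.empty(0),
                   heights_au=v[idx[kept]].astype(float) if kept else np.empty(0),
                   prominences_au=prom[kept].astype(float) if kept else np.empty(0))


def ladder_intensity(peaks: PeakSet) -> float:
    """Mean of the seven highest peak heights (all of them if fewer than 7);
    NaN when the peak set is empty."""
    h = np.sort(peaks.heights_au)[::-1]
    if h.size == 0:
        return float("nan")
    return float(h[:7].mean())


def ring_spacings(peaks: PeakSet) -> tuple[np.ndarray, float]:
    """Adjacent-peak distances and their coefficient of variation
    (sample sd / mean; NaN with fewer than 2 spacings)."""
    d = np.diff(peaks.positions_um)
    if d.size == 0:
        return d, float("nan")
    if d.size == 1:
        return d, 0.0
    return d, float(d.std(ddof=1) / d.mean())


def ladder_metrics(peaks: PeakSet) -> LadderMetrics:
    d, cv = ring_spacings(peaks)
    return LadderMetrics(top7_mean_au=ladder_intensity(peaks),
                         n_peaks=peaks.n_peaks, spacings_um=d, spacing_cv=cv)


def ring_interval(trace: HyphaTrace, channel: Channel | str = Channel.FTSZ,
                  min_rings: int = 3, persistence: int = 2,
                  min_prominence_rel: float = 0.5,
                  min_separation_um: float = 0.5
                  ) -> tuple[float | None, float | None]:
    """Time window during which a Z-ring ladder is detectable.

    ``t_appear`` is the first frame with at least ``min_rings`` qualifying
    peaks sustained for ``persistence`` consecutive frames; ``t_disappear``
    is the first later frame where the count drops below ``min_rings`` and
    stays below for ``persistence`` frames.  Either may be ``None``.
    """
    channel = Channel.parse(channel) if not isinstance(channel, Channel) else channel
    times, counts = [], []
    for fr in trace.frames:
        prof = fr.profiles.get(channel)
        times.append(fr.time_min)
        if prof is None or prof.intensities_au.size < 5:
            counts.append(0)
        else:
            counts.append(find_ring_peaks(
                prof, min_prominence_rel=min_prominence_rel,
                min_separation_um=min_separation_um).n_peaks)
    c = np.asarray(counts)
    n = c.size
    t_appear = None
    start = None
    for i in range(0, n - persistence + 1):
        if (c[i: i + persistence] >= min_rings).all():
            t_appear, start = times[i], i
            break
    if t_appear is None:
        return None, None
    for i in range(start + 1, n):
        seg = c[i: i + persistence]
        if seg.size == persistence and (seg < min_rings).all():
            return t_appear, times[i]
    return t_appear, None


@dataclass(frozen=True)
class UniformityMetrics:
    """Uniformity of one ring's circumferential intensity profile."""

    ring_id: str
    scaled_variance: float       # variance after scaling the ring mean to 1
    broken: bool
    longest_low_arc_fraction: float
    n_samples: int


@dataclass(frozen=True)
class GroupComparison:
    """Group-level uniformity contrast (e.g. a mutant vs wild type)."""

    variance_ratio: float        # mean scaled variance A / B; inf flagged
    f_statistic: float
    p_value: float
    df_a: int
    df_b: int
    broken_fraction_a: float
    broken_fraction_b: float
    n_a: int
    n_b: int


def circumference_metrics(ring: RingProfile, low_level: float = 0.25,
                          min_arc_fraction: float = 0.10) -> UniformityMetrics:
    """Scaled variance and broken-ring classification for one ring.

    Intensities are scaled so the ring mean is 1; the scaled variance is the
    sample variance of the scaled values.  The ring is *broken* if some
    contiguous circular arc of at least ``min_arc_fraction`` of the
    circumference lies below ``low_level`` × the scaled median.  Arc lengths
    are measured with per-sample segment weights, so non-uniform sampling is
    handled; wrap-around arcs count as contiguous.
    """
    v = ring.intensities_au.astype(float)
    m = v.mean()
    if m <= 0:
        raise ValueError(f"ring {ring.ring_id}: non-positive mean intensity")
    s = v / m
    var = float(s.var(ddof=1)) if s.size > 1 else 0.0
    med = float(np.median(s))
    low = s < low_level * med

    p = ring.arc_positions_um
    n = p.size
    # circumference closes the circle with one more median step
    step = float(np.median(np.diff(p))) if n > 1 else 1.0
    circumference = float(p[-1] - p[0]) + step
    gaps = np.diff(np.concatenate([p, [p[0] + circumference]]))
    w = 0.5 * (gaps + np.roll(gaps, 1))          # segment length per sample

    frac = _longest_circular_run(low, w) / circumference
    return UniformityMetrics(ring_id=ring.ring_id, scaled_variance=var,
                             broken=frac >= min_arc_fraction,
                             longest_low_arc_fraction=float(frac),
                             n_samples=n)


def _longest_circular_run(mask: np.ndarray, weights: np.ndarray) -> float:
    """Total weight of the longest circular run of True values."""
    if not mask.any():
        return 0.0
    if mask.all():
        return float(weights.sum())
    # rotate so the sequence starts on a False; runs are then linear
    start = int(np.argmin(mask))
    m = np.roll(mask, -start)
    w = np.roll(weights, -start)
    best = cur = 0.0
    for flag, wt in zip(m, w):
        cur = cur + wt if flag else 0.0
        best = max(best, cur)
    return float(best)


def compare_uniformity(group_a: list[UniformityMetrics],
                       group_b: list[UniformityMetrics]) -> GroupComparison:
    """F-test contrast of ring uniformity between two groups.

    The variance ratio is the ratio of mean scaled variances; the F statistic
    uses the pooled scaled-intensity residual variances with degrees of
    freedom summed over rings, and a two-sided p-value.  A zero-variance
    denominator yields an infinite ratio (flagged, p = 0).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    va = np.array([u.scaled_variance for u in group_a])
    vb = np.array([u.scaled_variance for u in group_b])
    dfa = int(sum(u.n_samples - 1 for u in group_a))
    dfb = int(sum(u.n_samples - 1 for u in group_b))
    # pooled residual variance per group, weighted by per-ring df
    pa = float(sum((u.n_samples - 1) * u.scaled_variance for u in group_a) / dfa)
    pb = float(sum((u.n_samples - 1) * u.scaled_variance for u in group_b) / dfb)
    broken_a = float(np.mean([u.broken for u in group_a]))
    broken_b = float(np.mean([u.broken for u in group_b]))
    if vb.mean() == 0 or pb == 0:
        return GroupComparison(variance_ratio=float("inf"),
                               f_statistic=float("inf"), p_value=0.0,
                               df_a=dfa, df_b=dfb,
                               broken_fraction_a=broken_a,
                               broken_fraction_b=broken_b,
                               n_a=len(group_a), n_b=len(group_b))
    ratio = float(va.mean() / vb.mean())
    f = pa / pb
    sf = stats.f.sf(f, dfa, dfb)
    cdf = stats.f.cdf(f, dfa, dfb)
    p = float(min(2.0 * min(sf, cdf), 1.0))
    return GroupComparison(variance_ratio=ratio, f_statistic=float(f),
                           p_value=p, df_a=dfa, df_b=dfb,
                           broken_fraction_a=broken_a,
                           broken_fraction_b=broken_b,
                           n_a=len(group_a), n_b=len(group_b))
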