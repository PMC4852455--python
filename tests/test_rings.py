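"""Ladder peak detection, top-7 statistic, ring interval and uniformity."""

import numpy as np
import pytest
from scipy import stats

import hyphaq as hq
from hyphaq import rings as R
from hyphaq.trace_io import Channel, IntensityProfile, RingProfile


def make_profile(values, step=0.1, background=0.0):
    values = np.asarray(values, dtype=float)
    return IntensityProfile(channel=Channel.FTSZ,
                            positions_um=np.arange(values.size) * step,
                            intensities_au=values, background_au=background)


# ------------------------------------------------------- find_ring_peaks

def test_flat_profile_no_peaks():
    pk = hq.find_ring_peaks(make_profile(np.full(50, 10.0)))
    assert pk.n_peaks == 0


def test_two_gaussian_peaks_recovered_at_planted_positions():
    x = np.arange(0, 6, 0.1)
    v = 5.0 + 50 * np.exp(-(x - 2.0) ** 2 / (2 * 0.15 ** 2)) \
        + 50 * np.exp(-(x - 4.0) ** 2 / (2 * 0.15 ** 2))
    pk = hq.find_ring_peaks(make_profile(v))
    assert pk.n_peaks == 2
    np.testing.assert_allclose(pk.positions_um, [2.0, 4.0], atol=0.1)


def brute_force_peaks(x, v, min_prominence_rel, min_separation_um):
    """Independent local-maxima enumeration with textbook prominence."""
    thr = max(min_prominence_rel * v.mean(), 0.0)
    cands = []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            # base on each side: minimum between the peak and the first
            # strictly higher value (or the signal edge)
            bases = []
            for side in (v[:i][::-1], v[i + 1:]):
                base = v[i]
                for u in side:
                    if u > v[i]:
                        break
                    base = min(base, u)
                bases.append(base)
            prom = v[i] - max(bases)
            if prom >= max(thr, 1e-12):
                cands.append(i)
    kept = []
    for i in sorted(cands, key=lambda i: (-v[i], x[i])):
        if all(abs(x[i] - x[j]) >= min_separation_um for j in kept):
            kept.append(i)
    return sorted(x[i] for i in kept)


def test_peaks_match_brute_force_oracle_many_seeds():
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(40, 120))
        x = np.arange(n) * 0.1
        v = rng.uniform(1, 5) + rng.normal(0, 1, n) ** 2
        for _ in range(int(rng.integers(0, 6))):
            c = rng.uniform(0, x[-1])
            v += rng.uniform(2, 15) * np.exp(-(x - c) ** 2 / (2 * 0.15 ** 2))
        prof = make_profile(v)
        pk = hq.find_ring_peaks(prof)
        oracle = brute_force_peaks(x, v, 0.5, 0.5)
        np.testing.assert_allclose(sorted(pk.positions_um), oracle,
                                   atol=1e-12)


# ------------------------------------------------------ ladder statistics

@pytest.mark.parametrize("heights,expected", [
    (range(1, 8), 4.0),                 # 1..7 → 4
    (range(1, 11), 7.0),                # top 7 of 1..10 → (4+…+10)/7 = 7
    ([2, 4, 6], 4.0),                   # fewer than 7 → mean of all
])
def test_ladder_intensity_examples(heights, expected):
    h = np.asarray(list(heights), dtype=float)
    pk = R.PeakSet(frame_index=0, positions_um=np.arange(h.size) * 1.0,
                   heights_au=h, prominences_au=h)
    assert hq.ladder_intensity(pk) == pytest.approx(expected)


def test_ladder_intensity_empty_flagged_nan():
    pk = R.PeakSet(frame_index=0, positions_um=np.empty(0),
                   heights_au=np.empty(0), prominences_au=np.empty(0))
    assert np.isnan(hq.ladder_intensity(pk))


def test_ladder_intensity_permutation_invariant_and_monotone():
    rng = np.random.default_rng(2)
    h = rng.uniform(1, 10, 9)
    def stat(hs):
        return hq.ladder_intensity(R.PeakSet(
            frame_index=0, positions_um=np.arange(len(hs)) * 1.0,
            heights_au=np.asarray(hs, float),
            prominences_au=np.asarray(hs, float)))
    base = stat(h)
    assert stat(rng.permutation(h)) == pytest.approx(base)
    for i in range(h.size):
        raised = h.copy()
        raised[i] += 1.0
        assert stat(raised) >= base - 1e-12


def test_ring_spacings_examples():
    pk = R.PeakSet(frame_index=0, positions_um=np.array([0.0, 1.2, 2.4]),
                   heights_au=np.ones(3), prominences_au=np.ones(3))
    d, cv = hq.ring_spacings(pk)
    np.testing.assert_allclose(d, [1.2, 1.2])
    assert cv == pytest.approx(0.0)
    pk2 = R.PeakSet(frame_index=0, positions_um=np.array([0.0, 1.0, 3.0]),
                    heights_au=np.ones(3), prominences_au=np.ones(3))
    d2, cv2 = hq.ring_spacings(pk2)
    np.testing.assert_allclose(d2, [1.0, 2.0])
    assert cv2 == pytest.approx(np.std([1.0, 2.0], ddof=1) / 1.5)


def test_spacing_cv_larger_with_planted_jitter():
    """A TopA-like cohort (spacing jitter on) shows a larger spacing CV
    than the regular wild-type-like ladder."""
    import dataclasses
    wt = hq.STRAIN_DEFAULTS["WT"].zero_variance()
    jit = dataclasses.replace(wt, ring_spacing_cv=0.3)
    cvs = {}
    for name, p in (("wt", wt), ("jit", jit)):
        cohort, truth = hq.simulate_cohort({"WT": p}, 3, seed=21)
        vals = []
        for trace in cohort["WT"]:
            row = truth.hyphae[truth.hyphae.hypha_id == trace.hypha_id].iloc[0]
            k = int((row.t_ring_appear_min + 30) / 15)
            prof = trace.frames[k].profiles[Channel.FTSZ]
            _, cv = hq.ring_spacings(hq.find_ring_peaks(prof))
            vals.append(cv)
        cvs[name] = np.mean(vals)
    assert cvs["jit"] > cvs["wt"]


# ---------------------------------------------------------- ring_interval

def test_ring_interval_zero_variance_exact(wt_zero_cohort):
    cohort, truth = wt_zero_cohort
    trace = cohort["WT"][0]
    row = truth.hyphae.iloc[0]
    t_appear, t_gone = hq.ring_interval(trace)
    assert t_appear == row.t_ring_appear_min
    assert t_gone == row.t_ring_disappear_min


def test_ring_interval_no_peaks_is_none():
    wt = hq.STRAIN_DEFAULTS["WT"].zero_variance()
    cohort, _ = hq.simulate_cohort({"WT": wt}, 1, seed=1, channels=("PARA",))
    trace = cohort["WT"][0]
    # copy PARA (no rings) into FTSZ slots so profiles exist but are flat
    for fr in trace.frames:
        p = fr.profiles.pop(Channel.PARA)
        fr.profiles[Channel.FTSZ] = IntensityProfile(
            channel=Channel.FTSZ, positions_um=p.positions_um,
            intensities_au=p.intensities_au, background_au=p.background_au)
    assert hq.ring_interval(trace) == (None, None)


def test_single_frame_of_rings_fails_persistence(simple_trace):
    x = np.arange(0, 10, 0.1)
    ladder = 5.0 + 40 * sum(np.exp(-(x - c) ** 2 / 0.045)
                            for c in np.arange(0.6, 9.5, 1.2))
    flat = np.full_like(x, 5.0)
    for k, fr in enumerate(simple_trace.frames):
        v = ladder if k == 10 else flat
        fr.profiles[Channel.FTSZ] = IntensityProfile(
            channel=Channel.FTSZ, positions_um=x, intensities_au=v.copy(),
            background_au=0.0)
    assert hq.ring_interval(simple_trace, persistence=2) == (None, None)


# ------------------------------------------------- circumference metrics

def ring_from(values, circ=3.2):
    v = np.asarray(values, dtype=float)
    return RingProfile(ring_id="r", strain="s",
                       arc_positions_um=np.arange(v.size) * circ / v.size,
                       intensities_au=v)


def test_uniform_ring_zero_variance_not_broken():
    m = hq.circumference_metrics(ring_from(np.full(64, 7.0)))
    assert m.scaled_variance == pytest.approx(0.0)
    assert not m.broken


def test_contiguous_zero_arc_is_broken():
    v = np.full(60, 10.0)
    v[10:22] = 0.0  # 20% contiguous arc at zero
    m = hq.circumference_metrics(ring_from(v))
    assert m.broken
    assert m.longest_low_arc_fraction == pytest.approx(0.2, abs=0.02)


def test_broken_flag_rotation_invariant():
    rng = np.random.default_rng(8)
    v = np.full(64, 10.0) * (1 + 0.1 * rng.standard_normal(64))
    v[50:] = 0.2  # wrap-adjacent low arc
    v[:3] = 0.2   # extends across the origin
    flags = set()
    for shift in range(0, 64, 7):
        m = hq.circumference_metrics(ring_from(np.roll(v, shift)))
        flags.add(m.broken)
    assert flags == {True}


def test_scaled_variance_moment_oracle():
    """cv = 0.1 multiplicative noise → mean scaled variance ≈ 0.01."""
    rings, _ = hq.simulate_ring_profiles(500, 0.0, 0.1, seed=13)
    vs = [hq.circumference_metrics(r).scaled_variance for r in rings]
    assert np.mean(vs) == pytest.approx(0.01, rel=0.15)


def test_nonpositive_mean_rejected():
    with pytest.raises(ValueError, match="mean"):
        hq.circumference_metrics(ring_from(np.zeros(32)))


# ------------------------------------------------------ group comparison

def _metrics(n, broken_fraction, cv, seed):
    rings, _ = hq.simulate_ring_profiles(n, broken_fraction, cv, seed=seed)
    return [hq.circumference_metrics(r) for r in rings]


def test_identical_groups_ratio_one_nonsignificant():
    g = _metrics(100, 0.0, 0.1, seed=17)
    cmp_ = hq.compare_uniformity(g, g)
    assert cmp_.variance_ratio == pytest.approx(1.0)
    assert cmp_.p_value >= 0.99
    assert cmp_.broken_fraction_a == cmp_.broken_fraction_b


def test_variance_ratio_scaling_oracle():
    """Group A at cv·√2 vs B at cv → variance ratio → 2."""
    a = _metrics(400, 0.0, 0.1 * np.sqrt(2.0), seed=19)
    b = _metrics(400, 0.0, 0.1, seed=23)
    cmp_ = hq.compare_uniformity(a, b)
    assert cmp_.variance_ratio == pytest.approx(2.0, rel=0.15)
    assert cmp_.p_value < 0.001


def test_broken_fraction_contrast_binomial():
    """Planted 20% vs 1% broken rings (the mutant-vs-wild-type contrast)."""
    a = _metrics(500, 0.20, 0.1, seed=29)
    b = _metrics(500, 0.01, 0.1, seed=31)
    cmp_ = hq.compare_uniformity(a, b)
    lo_a, hi_a = np.array(stats.binom.interval(0.99, 500, 0.20)) / 500
    lo_b, hi_b = np.array(stats.binom.interval(0.99, 500, 0.01)) / 500
    assert lo_a <= cmp_.broken_fraction_a <= hi_a
    assert lo_b <= cmp_.broken_fraction_b <= hi_b


def test_zero_denominator_flags_infinite_ratio():
    a = _metrics(20, 0.0, 0.1, seed=37)
    b = [hq.circumference_metrics(ring_from(np.full(32, 5.0)))] * 5
    cmp_ = hq.compare_uniformity(a, b)
    assert np.isinf(cmp_.variance_ratio)
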