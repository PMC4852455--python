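"""Changepoint fitting, growth-rate OLS and rise detection vs oracles."""

import numpy as np
import pandas as pd
import pytest

import hyphaq as hq
from hyphaq import kinetics
from hyphaq.trace_io import Channel, FrameRecord, HyphaTrace, IntensityProfile

from conftest import linear_plateau_trace


# ---------------------------------------------------------------- oracles

def brute_force_cessation(t, y, min_plateau_frames=3, slope_grid=None):
    """Independent exhaustive scan over (breakpoint, slope, intercept) with
    the slope on a fine grid; continuity enforced by construction."""
    if slope_grid is None:
        smax = max((y.max() - y.min()) / max(t[1] - t[0], 1e-9), 1e-9)
        slope_grid = np.linspace(0.0, 2.0 * smax, 4001)
    best = (0, np.inf)
    for b in range(0, len(t) - min_plateau_frames):
        x = np.minimum(t, t[b])
        # residuals for every gridded slope at its optimal intercept
        r = y[None, :] - slope_grid[:, None] * x[None, :]
        r = r - r.mean(axis=1, keepdims=True)
        sse = float((r ** 2).sum(axis=1).min())
        if sse < best[1] - 1e-9:
            best = (b, sse)
    return best[0]


def brute_force_rise(values, rel_threshold, window, persistence):
    n = len(values)
    for i in range(window, n - persistence + 1):
        if all(values[j] > (1 + rel_threshold) * np.mean(values[j - window:j])
               for j in range(i, i + persistence)):
            return i
    return None


def trace_from_lengths(lengths, dt=15.0):
    frames = [FrameRecord(frame_index=k, time_min=k * dt, length_um=float(l))
              for k, l in enumerate(lengths)]
    return HyphaTrace(hypha_id="h", strain="WT", frames=frames)


# ------------------------------------------------------- detect_cessation

def test_exact_changepoint_noise_free():
    tr = linear_plateau_trace(rate_um_per_h=6.0, t_cess=300.0, n_frames=30)
    b, sse = hq.detect_cessation(tr)
    assert b == 20
    assert sse == pytest.approx(0.0, abs=1e-18)


def test_all_constant_trace_gives_frame_zero_rate_zero():
    tr = trace_from_lengths([5.0] * 10)
    b, sse = hq.detect_cessation(tr)
    assert b == 0
    fit = hq.fit_growth(tr)
    assert fit.rate_um_per_h == 0.0


def test_too_few_frames_rejected():
    with pytest.raises(ValueError, match="6 frames"):
        hq.detect_cessation(trace_from_lengths([0, 1, 2, 3, 4]))


def test_cessation_matches_brute_force_oracle_many_seeds():
    """Exhaustive (b, slope)-grid oracle agreement on 200 random traces."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(8, 26))
        b_true = int(rng.integers(2, n - 3))
        rate = rng.uniform(0.5, 3.0)
        t = np.arange(n) * 15.0
        y = rate * np.minimum(t, t[b_true]) / 60.0
        y = y + rng.normal(0, 0.1, size=n)
        tr = trace_from_lengths(y)
        b, _ = hq.detect_cessation(tr)
        assert b == brute_force_cessation(t, y)


# ------------------------------------------------------------ growth_rate

@pytest.mark.parametrize("rate", [7.6, 12.0])
def test_growth_rate_exact_on_line(rate):
    tr = linear_plateau_trace(rate_um_per_h=rate, t_cess=300.0)
    assert hq.growth_rate(tr, 20) == pytest.approx(rate, rel=1e-12)


def test_growth_rate_worked_example():
    # points (0,0),(15,2),(30,4),(45,6) min/µm → 8 µm/h, plus plateau frames
    tr = trace_from_lengths([0, 2, 4, 6, 6, 6])
    assert hq.growth_rate(tr, 3) == pytest.approx(8.0, rel=1e-12)


def test_growth_rate_matches_closed_form_ols():
    rng = np.random.default_rng(3)
    y = 0.05 * np.arange(12) * 15 + rng.normal(0, 0.3, 12)
    tr = trace_from_lengths(y)
    t = tr.times_min
    slope = np.polyfit(t, y, 1)[0] * 60
    assert hq.growth_rate(tr, 11) == pytest.approx(slope, rel=1e-9)


def test_growth_rate_invariant_under_time_translation():
    rng = np.random.default_rng(4)
    y = 0.04 * np.arange(10) * 15 + rng.normal(0, 0.2, 10)
    tr = trace_from_lengths(y)
    shifted = HyphaTrace(hypha_id="h", strain="WT", frames=[
        FrameRecord(frame_index=k, time_min=k * 15.0 + 120.0, length_um=v)
        for k, v in enumerate(y)])
    assert hq.growth_rate(tr, 9) == pytest.approx(
        hq.growth_rate(shifted, 9), rel=1e-12)


# ------------------------------------------- mean_intensity_series / rise

def _trace_with_series(values, background=20.0):
    frames = []
    for k, v in enumerate(values):
        rec = FrameRecord(frame_index=k, time_min=k * 15.0, length_um=10.0)
        if v is not None:
            rec.profiles[Channel.FTSZ] = IntensityProfile(
                channel=Channel.FTSZ, positions_um=np.arange(5) * 0.1,
                intensities_au=np.full(5, v), background_au=background)
        frames.append(rec)
    return HyphaTrace(hypha_id="h", strain="WT", frames=frames)


def test_mean_intensity_background_subtracted():
    tr = _trace_with_series([100.0] * 6)
    s = hq.mean_intensity_series(tr, Channel.FTSZ)
    assert (s == 80.0).all()


def test_missing_channel_frame_is_gap_not_zero():
    tr = _trace_with_series([100.0, None, 100.0, 100.0, 100.0, 100.0])
    s = hq.mean_intensity_series(tr, Channel.FTSZ)
    assert np.isnan(s.iloc[1])
    with pytest.raises(ValueError, match="absent"):
        hq.mean_intensity_series(tr, Channel.PARA)


def test_constant_series_no_rise():
    s = pd.Series([100.0] * 10, index=np.arange(10) * 15.0)
    assert hq.detect_rise(s) is None


def test_rise_detected_at_first_exceeding_frame():
    s = pd.Series([100, 100, 100, 100, 120, 120, 120],
                  index=np.arange(7) * 15.0, dtype=float)
    ev = hq.detect_rise(s)
    assert ev is not None
    assert ev.frame_index == 4
    assert ev.time_min == 60.0


def test_rise_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(8, 30))
        base = rng.uniform(20, 60)
        onset = int(rng.integers(5, n))
        v = np.full(n, base) + rng.normal(0, base * 0.02, n)
        ramp = rng.uniform(0.0, base * 0.2)
        v[onset:] += ramp * (1 + np.arange(n - onset))
        s = pd.Series(v, index=np.arange(n) * 15.0)
        ev = hq.detect_rise(s)
        expected = brute_force_rise(list(v), 0.10, 4, 2)
        assert (ev.frame_index if ev else None) == expected


def test_rise_monotone_in_threshold():
    """Raising the threshold never yields an earlier detection."""
    rng = np.random.default_rng(6)
    for _ in range(50):
        v = np.full(20, 50.0) + rng.normal(0, 1.0, 20)
        v[10:] += np.linspace(2, 40, 10)
        s = pd.Series(v, index=np.arange(20) * 15.0)
        prev = None
        for thr in (0.05, 0.10, 0.20, 0.40):
            ev = hq.detect_rise(s, rel_threshold=thr)
            t = np.inf if ev is None else ev.frame_index
            if prev is not None:
                assert t >= prev
            prev = t


def test_nonpositive_baseline_is_error():
    s = pd.Series([0.0] * 4 + [10.0] * 4, index=np.arange(8) * 15.0)
    with pytest.raises(ValueError, match="baseline"):
        hq.detect_rise(s)


# ----------------------------------------------------------- event timing

def test_event_offsets_sign_convention_and_identities():
    tr = linear_plateau_trace()
    fit = hq.fit_growth(tr)
    assert fit.cessation_time_min == 300.0
    rise = kinetics.RiseEvent(channel=Channel.FTSZ, time_min=258.0,
                              frame_index=17)
    timing = hq.event_offsets(tr, fit, rise, (300.0, 390.0), 450.0)
    assert timing.ftsz_rise_offset_min == -42.0
    assert timing.ring_appear_offset_min == 0.0
    assert timing.ring_lifetime_min == 90.0
    assert timing.maturation_min == 60.0
    assert timing.total_sporulation_min == 150.0
    assert timing.total_differentiation_min == 450.0
    # identities hold exactly
    assert (timing.ring_appear_offset_min + timing.ring_lifetime_min
            + timing.maturation_min) == timing.total_sporulation_min


def test_zero_lifetime_allowed_inverted_interval_rejected():
    tr = linear_plateau_trace()
    fit = hq.fit_growth(tr)
    timing = hq.event_offsets(tr, fit, None, (300.0, 300.0), 330.0)
    assert timing.ring_lifetime_min == 0.0
    with pytest.raises(ValueError, match="precedes"):
        hq.event_offsets(tr, fit, None, (330.0, 300.0), 400.0)


def test_zero_variance_offsets_equal_generator_truth(wt_zero_cohort):
    cohort, truth = wt_zero_cohort
    sep = dict(zip(truth.hyphae.hypha_id, truth.hyphae.t_spore_sep_min))
    df = hq.quantify_cohort(cohort, spore_sep_times=sep)
    m = df.merge(truth.hyphae, on="hypha_id")
    assert (m.ftsz_rise_offset_min_x == m.ftsz_rise_offset_min_y).all()
    assert (m.ring_appear_offset_min == m.ring_offset_min).all()
    assert (m.ring_lifetime_min_x == m.ring_lifetime_min_y).all()
    assert (m.extension_time_min == m.t_cessation_min).all()
    np.testing.assert_allclose(m.rate_um_per_h_x, m.rate_um_per_h_y,
                               rtol=1e-9)
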