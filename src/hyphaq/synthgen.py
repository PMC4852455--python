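"""Synthetic cohorts, ring profiles and genomes with planted ground truth.

The generator emulates what the time-lapse experiments measure, one level
above pixels: per-frame hyphal lengths and 1-D fluorescence profiles.
A sporogenic hypha extends linearly at a drawn rate until a drawn cessation
time, then plateaus.  The FtsZ channel shows a diffuse fluorescence rise
starting tens of minutes before cessation, followed by a ladder of Gaussian
ring peaks that ramp up in amplitude, plateau, and are removed at the end of
the ring lifetime.  The ParA channel ramps monotonically from its rise time
to several-fold its baseline by spore separation.

Modelling conventions (see docs/methods.md for rationale):

* Event times are drawn from normal distributions (truncated at zero where a
  negative duration is meaningless) and then snapped to the frame grid, so a
  zero-variance cohort is *exactly* recoverable by the frame-based detectors.
* Fluorescence onsets begin with a 20% step above baseline at the event
  frame, followed by a linear ramp; rings appear at half their plateau
  amplitude and ramp to full.  This makes the planted event time coincide
  with the first frame at which the detection rules can fire.
* Ring peaks are removed instantaneously at the end of their lifetime.

Per-strain default parameters are the published cohort values for the
wild-type reporter strain and the *parA*/*parB*/*parAB* deletion and
TopA-depletion strains (see :data:`STRAIN_DEFAULTS`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trace_io import (Channel, Cohort, FrameRecord, HyphaTrace,
                       IntensityProfile, RingProfile)

__all__ = [
    "StrainParams",
    "GenomeParams",
    "SynthTruth",
    "STRAIN_DEFAULTS",
    "simulate_cohort",
    "simulate_ring_profiles",
    "simulate_genome",
    "revcomp",
]


@dataclass(frozen=True)
class StrainParams:
    """Per-strain generative parameters.

    Rates are µm/h, times and durations minutes, intensities arbitrary units.
    Signed offsets are relative to growth cessation (negative = before).
    """

    # growth
    rate_mean: float = 7.6
    rate_sd: float = 2.2
    extension_mean: float = 299.0
    extension_sd: float = 61.0
    # FtsZ diffuse rise
    ftsz_rise_offset_mean: float = -42.0
    ftsz_rise_offset_sd: float = 7.0
    ftsz_diffuse_fold: float = 3.0
    ftsz_ramp_min: float = 42.0
    # Z-ring ladder
    ring_offset_mean: float = 0.0
    ring_offset_sd: float = 9.0
    ring_lifetime_mean: float = 84.0
    ring_lifetime_sd: float = 26.0
    ring_spacing_um: float = 1.2
    ring_spacing_cv: float = 0.0
    ring_amp_ramp_min: float = 29.0
    ring_amp_plateau_min: float = 55.0
    ring_peak_fold: float = 3.0
    ring_sigma_um: float = 0.15
    # maturation (ring disappearance -> spore separation)
    maturation_mean: float = 63.0
    maturation_sd: float = 37.0
    # ParA accumulation
    para_rise_offset_mean: float = -54.0
    para_rise_offset_sd: float = 14.0
    para_ramp_min: float = 164.0
    para_fold_at_separation: float = 8.0
    # imaging / noise
    background_au: float = 100.0
    ftsz_base_au: float = 50.0
    para_base_au: float = 50.0
    onset_step_frac: float = 0.2
    noise_sd_au: float = 3.0
    length_noise_sd_um: float = 0.15
    sample_step_um: float = 0.1
    frame_interval_min: float = 15.0
    tail_frames: int = 4

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_sd") and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.ring_spacing_um <= 0:
            raise ValueError("ring_spacing_um must be > 0")
        if self.sample_step_um <= 0:
            raise ValueError("sample_step_um must be > 0")

    def zero_variance(self) -> "StrainParams":
        """Copy with all sds and noise set to 0 (exact-recovery mode)."""
        kw = {f.name: 0.0 for f in dataclasses.fields(self)
              if f.name.endswith("_sd") or f.name.endswith("_cv")}
        kw["noise_sd_au"] = 0.0
        kw["length_noise_sd_um"] = 0.0
        return replace(self, **kw)


#: Published cohort parameters per strain (mean, sd).  The TopA-depleted
#: strain has no published growth-rate or FtsZ-rise values; wild-type values
#: stand in for those, and its extension time is derived as
#: total differentiation − total sporulation (372 − 38 min).
STRAIN_DEFAULTS: dict[str, StrainParams] = {
    "WT": StrainParams(),
    "dparA": StrainParams(
        rate_mean=12.0, rate_sd=3.5, extension_mean=335.0, extension_sd=85.0,
        ftsz_rise_offset_mean=-44.0, ftsz_rise_offset_sd=4.0,
        ring_offset_mean=15.0, ring_offset_sd=12.0,
        ring_lifetime_mean=79.0, ring_lifetime_sd=12.0,
        maturation_mean=60.0, maturation_sd=17.0),
    "dparB": StrainParams(
        rate_mean=5.5, rate_sd=2.1, extension_mean=367.0, extension_sd=88.0,
        ftsz_rise_offset_mean=-43.0, ftsz_rise_offset_sd=6.0,
        ring_offset_mean=-28.0, ring_offset_sd=15.0,
        ring_lifetime_mean=117.0, ring_lifetime_sd=21.0,
        maturation_mean=62.0, maturation_sd=27.0),
    "dparAB": StrainParams(
        rate_mean=6.3, rate_sd=2.1, extension_mean=319.0, extension_sd=115.0,
        ftsz_rise_offset_mean=-44.0, ftsz_rise_offset_sd=4.0,
        ring_offset_mean=-39.0, ring_offset_sd=12.0,
        ring_lifetime_mean=135.0, ring_lifetime_sd=28.0,
        maturation_mean=47.0, maturation_sd=20.0),
    "topA": StrainParams(
        extension_mean=334.0, extension_sd=77.0,
        ring_offset_mean=-191.0, ring_offset_sd=49.0,
        ring_lifetime_mean=205.0, ring_lifetime_sd=52.0,
        maturation_mean=26.0, maturation_sd=10.0,
        ring_spacing_cv=0.3),
}


#: Published hyphal length at growth cessation per strain, µm:
#: (mean, sd, median).  Reference values for worked-example ratios; the
#: generator's lengths follow rate × extension time instead.
STRAIN_FINAL_LENGTHS_UM: dict[str, tuple[float, float, float]] = {
    "WT": (36.0, 13.0, 34.0),
    "dparA": (61.0, 16.0, 57.0),
    "dparB": (31.0, 11.0, 30.0),
    "dparAB": (31.0, 12.0, 28.0),
}


@dataclass
class SynthTruth:
    """Ground truth emitted alongside every generated dataset."""

    hyphae: pd.DataFrame | None = None        # per-hypha event times & rates
    ring_positions: pd.DataFrame | None = None  # per-hypha planted ring centres
    rings: pd.DataFrame | None = None         # per circumference ring: broken flag
    sites: pd.DataFrame | None = None         # per genome: planted site table

    def write(self, path) -> None:
        """Write the per-hypha truth table (the main one) to TSV."""
        if self.hyphae is None:
            raise ValueError("no per-hypha truth to write")
        self.hyphae.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _draw(rng: np.random.Generator, mean: float, sd: float,
          low: float | None = None) -> float:
    """Normal draw, optionally truncated below at ``low``."""
    if sd == 0:
        return float(mean) if low is None else float(max(mean, low))
    if low is None:
        return float(rng.normal(mean, sd))
    a = (low - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def _snap(t: float, interval: float) -> float:
    return round(t / interval) * interval


def simulate_cohort(params: Mapping[str, StrainParams] | StrainParams,
                    n_per_strain: int, seed: int,
                    channels: Sequence[str] = ("FTSZ", "PARA"),
                    ) -> tuple[Cohort, SynthTruth]:
    """Simulate ``n_per_strain`` hyphae for each strain.

    Parameters
    ----------
    params
        Either a single :class:`StrainParams` (strain name ``"WT"``) or a
        mapping strain name → params.
    channels
        Which fluorescence channels to render.  Pass ``()`` to generate
        length traces only (much faster for large Monte-Carlo cohorts).

    Returns
    -------
    (cohort, truth)
        ``cohort`` maps strain → list of :class:`~hyphaq.trace_io.HyphaTrace`;
        ``truth.hyphae`` holds the planted rates and event times,
        ``truth.ring_positions`` the planted ring centres.
    """
    if isinstance(params, StrainParams):
        params = {"WT": params}
    if n_per_strain < 1:
        raise ValueError("n_per_strain must be >= 1")
    channels = tuple(Channel.parse(c) for c in channels)

    cohort: Cohort = {}
    truth_rows = []
    ring_rows = []
    root = np.random.SeedSequence(seed)
    strain_seeds = root.spawn(len(params))
    for (strain, sp), ss in zip(params.items(), strain_seeds):
        sp.validate()
        rng = np.random.default_rng(ss)
        dt = sp.frame_interval_min
        traces = []
        for i in range(n_per_strain):
            hid = f"{strain}_{i:03d}"
            rate = _draw(rng, sp.rate_mean, sp.rate_sd, low=0.1)
            t_cess = _snap(_draw(rng, sp.extension_mean, sp.extension_sd,
                                 low=6 * dt), dt)
            t_ring = max(_snap(t_cess + _draw(rng, sp.ring_offset_mean,
                                              sp.ring_offset_sd), dt), 6 * dt)
            # diffuse FtsZ must be up before rings assemble from it
            t_rise = max(min(_snap(t_cess + _draw(rng, sp.ftsz_rise_offset_mean,
                                                  sp.ftsz_rise_offset_sd), dt),
                             t_ring - dt),
                         5 * dt)
            lifetime = _snap(_draw(rng, sp.ring_lifetime_mean,
                                   sp.ring_lifetime_sd, low=dt), dt)
            t_gone = t_ring + lifetime
            maturation = _snap(_draw(rng, sp.maturation_mean,
                                     sp.maturation_sd, low=0.0), dt)
            t_sep = t_gone + maturation
            t_para = max(_snap(t_cess + _draw(rng, sp.para_rise_offset_mean,
                                              sp.para_rise_offset_sd), dt),
                         5 * dt)

            final_len = rate * t_cess / 60.0
            # planted ring centres along the final hypha length
            spacings = np.full(max(int(final_len / sp.ring_spacing_um) + 2, 1),
                               sp.ring_spacing_um)
            if sp.ring_spacing_cv > 0:
                spacings = spacings * np.maximum(
                    1.0 + sp.ring_spacing_cv * rng.standard_normal(spacings.size),
                    0.2)
            centres = sp.ring_spacing_um / 2.0 + np.concatenate(
                ([0.0], np.cumsum(spacings[:-1])))
            # keep centres on the sampling grid so noise-free peak heights
            # are exact
            centres = np.round(centres / sp.sample_step_um) * sp.sample_step_um
            centres = centres[centres <= final_len - sp.sample_step_um]

            n_frames = int(round(max(t_sep, t_cess) / dt)) + sp.tail_frames + 1
            frames = []
            for k in range(n_frames):
                t = k * dt
                length = rate * min(t, t_cess) / 60.0
                if sp.length_noise_sd_um > 0:
                    length = max(length + rng.normal(0.0, sp.length_noise_sd_um),
                                 0.0)
                rec = FrameRecord(frame_index=k, time_min=t, length_um=length)
                for ch in channels:
                    rec.profiles[ch] = _render_profile(
                        ch, sp, rng, t, length, t_rise, t_ring, t_gone,
                        t_para, centres)
                frames.append(rec)
            traces.append(HyphaTrace(hypha_id=hid, strain=strain, frames=frames))
            truth_rows.append(dict(
                hypha_id=hid, strain=strain, rate_um_per_h=rate,
                t_cessation_min=t_cess, final_length_um=final_len,
                t_ftsz_rise_min=t_rise, t_ring_appear_min=t_ring,
                t_ring_disappear_min=t_gone, t_spore_sep_min=t_sep,
                t_para_rise_min=t_para,
                ftsz_rise_offset_min=t_rise - t_cess,
                ring_offset_min=t_ring - t_cess,
                ring_lifetime_min=lifetime, maturation_min=maturation,
                n_rings=centres.size))
            for j, c in enumerate(centres):
                ring_rows.append(dict(hypha_id=hid, ring_index=j,
                                      position_um=c))
        cohort[strain] = traces
    truth = SynthTruth(hyphae=pd.DataFrame(truth_rows),
                       ring_positions=pd.DataFrame(ring_rows))
    return cohort, truth


def _render_profile(ch: Channel, sp: StrainParams, rng: np.random.Generator,
                    t: float, length: float, t_rise: float, t_ring: float,
                    t_gone: float, t_para: float,
                    centres: np.ndarray) -> IntensityProfile:
    n = max(int(length / sp.sample_step_um) + 1, 1)
    x = np.arange(n) * sp.sample_step_um
    if ch is Channel.FTSZ:
        base = sp.ftsz_base_au
        level = _onset_ramp(t, t_rise, base, sp.ftsz_diffuse_fold * base,
                            sp.ftsz_ramp_min, sp.onset_step_frac)
        v = np.full(n, sp.background_au + level)
        if t_ring <= t < t_gone and centres.size:
            amp_full = (sp.ring_peak_fold - 1.0) * level
            frac = 0.5 + 0.5 * min((t - t_ring) / sp.ring_amp_ramp_min, 1.0) \
                if sp.ring_amp_ramp_min > 0 else 1.0
            amp = amp_full * frac
            d2 = (x[:, None] - centres[None, :]) ** 2
            v = v + amp * np.exp(-d2 / (2.0 * sp.ring_sigma_um ** 2)).sum(axis=1)
    elif ch is Channel.PARA:
        base = sp.para_base_au
        level = _onset_ramp(t, t_para, base, sp.para_fold_at_separation * base,
                            sp.para_ramp_min, sp.onset_step_frac)
        v = np.full(n, sp.background_au + level)
    else:
        v = np.full(n, sp.background_au)
    if sp.noise_sd_au > 0:
        v = v + rng.normal(0.0, sp.noise_sd_au, size=n)
    return IntensityProfile(channel=ch, positions_um=x, intensities_au=v,
                            background_au=sp.background_au)


def _onset_ramp(t: float, t0: float, base: float, top: float,
                ramp_min: float, step_frac: float) -> float:
    """Baseline until ``t0``; then a ``step_frac`` step and linear ramp to
    ``top`` over ``ramp_min`` minutes; constant afterwards."""
    if t < t0:
        return base
    start = base * (1.0 + step_frac)
    if ramp_min <= 0:
        return top
    return start + (top - start) * min((t - t0) / ramp_min, 1.0)


def simulate_ring_profiles(n: int, broken_fraction: float,
                           cv_intensity: float, seed: int,
                           n_samples: int = 64,
                           circumference_um: float = 3.2,
                           strain: str = "synthetic",
                           base_au: float = 100.0,
                           ) -> tuple[list[RingProfile], SynthTruth]:
    """Simulate ring-circumference intensity profiles.

    A fraction ``broken_fraction`` of rings carries a contiguous
    low-intensity arc (3% of the base level over 15–30% of the
    circumference); intact rings have multiplicative noise with coefficient
    of variation ``cv_intensity``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= broken_fraction <= 1.0:
        raise ValueError("broken_fraction must be in [0, 1]")
    if cv_intensity < 0:
        raise ValueError("cv_intensity must be >= 0")
    rng = np.random.default_rng(seed)
    pos = np.arange(n_samples) * circumference_um / n_samples
    rings, rows = [], []
    for i in range(n):
        broken = bool(rng.random() < broken_fraction)
        v = base_au * (1.0 + cv_intensity * rng.standard_normal(n_samples))
        v = np.maximum(v, 1e-3)
        if broken:
            arc_frac = rng.uniform(0.15, 0.30)
            k = max(int(round(arc_frac * n_samples)), 1)
            start = int(rng.integers(0, n_samples))
            idx = (start + np.arange(k)) % n_samples
            v[idx] = base_au * 0.03
        rid = f"ring_{i:04d}"
        rings.append(RingProfile(ring_id=rid, strain=strain,
                                 arc_positions_um=pos.copy(),
                                 intensities_au=v))
        rows.append(dict(ring_id=rid, strain=strain, broken=broken))
    return rings, SynthTruth(rings=pd.DataFrame(rows))


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeParams:
    """Parameters for a synthetic genome with planted motif sites."""

    length_bp: int
    gc_fraction: float = 0.72
    planted_sites: tuple = ()  # (sequence, position, strand) triples
    substitution_rate: float = 0.0

    def validate(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        spans = []
        for s, p, strand in self.planted_sites:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if p < 0 or p + len(s) > self.length_bp:
                raise ValueError(f"site at {p} out of bounds")
            spans.append((p, p + len(s)))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("planted sites overlap")


def simulate_genome(params: GenomeParams, seed: int
                    ) -> tuple[str, SynthTruth]:
    """Generate an iid background genome and plant the configured sites.

    Returns the sequence and a truth table with 0-based half-open
    coordinates, strands and the final (possibly substituted) site sequence.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    gc = params.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=params.length_bp,
                     p=probs)
    rows = []
    for s, p, strand in params.planted_sites:
        site = s.upper() if strand == "+" else revcomp(s.upper())
        site = list(site)
        n_sub = 0
        if params.substitution_rate > 0:
            for j in range(len(site)):
                if rng.random() < params.substitution_rate:
                    alts = [b for b in "ACGT" if b != site[j]]
                    site[j] = alts[int(rng.integers(0, 3))]
                    n_sub += 1
        site = "".join(site)
        arr[p:p + len(site)] = np.frombuffer(site.encode(), dtype="S1")
        rows.append(dict(start=p, end=p + len(site), strand=strand,
                         sequence=site, n_substitutions=n_sub))
    seq = arr.tobytes().decode()
    truth = pd.DataFrame(rows, columns=["start", "end", "strand", "sequence",
                                        "n_substitutions"])
    return seq, SynthTruth(sites=truth.sort_values("start").reset_index(drop=True))
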