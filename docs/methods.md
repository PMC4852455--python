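# Methods

## Scope and data model

The package quantifies *Streptomyces* sporulation from 1-D measurements:
per-frame hyphal length and per-frame fluorescence intensity profiles
sampled along a line laid down the hypha (channels: FtsZ reporter, ParA
reporter, DNA stain), and intensity profiles around the circumference of
individual Z-rings from super-resolution images.  Segmenting hyphae from
pixels, vendor image formats and 3-D reconstruction are out of scope; the
schemas assume arclength positions are supplied upstream.  Time is minutes
since branch emergence (t = 0), the frame interval defaults to 15 min, and
every event offset is signed relative to growth cessation
(negative = before).  One printed source inconsistency is worth noting: the
published wild-type FtsZ-appearance row pairs a mean of −42 min with a
median printed as "45"; we standardise on signed values throughout and
treat that median as −45.

## Growth fitting

Growth cessation is estimated by a continuous two-segment least-squares
model: `ℓ(t) = a + v·min(t, t_b)` with slope `v ≥ 0`, i.e. linear
extension up to a breakpoint frame `b`, constant afterwards.  The
breakpoint is searched exhaustively over all frames with at least 3 frames
of plateau (traces are ≤ ~100 frames, so exhaustive search is cheap); for
fixed `b` the fit is closed-form OLS on the regressor `min(t, t_b)`, with
the slope clamped at 0.  Ties break to the earliest frame; an all-constant
trace yields cessation at frame 0 with rate 0.  The source study judged
cessation visually, so the detector is this package's operationalisation.
The extension rate is the OLS slope of length vs time over frames
`[0, b]`, converted to µm h⁻¹.

## Event detection

Fluorescence rises use a relative-threshold rule on the per-frame mean of
the background-subtracted profile: the first frame whose value exceeds
`(1 + 0.10)` × the mean of the 4 preceding frames, sustained for 2
consecutive frames.  "Earlier time points" is not otherwise
operationalised in the source description, so the baseline is a trailing
window; window, persistence and threshold are exposed as configuration.  A
non-positive baseline mean is an error (a relative threshold is undefined
there).  Frames lacking a channel are gaps, never zeros.  Times are
frame-quantised; there is no sub-frame interpolation, matching the 15-min
reporting precision of the measurements.

Ring-ladder intervals come from per-frame peak counts: appearance is the
first frame with ≥ 3 qualifying peaks sustained 2 frames, disappearance
the first later frame where the count drops below 3 and stays below for 2
frames.  "Clearly visible rings" is thereby operationalised as persistent
qualifying peaks; both knobs are configurable.

## Ring metrics

Profile peaks are local maxima with prominence ≥ 0.5 × the
background-subtracted profile mean, thinned greedily (higher peak wins,
ties leftmost) to a minimum separation of 0.5 µm.  Ladder fluorescence is
the mean of the seven highest peaks (all peaks if fewer; undefined/NaN for
none).  Ring spacings are adjacent-peak distances; their CV uses the
sample (n−1) standard deviation.

Circumference profiles are scaled to mean 1; the scaled variance is the
sample variance of the scaled values.  A ring is *broken* when a
contiguous circular arc of ≥ 10% of the circumference falls below 25% of
the scaled median; arcs are measured with per-sample segment weights and
wrap-around runs count as contiguous, so the classification is
rotation-invariant.  "Scaled up to similar values" is interpreted as
per-ring mean normalisation (max-normalisation is a possible alternative;
it would shrink all variances by a common factor and leave the group
contrast qualitatively unchanged).  Group comparisons report the ratio of
mean scaled variances and an F-test on the pooled scaled residual
variances, with degrees of freedom summed over rings (each ring
contributes n−1); whether the published "ratio of variances" statistic was
group-level or per-pair is not stated, so we report the group-level ratio
and do not claim equivalence.

## Cohort statistics

Summaries are sample mean, sd (n−1 denominator — the convention for
reported sample sds) and midpoint median.  Across-strain comparisons use
Kruskal–Wallis (tie-corrected); pairwise contrasts use Mann–Whitney
(normal approximation with tie correction) or Student's t.  When every
group has ≤ 8 observations and the enumeration is small, all three tests
switch to their exact permutation form (full enumeration of group
assignments; two-sided by |statistic| for U and t, upper tail for H), so
small-sample p-values are exact rather than asymptotic.  No
multiple-testing correction is applied, matching the source analyses; the
comparison count is reported for transparency.  Significance tiers
(*, **, ***) follow the table legends at 0.1/0.01/0.001.

The timing budget identity — ring-appearance offset + ring lifetime +
maturation = total sporulation time — is checked on medians and returned
as a signed residual.

## parS scanning

The PWM uses pseudocounted column probabilities
`(count + 0.5)/(n + 2)` and log-odds in bits against a background that
defaults to the genome's mononucleotide composition (GC ≈ 0.72 for these
genomes; uniform is available — the scanning tool used in the source work
supports both and the choice is not recorded).  Score p-values are exact:
a dynamic-programming convolution of per-position score distributions on a
0.001-bit grid; windows are scored with the same rounded matrix, so
thresholding at p ≤ 10⁻⁶ is reproducible and enumeration-exact for the
discretised score.  Both strands are scanned; the forward and
reverse-complement match of one window are merged (best strand, ties to
forward) so palindromic sites are counted once.  Ambiguity codes never
match (conservative).  Coordinates are 0-based half-open; output is BED6
with the score in bits and −10·log₁₀(p) capped at 1000.

The default seed set is a documented synthetic stand-in: the published
consensus `GTTTCACCTGAAAC` plus its single symmetric-pair palindromized
variants (the experimentally determined sequence collection is not
reproduced here and can be supplied explicitly).  Scans of the real
chromosome accessions may therefore differ in exact hit counts from the
published 16 (*S. venezuelae*) and 23+1 (*S. coelicolor*) sites.

The DNA walk steps +1 per A/T and −1 per G/C (0 for ambiguous bases),
reported once per window; its final value equals the A+T surplus of the
covered sequence, a telescoping identity used as a self-check.  ChIP peak
annotation is positional only: nearest hit by midpoint distance, signed
peak−hit, zero for overlap.

## Synthetic generator

The generator emulates the study conditions, not microscope physics.  Per
strain it draws, per hypha: extension rate, cessation time, FtsZ rise
offset, ring-appearance offset, ring lifetime and maturation from normal
distributions at the published cohort means and sds (truncated at zero
where a negative duration is meaningless — normality is an assumption;
only mean ± sd are published).  Lengths grow linearly to cessation and
plateau, with 0.15 µm Gaussian length noise.  Profiles are sampled every
0.1 µm: the FtsZ channel is background + diffuse level + Gaussian ring
peaks (σ = 0.15 µm) at 1.2 µm spacing; the ParA channel ramps from its
rise time over 164 min to 8× baseline (≈3× at cessation).  Ring peak
amplitude ramps over 29 min to 3× the diffuse level and holds until
removal; ring spacing is exactly regular except for the TopA-depleted
parameter set, which adds a 30% spacing CV to emulate its irregular
ladders.  Additive intensity noise defaults to 3 au against a 50 au
baseline — per-sample white noise, deliberately mild because real
profiles are smoothed by the point-spread function.

Three modelling conventions make planted truth exactly recoverable, which
is what turns the generator into an oracle:

* **Frame-grid quantisation.** Drawn event times are snapped to the 15-min
  frame grid in both the rendered data and the truth table.  A cessation
  at 299 min is not exactly representable by any frame-based changepoint,
  so the zero-variance wild type has a 300-min extension; all published
  medians are 15-min multiples, consistent with frame-quantised
  measurement.
* **Onset steps.** A rise that starts from baseline is only detectable one
  or more frames after it begins under a >10% rule.  Onsets therefore
  begin with a 20% step at the event frame followed by the linear ramp,
  and rings appear at half their plateau amplitude; the planted event time
  then coincides with the first frame the detection rules can fire on.
* **Orderings.** The diffuse rise is constrained to precede ring
  appearance by at least one frame, rings disassemble instantaneously at
  lifetime end, and traces always cover both cessation and spore
  separation.

The TopA-depleted strain has no published growth-rate or FtsZ-rise values;
wild-type values stand in, and its extension time is derived as total
differentiation − total sporulation (334 min).  No branch-emergence length
is published either; hyphae start at length 0.  Spore separation has no
fluorescence signature in the modelled channels, so it is an input to the
pipeline (the generator's truth value, or a curated observation for real
data).

What the generator does **not** emulate: 2-D/3-D imaging, photobleaching,
focus drift, curved hyphae, branching, tip-proximal rate changes around
emergence/cessation, and correlations between parameters (all draws are
independent, with the stated ordering constraints).  Passing
parameter-recovery tests therefore demonstrates that the detectors are
unbiased and exact under the stated event model at the published parameter
values — not that they are robust to every artefact of real microscopy.

## Problem sizes and numerics

Recovery tests use cohorts of n = 35 hyphae per strain (the published
cohort size) and 500-ring groups for uniformity contrasts; oracle
equivalence uses 200 random instances per detector; genome scans use
600 kb synthetic chromosomes with a 16-site cluster planted in a 200 kb
central region, chosen to mirror the published cluster layout at a size
where the expected number of background false positives at p ≤ 10⁻⁶ is
~1.  Changepoint ties break to the earliest frame; slope estimates are
clamped non-negative; the score-grid discretisation (0.001 bits) bounds
p-value error by one grid step; SSE comparisons use a 1e-12 absolute
guard.  Known limitations: the broken-ring thresholds (25%/10%) were
calibrated on the generator, not on real super-resolution data; the exact
*parS* seed set is a stand-in; and the F-test assumes approximately normal
scaled residuals within rings.
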