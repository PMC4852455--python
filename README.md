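# hyphaq

Single-cell quantification of *Streptomyces* sporulation from time-lapse
fluorescence microscopy, plus in-silico *parS* centromere-site discovery.

## The problem

Sporulating *Streptomyces* convert a long aerial (sporogenic) hypha into a
chain of unigenomic spores.  The transition is tightly choreographed: the
hyphal tip stops extending (**growth cessation**), diffuse FtsZ
fluorescence rises tens of minutes beforehand, a ladder of regularly spaced
**Z-rings** assembles along the compartment, persists while chromosomes
segregate, disassembles, and the spores then round up and separate.  The
chromosome-segregation proteins ParA and ParB modulate the extension rate,
the timing of Z-ring assembly and the structural uniformity of the rings;
ParB binds the near-palindromic *parS* sites (consensus `GTTTCACCTGAAAC`)
clustered near *oriC*.

`hyphaq` turns the measurements behind this kind of study into a tested,
reusable pipeline.  It works one level above pixels, on 1-D quantities
exported from microscopy software (or produced by the built-in synthetic
generator): per-frame hyphal lengths and per-frame fluorescence intensity
profiles along the hypha, plus intensity profiles around individual ring
circumferences, all as plain TSV.

## What it computes

* **Growth kinetics** — growth cessation by an exhaustive continuous
  two-segment least-squares changepoint fit, `ℓ(t) = a + v·min(t, t_c)`
  with `v ≥ 0`; the extension rate as the OLS slope of length vs time over
  the growth segment (µm h⁻¹).
* **Event detection** — fluorescence rise at the first frame whose
  background-subtracted mean exceeds the trailing-window baseline by >10%
  (sustained 2 frames); Z-ring ladder appearance/disappearance from
  per-frame counts of qualifying profile peaks.  All event times are
  reported as signed offsets from growth cessation (negative = before).
* **Ring metrics** — ladder fluorescence as the mean of the seven highest
  profile peaks; adjacent ring spacings and their CV; per-ring scaled
  variance (intensities normalised to mean 1) and broken-ring
  classification (a contiguous circular arc ≥10% of the circumference below
  25% of the ring median); group contrasts by F-test on pooled scaled
  residuals.
* **Cohort statistics** — per-strain `mean ± sd (median)` tables,
  Kruskal–Wallis / Mann–Whitney / Student's t comparisons (exact
  permutation p-values for small samples), and the sporulation timing
  budget identity: appearance offset + ring lifetime + maturation = total
  sporulation time.
* **parS discovery** — a position weight matrix scored in bits
  (`log₂ p_i(b)/q(b)`), with the score p-value computed by exact dynamic
  programming convolution on a 0.001-bit grid; both-strand genome scanning
  at p ≤ 10⁻⁶ with palindromic matches counted once; DNA-walk (+1 for A/T,
  −1 for G/C) composition profiles; nearest-site annotation of ChIP peak
  intervals.
* **Synthetic data** — cohorts, ring-circumference profiles and genomes
  with planted ground truth, parameterised per strain (wild type,
  Δ*parA*, Δ*parB*, Δ*parAB*, TopA-depleted) by the published cohort values.

## Worked example

Simulate wild-type and Δ*parA* cohorts (35 hyphae each, 15-min frames),
quantify every hypha and build the strain comparison table:

```python
import hyphaq as hq

cohort, truth = hq.simulate_cohort(
    {s: hq.STRAIN_DEFAULTS[s] for s in ("WT", "dparA")}, 35, seed=1)
sep = dict(zip(truth.hyphae.hypha_id, truth.hyphae.t_spore_sep_min))
results = hq.quantify_cohort(cohort, spore_sep_times=sep)

from hyphaq.pipeline import tables_to_frame
print(tables_to_frame(hq.cohort_tables(results)).to_string())

test = hq.compare_groups(
    {s: results.loc[results.strain == s, "rate_um_per_h"]
     for s in ("WT", "dparA")}, "mann_whitney")
print(f"Mann-Whitney U={test.statistic:.0f}, p={test.p_value:.2e}")
```

Output:

```text
strain                                     WT               dparA
extension_time_min         299.1±50.4 (300.0)  351.9±78.2 (360.0)
final_length_um              37.7±13.9 (35.8)    68.1±21.7 (66.4)
rate_um_per_h                   7.6±2.6 (7.9)     11.5±2.2 (11.4)
ftsz_rise_offset_min        -43.3±7.1 (-45.0)   -44.6±2.5 (-45.0)
ring_appear_offset_min         -0.9±8.9 (0.0)    15.4±11.2 (15.0)
ring_lifetime_min            86.6±25.0 (90.0)    82.3±12.3 (90.0)
maturation_min               74.6±32.8 (75.0)    62.6±15.2 (60.0)
total_sporulation_min      160.3±40.0 (165.0)  160.3±22.1 (165.0)
total_differentiation_min  459.4±65.8 (450.0)  512.1±80.5 (510.0)
Mann-Whitney U=148, p=5.03e-08
```

Reading the table: the wild-type hypha extends for ~5 h at ~7.6 µm h⁻¹,
FtsZ fluorescence rises ~45 min before cessation, rings appear at
cessation (offset ≈ 0) and persist ~90 min; the Δ*parA* strain grows ~50%
faster and assembles its rings ~15 min late — the planted contrasts, read
back by the detectors.  The same workflows are available from the shell:

```sh
hyphaq simulate cohort --strain WT --n 35 --seed 1 --out-dir data/
hyphaq growth --traces data/traces.tsv --out growth.tsv
hyphaq events --traces data/traces.tsv --profiles data/profiles.tsv \
              --spore-sep data/truth.tsv --out events.tsv
hyphaq cohort --events events.tsv --tests kruskal_wallis --out summary.tsv
hyphaq simulate genome --length 600000 --n-sites 16 --out g.fasta --truth-bed t.bed
hyphaq pars scan --genome g.fasta --p-max 1e-6 --out hits.bed
```

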