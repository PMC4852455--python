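"""parS motif discovery: PWM scanning with exact p-values, DNA walk,
and ChIP-peak annotation.

The centromere-like *parS* site of *Streptomyces* is a near-palindromic
14-mer (consensus ``GTTTCACCTGAAAC``) bound by ParB.  Candidate sites are
found by scoring every genomic window on both strands against a position
weight matrix (PWM) and keeping windows whose score p-value — the
probability that a random background sequence of the same length scores at
least as high — falls below a threshold (default 1e-6).

The p-value machinery is an exact dynamic-programming convolution of the
per-position score distributions on a discretised score grid (default step
0.001 bits), not a sampling approximation, so thresholding is reproducible.
Scores are computed with the same discretised matrix, making scan p-values
exact with respect to the discretisation.

Coordinates are 0-based half-open throughout; BED is used for interval
output.  Ambiguous bases (N etc.) never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PWM",
    "ScoreDistribution",
    "ParSHit",
    "WalkSeries",
    "PARS_CONSENSUS",
    "default_seed_set",
    "build_pwm",
    "score_pvalues",
    "scan_genome",
    "hit_span",
    "dna_walk",
    "annotate_peaks",
    "read_genome",
    "read_bed",
    "write_hits_bed",
]

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMP_IDX = [3, 2, 1, 0]  # A<->T, C<->G

#: parS consensus identified experimentally in *S. coelicolor*.
PARS_CONSENSUS = "GTTTCACCTGAAAC"


def default_seed_set() -> list[str]:
    """Synthetic stand-in seed set for the PWM.

    The experimentally determined *parS* sequence collection is not
    reproduced here; the default is the published consensus plus every
    single symmetric-pair palindromized variant (position ``i`` replaced by
    an alternative base and position ``L−1−i`` by its complement), which
    yields a consensus-dominated, mildly degenerate matrix.  Supply the true
    experimental set via :func:`build_pwm` when available.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    cons = PARS_CONSENSUS
    out = [cons]
    half = len(cons) // 2
    for i in range(half):
        for b in ALPHABET:
            if b == cons[i]:
                continue
            v = list(cons)
            v[i] = b
            v[len(cons) - 1 - i] = comp[b]
            out.append("".join(v))
    return out


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over {A, C, G, T}.

    ``probs[(i, b)]`` is the per-position base probability (pseudocounted);
    ``log_odds`` is log2(prob / background) in bits.
    """

    probs: np.ndarray       # (L, 4)
    log_odds: np.ndarray    # (L, 4), bits
    background: np.ndarray  # (4,)
    pseudocount: float

    @property
    def length(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def score(self, seq: str) -> float:
        """Log-odds score of one L-mer, bits.  −inf on ambiguous bases."""
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != PWM length {self.length}")
        s = 0.0
        for i, b in enumerate(seq.upper()):
            if b not in _IDX:
                return float("-inf")
            s += self.log_odds[i, _IDX[b]]
        return float(s)

    def reverse_complement(self) -> "PWM":
        rc = self.log_odds[::-1, :][:, _COMP_IDX]
        pr = self.probs[::-1, :][:, _COMP_IDX]
        return PWM(probs=pr, log_odds=rc, background=self.background,
                   pseudocount=self.pseudocount)


def _as_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    return bg


def genome_background(sequence: str) -> np.ndarray:
    """Mononucleotide background frequencies of a genome (ACGT order)."""
    counts = np.array([sequence.upper().count(b) for b in ALPHABET], dtype=float)
    if counts.sum() == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return counts / counts.sum()


def build_pwm(seed_sequences: list[str], pseudocount: float = 0.5,
              background=None) -> PWM:
    """Build a PWM from equal-length DNA seed sequences.

    Position probabilities are ``(count + pseudocount) / (n + 4·pseudocount)``
    and log-odds are log2(prob / background).
    """
    if not seed_sequences:
        raise ValueError("need at least one seed sequence")
    seqs = [s.upper() for s in seed_sequences]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("seed sequences must have equal length")
    if any(b not in _IDX for s in seqs for b in s):
        raise ValueError("seed sequences must be over {A,C,G,T}")
    bg = _as_background(background)
    counts = np.zeros((L, 4))
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, _IDX[b]] += 1
    n = len(seqs)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / bg)
    return PWM(probs=probs, log_odds=log_odds, background=bg,
               pseudocount=pseudocount)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the PWM score of a random background L-mer,
    on a discretised score grid."""

    step: float
    min_units: int           # grid index of the lowest achievable score
    tail: np.ndarray         # tail[k] = P(score >= (min_units + k) * step)
    int_matrix: np.ndarray   # (L, 4) log-odds rounded to grid units

    @property
    def scores(self) -> np.ndarray:
        return (self.min_units + np.arange(self.tail.size)) * self.step

    def pvalue_units(self, units: int) -> float:
        """P(score >= units·step) for an integer grid score."""
        k = units - self.min_units
        if k < 0:
            return 1.0
        if k >= self.tail.size:
            return 0.0
        return float(self.tail[k])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_units(int(round(score_bits / self.step)))

    def threshold_units(self, p_max: float) -> int:
        """Smallest integer grid score whose tail probability is <= p_max."""
        ok = np.nonzero(self.tail <= p_max)[0]
        if ok.size == 0:
            return self.min_units + self.tail.size  # unreachable score
        return self.min_units + int(ok[0])


def score_pvalues(pwm: PWM, background=None, step: float = 0.001
                  ) -> ScoreDistribution:
    """Exact score distribution by per-position convolution on a score grid.

    ``background`` defaults to the PWM's own background.  Scores are rounded
    to multiples of ``step`` (bits); the returned tail probabilities are
    exact for the rounded matrix, hence within one discretisation step of
    the continuous-score tail.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    bg = pwm.background if background is None else _as_background(background)
    # finite grid representation; -inf cannot occur with pseudocount > 0,
    # with pseudocount 0 clamp to a very low finite score
    lo = pwm.log_odds.copy()
    finite_min = lo[np.isfinite(lo)].min() if np.isfinite(lo).any() else 0.0
    lo[~np.isfinite(lo)] = min(finite_min, 0.0) - 100.0
    m = np.rint(lo / step).astype(np.int64)

    min_units = int(m.min(axis=1).sum())
    max_units = int(m.max(axis=1).sum())
    width = max_units - min_units + 1
    dist = np.zeros(width)
    # running support [cur_min, cur_min + used)
    cur_min = 0
    dist[0] = 1.0
    used = 1
    for i in range(pwm.length):
        row = m[i]
        new_min = cur_min + int(row.min())
        new_used = used + int(row.max() - row.min())
        new = np.zeros(new_used)
        for b in range(4):
            off = int(row[b]) - int(row.min())
            new[off: off + used] += bg[b] * dist[:used]
        dist = np.zeros(max(new_used, width))
        dist[:new_used] = new
        cur_min, used = new_min, new_used
    probs = dist[:used]
    tail = probs[::-1].cumsum()[::-1]
    # align to the global grid [min_units, max_units]
    assert cur_min == min_units and used == width
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(step=step, min_units=min_units, tail=tail,
                             int_matrix=m)


@dataclass(frozen=True)
class ParSHit:
    """One genomic PWM match (0-based half-open coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    score_bits: float
    p_value: float

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _encode(sequence: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _IDX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def scan_genome(sequence: str, pwm: PWM, p_max: float = 1e-6,
                background=None, step: float = 0.001,
                contig: str = "genome") -> list[ParSHit]:
    """Scan both strands of a sequence for PWM matches with p <= p_max.

    The forward and reverse-complement match of the same window are merged
    into a single hit (best strand by score, ties to forward), so perfectly
    palindromic sites are counted once.  Windows containing ambiguous bases
    never match.  Hits are sorted by start coordinate.
    """
    dist = score_pvalues(pwm, background=background, step=step)
    L = pwm.length
    if len(sequence) < L:
        raise ValueError(f"sequence shorter than PWM length {L}")
    codes = _encode(sequence)
    n_win = codes.size - L + 1

    NEG = np.int64(-(10 ** 9))
    mfwd = np.full((L, 5), NEG, dtype=np.int64)
    mfwd[:, :4] = dist.int_matrix
    # reverse-complement matrix scores the window against the other strand
    mrev = np.full((L, 5), NEG, dtype=np.int64)
    mrev[:, :4] = dist.int_matrix[::-1, :][:, _COMP_IDX]

    fwd = np.zeros(n_win, dtype=np.int64)
    rev = np.zeros(n_win, dtype=np.int64)
    for j in range(L):
        c = codes[j: j + n_win]
        fwd += mfwd[j][c]
        rev += mrev[j][c]

    thr = dist.threshold_units(p_max)
    hits = []
    sel = np.nonzero((fwd >= thr) | (rev >= thr))[0]
    for i in sel:
        f, r = int(fwd[i]), int(rev[i])
        if f >= r:
            strand, units = "+", f
        else:
            strand, units = "-", r
        hits.append(ParSHit(contig=contig, start=int(i), end=int(i) + L,
                            strand=strand, score_bits=units * dist.step,
                            p_value=dist.pvalue_units(units)))
    return hits


@dataclass(frozen=True)
class HitSpan:
    min_start: int
    max_end: int
    span_bp: int
    max_distance_to_reference: float | None


def hit_span(hits: list[ParSHit], reference_point: float | None = None
             ) -> HitSpan:
    """Genomic extent of a hit set and, optionally, the largest midpoint
    distance to a reference coordinate (e.g. *oriC*)."""
    if not hits:
        raise ValueError("empty hit list")
    lo = min(h.start for h in hits)
    hi = max(h.end for h in hits)
    maxd = None
    if reference_point is not None:
        maxd = max(abs(h.midpoint - reference_point) for h in hits)
    return HitSpan(min_start=lo, max_end=hi, span_bp=hi - lo,
                   max_distance_to_reference=maxd)


@dataclass(frozen=True)
class WalkSeries:
    """Cumulative A+T composition walk (+1 per A/T, −1 per G/C)."""

    positions: np.ndarray  # window midpoints, bp
    values: np.ndarray     # walk value at the last base of each window


def dna_walk(sequence: str, window: int = 1000) -> WalkSeries:
    """DNA walk visualising A+T content along a sequence.

    Each base steps the walk by +1 (A/T) or −1 (G/C); ambiguous bases step
    by 0.  The cumulative value is reported once per window (at the last
    base), labelled with the window midpoint.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not sequence:
        raise ValueError("empty sequence")
    codes = _encode(sequence)
    steps = np.zeros(codes.size, dtype=np.int64)
    steps[(codes == 0) | (codes == 3)] = 1    # A, T
    steps[(codes == 1) | (codes == 2)] = -1   # C, G
    cum = steps.cumsum()
    k = codes.size // window
    values = cum[window - 1::window][:k]
    positions = np.arange(k) * window + window / 2.0
    return WalkSeries(positions=positions, values=values)


@dataclass(frozen=True)
class PeakAnnotation:
    """Nearest-parS annotation of ChIP peak intervals."""

    table: pd.DataFrame
    region_start: int
    region_end: int
    region_span_bp: int
    no_hits: bool


def annotate_peaks(peaks, hits: list[ParSHit]) -> PeakAnnotation:
    """Annotate each peak interval with its nearest hit by midpoint distance.

    ``peaks`` is a sequence of ``(start, end)`` pairs or a DataFrame with
    ``start``/``end`` columns (same contig, 0-based half-open).  Distance is
    signed as peak midpoint − hit midpoint (negative = peak left of hit) and
    0 for overlapping intervals.  With no hits the distances are undefined
    (NaN) and ``no_hits`` is flagged.
    """
    if isinstance(peaks, pd.DataFrame):
        intervals = list(zip(peaks["start"].astype(int), peaks["end"].astype(int)))
    else:
        intervals = [(int(a), int(b)) for a, b in peaks]
    if not intervals:
        raise ValueError("no peak intervals")
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    rows = []
    for a, b in intervals:
        mid = (a + b) / 2.0
        if not hits:
            rows.append(dict(peak_start=a, peak_end=b, hit_start=np.nan,
                             hit_end=np.nan, hit_strand="", distance=np.nan))
            continue
        best = min(hits, key=lambda h: (abs(mid - h.midpoint), h.start))
        overlap = a < best.end and best.start < b
        dist = 0.0 if overlap else mid - best.midpoint
        rows.append(dict(peak_start=a, peak_end=b, hit_start=best.start,
                         hit_end=best.end, hit_strand=best.strand,
                         distance=dist))
    return PeakAnnotation(table=pd.DataFrame(rows), region_start=lo,
                          region_end=hi, region_span_bp=hi - lo,
                          no_hits=not hits)


def read_genome(path) -> tuple[str, str]:
    """Read the first record of a FASTA or GenBank file → (id, sequence)."""
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    rec = next(SeqIO.parse(str(path), fmt))
    return rec.id, str(rec.seq).upper()


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end, ...)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(6, df.shape[1])]
    return df


def write_hits_bed(hits: list[ParSHit], path) -> None:
    """Write hits as BED6: name = score in bits, score = −10·log10(p)
    capped at 1000."""
    rows = []
    for h in hits:
        capped = min(-10.0 * np.log10(max(h.p_value, 1e-300)), 1000.0)
        rows.append((h.contig, h.start, h.end, f"{h.score_bits:.3f}",
                     f"{capped:.1f}", h.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
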