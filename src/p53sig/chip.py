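"""ChIP-side operations: peak significance, merging, counting, the top-30%
cross-condition normalization, and p53 response-element PWM scanning.

The significance test is a deliberately simple Poisson enrichment test of the
IP count against the depth-scaled pooled negative control (a documented
stand-in for a full peak caller): candidate peaks arrive pre-called, and the
significance filters -- Benjamini-Hochberg FDR < 0.01 and fold enrichment
>= 5 over the pooled control -- are applied on top, which is where the method's
discrimination happens.

The p53 response element is modeled as two adjacent RRRCWWGYYY half-sites
(20 bp, no spacer).  Scanning is plain log2-odds scoring of a position
weight matrix against a uniform background on both strands.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GenomicInterval, MergedRegion, PeakCall

DEFAULT_FDR_MAX = 0.01
DEFAULT_MIN_FOLD = 5.0
DEFAULT_TOP_FRACTION = 0.30
P53_CONSENSUS = "RRRCWWGYYY" * 2  # two adjacent half-sites, zero spacer

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


# ---------------------------------------------------------------------------
# significance primitives

def poisson_tail(k: int, lam: float) -> float:
    """Upper tail P(X >= k) for X ~ Poisson(lam), stable for large lam."""
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def call_significant_peaks(
    peaks: List[PeakCall],
    fdr_max: float = DEFAULT_FDR_MAX,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> List[PeakCall]:
    """Flag one sample's candidate peaks as significant or not.

    Enrichment is the library-size-scaled IP/control ratio with a +1
    pseudocount on the control; the p-value is the Poisson upper tail of the
    IP count at the depth-scaled control rate; q-values are BH over the
    sample's peaks.  A peak is significant iff q < ``fdr_max`` and
    enrichment >= ``min_fold``.
    """
    if not peaks:
        return []
    samples = {p.sample_id for p in peaks}
    if len(samples) > 1:
        raise ValueError(f"peaks from multiple samples: {sorted(samples)}")
    pvals = []
    for p in peaks:
        scale = p.ip_libsize / p.control_libsize
        lam = (p.control_count + 1) * scale
        p.enrichment = (p.ip_count / p.ip_libsize) / (
            (p.control_count + 1) / p.control_libsize
        )
        p.pvalue = poisson_tail(p.ip_count, lam)
        pvals.append(p.pvalue)
    qvals = bh_fdr(pvals)
    for p, q in zip(peaks, qvals):
        p.qvalue = q
        p.significant = bool(q < fdr_max and p.enrichment >= min_fold)
    return peaks


# ---------------------------------------------------------------------------
# merging and counting

def merge_regions(intervals: Iterable[GenomicInterval]) -> List[MergedRegion]:
    """Merge overlapping intervals into the minimal disjoint cover.

    Two intervals merge iff they share at least one base (half-open overlap);
    adjacent (touching) intervals stay separate.  Output is sorted by
    (chrom, start) with deterministic ids ``chrom:start-end`` (0-based
    half-open, matching the BED columns written downstream).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[MergedRegion] = []
    cur: Optional[Tuple[str, int, int]] = None
    for iv in ivs:
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end))
        else:
            if cur is not None:
                merged.append(_mk_region(*cur))
            cur = (iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(_mk_region(*cur))
    return merged


def _mk_region(chrom: str, start: int, end: int) -> MergedRegion:
    return MergedRegion(
        region_id=f"{chrom}:{start}-{end}",
        interval=GenomicInterval(chrom, start, end),
    )


def count_fragments(
    fragments: Iterable[GenomicInterval],
    regions: List[MergedRegion],
) -> np.ndarray:
    """Count fragments overlapping each region (>=1 shared base).

    A fragment overlapping two disjoint regions increments both.  Regions
    must be disjoint (the output of :func:`merge_regions`).  Returns an
    integer vector aligned with ``regions``.
    """
    by_chrom: Dict[str, List[int]] = {}
    for idx, reg in enumerate(regions):
        by_chrom.setdefault(reg.interval.chrom, []).append(idx)
    index = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: regions[i].interval.start)
        starts = np.array([regions[i].interval.start for i in idxs])
        ends = np.array([regions[i].interval.end for i in idxs])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("regions must be disjoint")
        index[chrom] = (starts, ends, np.array(idxs))

    counts = np.zeros(len(regions), dtype=np.int64)
    frags_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    known_chroms = set(index)
    for frag in fragments:
        frags_by_chrom.setdefault(frag.chrom, []).append((frag.start, frag.end))
    for chrom, spans in frags_by_chrom.items():
        if chrom not in known_chroms:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        starts, ends, idxs = index[chrom]
        fs = np.array([s for s, _ in spans])
        fe = np.array([e for _, e in spans])
        # overlapping regions form the contiguous run [lo, hi)
        lo = np.searchsorted(ends, fs, side="right")
        hi = np.searchsorted(starts, fe, side="left")
        diff = np.zeros(len(starts) + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        counts[idxs] += np.cumsum(diff[:-1])
    return counts


def normalize_top30(
    raw: pd.DataFrame, top_fraction: float = DEFAULT_TOP_FRACTION
) -> pd.DataFrame:
    """Cross-condition peak normalization via shared top-ranked peaks.

    Per condition, regions are ranked by count (descending, ties broken by
    region id); the scaling denominator for a condition is the summed counts
    of regions ranked in the top ``top_fraction`` in *every* condition.
    Columns are rescaled by the mean denominator so magnitudes stay
    read-like.  ``raw`` is a region x condition DataFrame.
    """
    n_regions = len(raw.index)
    need = math.ceil(1.0 / top_fraction)
    if n_regions < need:
        raise ValueError(f"need >= {need} regions for top_fraction={top_fraction}")
    k = math.ceil(top_fraction * n_regions)
    top_sets = []
    for cond in raw.columns:
        order = sorted(raw.index, key=lambda r: (-raw.at[r, cond], r))
        top_sets.append(set(order[:k]))
    shared = set.intersection(*top_sets)
    if not shared:
        raise ValueError(
            "no region ranks in the top fraction of every condition; "
            "increase top_fraction"
        )
    sums = raw.loc[sorted(shared)].sum(axis=0).astype(float)
    return raw / sums * sums.mean()


# ---------------------------------------------------------------------------
# PWM model and scanning

@dataclass
class PWM:
    """Position weight matrix over (A, C, G, T) with uniform background."""

    probs: np.ndarray  # L x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float = 0.0  # bits

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be an L x 4 matrix")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """L x 5 log2-odds matrix; column 4 (N) contributes score 0.

        Zero probabilities (possible with pseudocount 0) score -inf, i.e.
        any window containing a forbidden base never reaches a threshold.
        """
        with np.errstate(divide="ignore"):
            lods = np.log2(self.probs / self.background)
        return np.hstack([lods, np.zeros((self.length, 1))])

    def reverse_complement(self) -> "PWM":
        probs = self.probs[::-1, ::-1].copy()
        return PWM(probs, self.background[::-1].copy(), self.score_threshold)

    def max_score(self) -> float:
        with np.errstate(divide="ignore"):
            lods = np.log2(self.probs / self.background)
        return float(lods.max(axis=1).sum())


def build_pwm_from_consensus(
    consensus: str = P53_CONSENSUS, pseudocount: float = 0.01
) -> PWM:
    """Build a PWM from an IUPAC consensus string.

    Each position distributes probability uniformly over the code's bases,
    mixed with ``pseudocount`` x uniform and renormalized.  The default
    score threshold is the consensus score minus the largest possible
    single-position drop (i.e. the score of the worst single-base mismatch
    to the consensus).
    """
    rows = []
    for i, code in enumerate(consensus.upper()):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}")
        allowed = IUPAC[code]
        row = np.zeros(4)
        for base in allowed:
            row[_BASE_INDEX[base]] = 1.0 / len(allowed)
        row = (1 - pseudocount) * row + pseudocount * 0.25
        rows.append(row / row.sum())
    pwm = PWM(np.array(rows))
    with np.errstate(divide="ignore"):
        lods = np.log2(pwm.probs / pwm.background)
    best = lods.max(axis=1).sum()
    worst_drop = (lods.max(axis=1) - lods.min(axis=1)).max()
    pwm.score_threshold = float(best - worst_drop)
    return pwm


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    enc = lut[arr]
    if np.any(enc < 0):
        bad = seq[int(np.argmax(enc < 0))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return enc.astype(np.int64)


def _strand_scores(enc: np.ndarray, score_matrix: np.ndarray) -> np.ndarray:
    L = score_matrix.shape[0]
    n = enc.size - L + 1
    scores = np.zeros(n)
    for j in range(L):
        scores += score_matrix[j, enc[j : j + n]]
    return scores


def scan_pwm(
    sequence: str, pwm: PWM, threshold_bits: Optional[float] = None
) -> List[Tuple[int, str, float]]:
    """Scan both strands; return hits ``(offset, strand, score)``.

    Offsets are 0-based starts of the L-mer window in forward coordinates on
    both strands.  N bases contribute score 0 (background probability).
    """
    if threshold_bits is None:
        threshold_bits = pwm.score_threshold
    if len(sequence) < pwm.length:
        return []
    enc = encode_sequence(sequence)
    fwd = _strand_scores(enc, pwm.score_matrix)
    rev = _strand_scores(enc, pwm.reverse_complement().score_matrix)
    hits: List[Tuple[int, str, float]] = []
    for offset in range(fwd.size):
        if fwd[offset] >= threshold_bits:
            hits.append((offset, "+", float(fwd[offset])))
        if rev[offset] >= threshold_bits:
            hits.append((offset, "-", float(rev[offset])))
    return hits


def annotate_motifs(
    regions: List[MergedRegion],
    genome: Dict[str, str],
    pwm: PWM,
    threshold_bits: Optional[float] = None,
) -> List[MergedRegion]:
    """Set ``has_motif``/``motif_score`` by scanning each region's sequence.

    The scan is restricted to the region sequence: a motif straddling the
    region edge with fewer than L bases inside does not count.
    """
    for reg in regions:
        iv = reg.interval
        if iv.chrom not in genome:
            raise ValueError(f"region {reg.region_id} on unknown chromosome")
        if iv.end > len(genome[iv.chrom]):
            raise ValueError(f"region {reg.region_id} exceeds chromosome bounds")
        seq = genome[iv.chrom][iv.start : iv.end]
        hits = scan_pwm(seq, pwm, threshold_bits)
        reg.has_motif = bool(hits)
        reg.motif_score = max((s for _, _, s in hits), default=None)
    return regions


def write_merged_regions_tsv(regions: List[MergedRegion], path: str) -> None:
    conditions = sorted({c for r in regions for c in r.raw_counts})
    rows = []
    for r in regions:
        row = {
            "region_id": r.region_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "significant_in": ",".join(sorted(r.significant_in)),
            "has_motif": int(bool(r.has_motif)),
            "motif_score": "" if r.motif_score is None else f"{r.motif_score:.4f}",
        }
        for c in conditions:
            row[f"raw_{c}"] = r.raw_counts.get(c, 0)
            nd = r.norm_density.get(c)
            row[f"norm_{c}"] = "" if nd is None else f"{nd:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
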