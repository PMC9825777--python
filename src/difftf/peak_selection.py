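"""Differential peak selection: merge, count, test, classify, trim and split.

Turns two cell types' peak calls and read placements into labeled
A-specific / B-specific / shared / abandoned sites with chromosome-based
train/validation/test splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "Split",
    "CountedPeak",
    "DifferentialResult",
    "LabeledPeak",
    "Thresholds",
    "merge_peaks",
    "count_reads",
    "normalize_count",
    "differential_test",
    "benjamini_hochberg",
    "classify_peak",
    "trim_peak",
    "split_by_chromosome",
    "select_peaks",
    "load_differential_results",
]


class Label(str, Enum):
    A_SPECIFIC = "A_SPECIFIC"
    B_SPECIFIC = "B_SPECIFIC"
    SHARED = "SHARED"
    ABANDONED = "ABANDONED"


class Split(str, Enum):
    TRAIN = "TRAIN"
    VAL = "VAL"
    TEST = "TEST"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class CountedPeak:
    interval: GenomicInterval
    counts_A: int
    counts_B: int

    def __post_init__(self) -> None:
        if self.counts_A < 0 or self.counts_B < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class DifferentialResult:
    """Per-peak differential outcome; log2fc is B over A."""

    log2fc: float
    pvalue: float
    qvalue: float
    flagged: bool = False


@dataclass(frozen=True)
class LabeledPeak:
    interval: GenomicInterval
    label: Label
    split: Split = Split.TRAIN
    log2fc: float = 0.0
    qvalue: float = 1.0


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds; defaults follow the standard rule set
    (q < 0.05 with |log2FC| > 2 for specific, q > 0.1 with |log2FC| < 1 for
    shared)."""

    q_specific: float = 0.05
    lfc_specific: float = 2.0
    q_shared: float = 0.1
    lfc_shared: float = 1.0


def merge_peaks(
    peaks_A: Sequence[GenomicInterval], peaks_B: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Union of overlapping intervals from both cell types, sorted and disjoint."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in list(peaks_A) + list(peaks_B):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # touching intervals merge too
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def count_reads(
    merged: Sequence[GenomicInterval],
    reads_A: Sequence[GenomicInterval],
    reads_B: Sequence[GenomicInterval],
    mode: str = "midpoint",
) -> list[CountedPeak]:
    """Count reads per merged peak.

    ``mode="midpoint"`` (default) counts a read for a peak iff its fragment
    midpoint lies within the half-open peak interval; ``mode="overlap"``
    counts any overlap (a read may then hit at most one peak because merged
    peaks are disjoint, assignment goes to the leftmost overlapping peak).
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"unknown counting mode {mode!r}")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    index: dict[str, list[int]] = {}
    for i, iv in enumerate(merged):
        index.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in index.items():
        starts[chrom] = np.array([merged[i].start for i in idxs])
        ends[chrom] = np.array([merged[i].end for i in idxs])

    def tally(reads: Sequence[GenomicInterval]) -> np.ndarray:
        counts = np.zeros(len(merged), dtype=np.int64)
        for read in reads:
            if read.chrom not in starts:
                continue
            s, e = starts[read.chrom], ends[read.chrom]
            if mode == "midpoint":
                mid = read.midpoint
                j = int(np.searchsorted(s, mid, side="right")) - 1
                if j >= 0 and mid < e[j]:
                    counts[index[read.chrom][j]] += 1
            else:
                j = int(np.searchsorted(e, read.start, side="right"))
                if j < len(s) and read.end > s[j]:
                    counts[index[read.chrom][j]] += 1
        return counts

    cA, cB = tally(reads_A), tally(reads_B)
    return [
        CountedPeak(iv, int(a), int(b)) for iv, a, b in zip(merged, cA, cB)
    ]


def normalize_count(M_i: float, N: float, L_i: float) -> float:
    """Depth- and length-normalized peak count: M / (N * L) * 1e9."""
    if N <= 0 or L_i <= 0:
        raise ValueError(f"N and L must be positive (got N={N}, L={L_i})")
    return M_i / (N * L_i) * 1e9


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def differential_test(
    counted: Sequence[CountedPeak],
    size_factors: tuple[float, float] | None = None,
    pseudocount: float = 1.0,
    dispersion: float | None = None,
) -> list[DifferentialResult]:
    """Negative-binomial Wald-style two-condition test per peak.

    A documented stand-in for a full count-model fit: log2 fold-changes use a
    pseudocount on library-size-normalized counts, a single shared dispersion
    is estimated across peaks by method of moments (median-based, robust to a
    minority of truly differential peaks) and p-values come from a Wald
    z-statistic on the log-mean difference. BH correction yields q-values.

    ``size_factors`` scales each condition's counts; by default they are
    derived from the conditions' total counts over peaks (pass ``(1.0, 1.0)``
    to test raw counts).
    """
    if len(counted) < 2:
        raise ValueError("need at least 2 peaks for a differential test")
    cA = np.array([c.counts_A for c in counted], dtype=float)
    cB = np.array([c.counts_B for c in counted], dtype=float)
    if size_factors is None:
        tot_A, tot_B = cA.sum(), cB.sum()
        if tot_A == 0 or tot_B == 0:
            raise ValueError("cannot derive size factors from all-zero counts")
        geo = np.sqrt(tot_A * tot_B)
        size_factors = (tot_A / geo, tot_B / geo)
    sA, sB = size_factors
    nA, nB = cA / sA, cB / sB

    if dispersion is None:
        # under the null the two normalized counts share a mean; excess of the
        # half squared difference over the mean estimates alpha * mean^2.
        # restrict to apparently non-differential peaks so that a large
        # truly-differential fraction cannot inflate the shared dispersion
        m = (nA + nB) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_i = ((nA - nB) ** 2 / 2.0 - m) / np.where(m > 0, m**2, np.nan)
        near_null = np.abs(np.log2((nB + pseudocount) / (nA + pseudocount))) < 1.0
        candidates = alpha_i[near_null & np.isfinite(alpha_i)]
        if candidates.size < 10:
            candidates = alpha_i[np.isfinite(alpha_i)]
        dispersion = (
            float(max(np.median(candidates), 1e-8)) if candidates.size else 1e-8
        )

    log2fc = np.log2((nB + pseudocount) / (nA + pseudocount))
    muA, muB = nA + pseudocount, nB + pseudocount
    # var(log mu_hat) ~ (mu + alpha mu^2) / mu^2 = 1/mu + alpha per condition
    se = np.sqrt(1.0 / muA + 1.0 / muB + 2.0 * dispersion) / np.log(2.0)
    z = log2fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    flagged = (cA == 0) & (cB == 0)
    pvals = np.where(flagged, 1.0, pvals)
    log2fc = np.where(flagged, 0.0, log2fc)
    qvals = benjamini_hochberg(pvals)
    return [
        DifferentialResult(float(l), float(p), float(q), bool(f))
        for l, p, q, f in zip(log2fc, pvals, qvals, flagged)
    ]


def load_differential_results(path: str) -> list[DifferentialResult]:
    """Load externally computed (log2fc, pvalue, qvalue) results from TSV.

    The file must carry a header with columns log2fc/log2FoldChange,
    pvalue and qvalue/padj; this bypasses the built-in test so results from a
    dedicated differential-count package can be plugged in directly.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    lfc = cols.get("log2fc") or cols.get("log2foldchange")
    p = cols.get("pvalue")
    q = cols.get("qvalue") or cols.get("padj")
    if not (lfc and p and q):
        raise ValueError(f"{path}: need log2fc/pvalue/qvalue columns")
    return [
        DifferentialResult(float(r[lfc]), float(r[p]), float(r[q]))
        for _, r in df.iterrows()
    ]


def classify_peak(
    result: DifferentialResult, thresholds: Thresholds = Thresholds()
) -> Label:
    """Map a differential result to a site label.

    q < 0.05 and log2FC < -2 -> A_SPECIFIC; q < 0.05 and log2FC > 2 ->
    B_SPECIFIC; q > 0.1 and |log2FC| < 1 -> SHARED; everything else
    ABANDONED. Thresholds are configurable.
    """
    t = thresholds
    if result.qvalue < t.q_specific and result.log2fc < -t.lfc_specific:
        return Label.A_SPECIFIC
    if result.qvalue < t.q_specific and result.log2fc > t.lfc_specific:
        return Label.B_SPECIFIC
    if result.qvalue > t.q_shared and abs(result.log2fc) < t.lfc_shared:
        return Label.SHARED
    return Label.ABANDONED


def trim_peak(
    interval: GenomicInterval,
    target_len: int = 600,
    chrom_size: int | None = None,
    use_summit: bool = False,
) -> GenomicInterval:
    """Trim (or extend) a peak to exactly ``target_len`` bp around its midpoint.

    The window is centered on the interval midpoint (or the narrowPeak summit
    when ``use_summit`` and a summit is recorded); odd remainders place the
    extra base on the right. Windows clipped by chromosome bounds are shifted
    to preserve the length.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if chrom_size is not None and chrom_size < target_len:
        raise ValueError(
            f"chromosome {interval.chrom} ({chrom_size} bp) shorter than "
            f"target length {target_len}"
        )
    if use_summit and interval.summit is not None:
        center = interval.start + interval.summit
    else:
        center = interval.midpoint
    start = center - target_len // 2
    end = start + target_len
    if start < 0:
        start, end = 0, target_len
    if chrom_size is not None and end > chrom_size:
        end = chrom_size
        start = end - target_len
    return GenomicInterval(interval.chrom, start, end, interval.strand)


_TEST_CHROMS = {"chr8", "chr16"}
_VAL_CHROMS = {"chr18"}
_EXCLUDED_CHROMS = {"chrY"}


def split_by_chromosome(peaks: Sequence[LabeledPeak]) -> list[LabeledPeak]:
    """Assign splits: chr8/chr16 -> TEST, chr18 -> VAL, chrY -> EXCLUDED,
    everything else -> TRAIN."""
    out: list[LabeledPeak] = []
    for peak in peaks:
        chrom = peak.interval.chrom
        if not chrom.startswith("chr"):
            logger.warning("chromosome %r not chr-prefixed; assigning to TRAIN", chrom)
            split = Split.TRAIN
        elif chrom in _TEST_CHROMS:
            split = Split.TEST
        elif chrom in _VAL_CHROMS:
            split = Split.VAL
        elif chrom in _EXCLUDED_CHROMS:
            split = Split.EXCLUDED
        else:
            split = Split.TRAIN
        out.append(replace(peak, split=split))
    return out


def select_peaks(
    peaks_A: Sequence[GenomicInterval],
    peaks_B: Sequence[GenomicInterval],
    reads_A: Sequence[GenomicInterval],
    reads_B: Sequence[GenomicInterval],
    thresholds: Thresholds = Thresholds(),
    target_len: int = 600,
    chrom_sizes: dict[str, int] | None = None,
    size_factors: tuple[float, float] | None = None,
    results: Sequence[DifferentialResult] | None = None,
    counting_mode: str = "midpoint",
) -> list[LabeledPeak]:
    """Full selection pipeline: merge, count, test, classify, trim, split.

    ``results`` may carry externally computed differential results (aligned
    with the merged peak order) to bypass the built-in test.
    """
    merged = merge_peaks(peaks_A, peaks_B)
    counted = count_reads(merged, reads_A, reads_B, mode=counting_mode)
    if results is None:
        results = differential_test(counted, size_factors=size_factors)
    elif len(results) != len(merged):
        raise ValueError("external results must align with merged peaks")
    labeled = []
    for peak, res in zip(counted, results):
        size = chrom_sizes.get(peak.interval.chrom) if chrom_sizes else None
        trimmed = trim_peak(peak.interval, target_len, chrom_size=size)
        labeled.append(
            LabeledPeak(trimmed, classify_peak(res, thresholds),
                        log2fc=res.log2fc, qvalue=res.qvalue)
        )
    return split_by_chromosome(labeled)
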