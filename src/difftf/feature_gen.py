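"""The four feature families computed per labeled, trimmed peak:

- seq:   gapped k-mer counts (or CNN-derived features, see models.cnn)
- motif: top-3 PWM scan scores per cofactor motif over both strands
- chrom: min/mean/max of 15 chromatin landscapes in two cell types + diffs
- hic:   statistics of the top-k contact partners per cell type + diffs
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PWM, ContactMap, GenomicInterval, SignalTrack

__all__ = [
    "FeatureTable",
    "MotifScore",
    "pwm_scan",
    "motif_features",
    "chromatin_features",
    "interaction_features",
    "gapped_kmer_features",
    "assemble_features",
    "FAMILIES",
]

FAMILIES = ("seq", "motif", "chrom", "hic")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _one_hot(seq: str) -> np.ndarray:
    """L x 4 one-hot; ambiguous bases give all-zero rows."""
    out = np.zeros((len(seq), 4))
    for i, base in enumerate(seq):
        j = _BASE_INDEX.get(base)
        if j is not None:
            out[i, j] = 1.0
    return out


@dataclass
class FeatureTable:
    """Peaks x named features; column names are prefixed by family tag
    (``seq.``, ``motif.``, ``chrom.``, ``hic.``)."""

    data: pd.DataFrame
    labels: pd.Series | None = None

    def validate(self) -> None:
        if self.data.shape[0] < 1:
            raise ValueError("feature table must have at least one row")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        bad = [c for c in self.data.columns if c.split(".", 1)[0] not in FAMILIES]
        if bad:
            raise ValueError(f"columns without a known family tag: {bad}")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels must align with rows")

    @property
    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for col in self.data.columns:
            out.setdefault(col.split(".", 1)[0], []).append(col)
        return out

    def family_view(self, families: Sequence[str]) -> "FeatureTable":
        cols = [c for c in self.data.columns if c.split(".", 1)[0] in families]
        return FeatureTable(self.data[cols], labels=self.labels)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class MotifScore:
    pwm_id: str
    top_scores: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.top_scores) != 3:
            raise ValueError("exactly 3 top scores required")
        if list(self.top_scores) != sorted(self.top_scores, reverse=True):
            raise ValueError("top scores must be sorted descending")


def pwm_scan(seq: str, pwm: PWM) -> np.ndarray:
    """Score every window on the forward sequence and its reverse complement.

    Returns a (2, L - w + 1) array (row 0 forward, row 1 reverse complement);
    each score is the sum over window positions of the PWM weight of the
    observed base. Ambiguous bases contribute 0.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError(
            f"sequence length {len(seq)} shorter than PWM width {w}"
        )
    scores = np.empty((2, len(seq) - w + 1))
    for row, s in enumerate((seq, reverse_complement(seq))):
        onehot = _one_hot(s)  # L x 4
        per_base = onehot @ pwm.weights  # L x w: score of base i at motif col j
        windows = np.lib.stride_tricks.sliding_window_view(per_base, w, axis=0)
        scores[row] = windows[:, np.arange(w), np.arange(w)].sum(axis=1)
    return scores


def top_motif_scores(seq: str, pwm: PWM, k: int = 3) -> np.ndarray:
    scores = pwm_scan(seq, pwm).ravel()
    if scores.size < k:
        raise ValueError(
            f"only {scores.size} windows available, need {k}"
        )
    return np.sort(scores)[::-1][:k]


def motif_features(seq: str, pwms: Sequence[PWM]) -> np.ndarray:
    """Concatenated top-3 both-strand scan scores per PWM: length 3 * n."""
    if len(pwms) < 1:
        raise ValueError("need at least one PWM")
    return np.concatenate([top_motif_scores(seq, pwm) for pwm in pwms])


def motif_feature_names(pwms: Sequence[PWM]) -> list[str]:
    return [f"motif.{pwm.id}.top{i + 1}" for pwm in pwms for i in range(3)]


_STATS = ("min", "mean", "max")


def chromatin_features(
    peak: GenomicInterval,
    tracks: Mapping[tuple[str, str], SignalTrack],
    cell_types: tuple[str, str],
    assays: Sequence[str],
) -> np.ndarray:
    """Per-assay, per-cell (min, mean, max) of per-base signal over the peak,
    followed by per-assay between-cell differences of each statistic.

    With 15 assays and 2 cell types this yields 2*15*3 + 15*3 = 135 values.
    Ordering matches :func:`chromatin_feature_names`.
    """
    missing = [
        (cell, assay)
        for assay in assays
        for cell in cell_types
        if (cell, assay) not in tracks
    ]
    if missing:
        raise KeyError(f"missing signal tracks: {missing}")
    per_cell = []
    diffs = []
    for assay in assays:
        stats_by_cell = []
        for cell in cell_types:
            vals = tracks[(cell, assay)].values(peak.chrom, peak.start, peak.end)
            stats_by_cell.append(
                (float(vals.min()), float(vals.mean()), float(vals.max()))
            )
        per_cell.extend(stats_by_cell[0])
        per_cell.extend(stats_by_cell[1])
        diffs.extend(a - b for a, b in zip(stats_by_cell[0], stats_by_cell[1]))
    return np.array(per_cell + diffs)


def chromatin_feature_names(
    cell_types: tuple[str, str], assays: Sequence[str]
) -> list[str]:
    names = [
        f"chrom.{assay}.{cell}.{stat}"
        for assay in assays
        for cell in cell_types
        for stat in _STATS
    ]
    names += [f"chrom.{assay}.diff.{stat}" for assay in assays for stat in _STATS]
    return names


def interaction_features(
    peak: GenomicInterval,
    contacts_A: ContactMap,
    contacts_B: ContactMap,
    k: int = 20,
    pad_missing: bool = False,
) -> np.ndarray:
    """Top-k contact partner statistics per cell type, plus A - B differences.

    For each map: locate the bin containing the peak midpoint, rank partner
    bins by contact count (ties broken toward the leftmost bin), keep the top
    k, and emit (min, mean, max) of the kept counts and of the genomic
    distances |partner bin start - peak bin start|. 6 values per cell type
    plus 6 differences = 18 total.

    If a bin has fewer than k partners the available ones are used; with
    ``pad_missing`` the count/distance lists are instead zero-padded to k.
    A bin without any contacts yields six zeros for that cell type.
    """
    if contacts_A.resolution != contacts_B.resolution:
        raise ValueError("contact maps must share resolution")
    res = contacts_A.resolution
    peak_bin = (peak.midpoint // res) * res

    def stats_for(cmap: ContactMap) -> np.ndarray:
        bins, counts = cmap.partners(peak.chrom, peak_bin)
        if counts.size == 0:
            return np.zeros(6)
        # stable sort on (-count, bin) -> ties leftmost-first
        order = np.lexsort((bins, -counts))[:k]
        kept_counts = counts[order]
        kept_dists = np.abs(bins[order] - peak_bin).astype(float)
        if pad_missing and kept_counts.size < k:
            padding = k - kept_counts.size
            kept_counts = np.pad(kept_counts, (0, padding))
            kept_dists = np.pad(kept_dists, (0, padding))
        return np.array(
            [
                kept_counts.min(), kept_counts.mean(), kept_counts.max(),
                kept_dists.min(), kept_dists.mean(), kept_dists.max(),
            ]
        )

    a, b = stats_for(contacts_A), stats_for(contacts_B)
    return np.concatenate([a, b, a - b])


def interaction_feature_names(cell_types: tuple[str, str] = ("A", "B")) -> list[str]:
    names = []
    for cell in (*cell_types, "diff"):
        for quantity in ("count", "distance"):
            names += [f"hic.{quantity}.{cell}.{stat}" for stat in _STATS]
    return names


def gapped_kmer_features(seq: str, l: int = 6, k: int = 4) -> np.ndarray:
    """Gapped k-mer counts: for every choice of k informative positions out of
    a length-l window and every k-letter word, the number of matching windows
    on the forward strand plus the reverse complement.

    Vector length C(l, k) * 4**k; windows containing ambiguous bases are
    skipped.
    """
    if k > l:
        raise ValueError(f"k ({k}) must not exceed l ({l})")
    if l > len(seq):
        raise ValueError(f"l ({l}) exceeds sequence length {len(seq)}")
    position_sets = list(combinations(range(l), k))
    counts = np.zeros((len(position_sets), 4**k), dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for s in (seq, reverse_complement(seq)):
        codes = np.array([_BASE_INDEX.get(b, -1) for b in s], dtype=np.int64)
        if codes.size < l:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, l)
        valid = ~(windows < 0).any(axis=1)
        windows = windows[valid]
        if windows.size == 0:
            continue
        for p, positions in enumerate(position_sets):
            word_codes = windows[:, positions] @ weights
            counts[p] += np.bincount(word_codes, minlength=4**k)
    return counts.ravel().astype(float)


def gapped_kmer_dim(l: int, k: int) -> int:
    return comb(l, k) * 4**k


def gapped_kmer_feature_names(l: int = 6, k: int = 4) -> list[str]:
    alphabet = "ACGT"
    names = []
    for positions in combinations(range(l), k):
        tag = "".join(str(p) for p in positions)
        for word_idx in range(4**k):
            word = "".join(
                alphabet[(word_idx // 4**(k - 1 - i)) % 4] for i in range(k)
            )
            names.append(f"seq.gkm.p{tag}.{word}")
    return names


def assemble_features(
    peak_ids: Sequence[str],
    family_blocks: Mapping[str, tuple[np.ndarray, Sequence[str]]],
    labels: Sequence | None = None,
    include_seq: bool = False,
) -> FeatureTable:
    """Column-wise concatenation of per-family feature blocks.

    ``family_blocks`` maps family -> (n_peaks x width matrix, column names).
    By default the ``seq`` family is excluded from the assembled table (it is
    dropped from the default boosted-trees configuration); pass
    ``include_seq=True`` to keep it.
    """
    blocks = []
    names: list[str] = []
    for family in FAMILIES:
        if family not in family_blocks:
            continue
        if family == "seq" and not include_seq:
            continue
        matrix, cols = family_blocks[family]
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != len(peak_ids):
            raise ValueError(
                f"family {family!r}: expected {len(peak_ids)} rows, "
                f"got shape {matrix.shape}"
            )
        if matrix.shape[1] != len(cols):
            raise ValueError(f"family {family!r}: name/width mismatch")
        blocks.append(matrix)
        names.extend(cols)
    if not blocks:
        raise ValueError("no feature families to assemble")
    df = pd.DataFrame(np.hstack(blocks), index=list(peak_ids), columns=names)
    series = pd.Series(list(labels), index=df.index) if labels is not None else None
    table = FeatureTable(df, labels=series)
    table.validate()
    return table
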