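"""Comparative analyses: per-peak signal correlations, Jaccard distances and
cross-factor / unified-model evaluation protocols."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from ..io_formats import GenomicInterval, SignalTrack

__all__ = [
    "pearson_signal_correlation",
    "summarize_correlation_by_label",
    "jaccard_distance",
    "CrossFactorReport",
    "cross_factor_eval",
    "train_unified",
]


def pearson_signal_correlation(
    peaks: Sequence[GenomicInterval],
    track_A: SignalTrack,
    track_B: SignalTrack,
) -> np.ndarray:
    """Pearson r of the two per-base signal vectors over each peak.

    Peaks where either vector has zero variance yield NaN (undefined r);
    callers exclude NaNs from summaries.
    """
    out = np.full(len(peaks), np.nan)
    for i, peak in enumerate(peaks):
        a = track_A.values(peak.chrom, peak.start, peak.end)
        b = track_B.values(peak.chrom, peak.start, peak.end)
        if a.std() == 0.0 or b.std() == 0.0:
            continue
        out[i] = float(np.corrcoef(a, b)[0, 1])
    return out


def summarize_correlation_by_label(
    r_values: np.ndarray, labels: Sequence
) -> dict[str, float]:
    """Median r per label class, NaNs excluded."""
    summary = {}
    labels = np.asarray([str(l) for l in labels])
    for label in np.unique(labels):
        vals = r_values[(labels == label) & ~np.isnan(r_values)]
        summary[label] = float(np.median(vals)) if vals.size else float("nan")
    return summary


def _interval_union(intervals: Sequence[GenomicInterval]) -> dict[str, list]:
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for start, end in spans[1:]:
            if start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = out
    return merged


def jaccard_distance(
    peaks_X: Sequence[GenomicInterval], peaks_Y: Sequence[GenomicInterval]
) -> float:
    """1 - (base pairs in the intersection of the two interval-set unions) /
    (base pairs in their union)."""
    if not peaks_X and not peaks_Y:
        raise ValueError("both interval sets are empty")
    ux, uy = _interval_union(peaks_X), _interval_union(peaks_Y)
    inter = 0
    total_x = sum(e - s for spans in ux.values() for s, e in spans)
    total_y = sum(e - s for spans in uy.values() for s, e in spans)
    for chrom in set(ux) & set(uy):
        xs, ys = ux[chrom], uy[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if e > s:
                inter += e - s
            if xs[i][1] <= ys[j][1]:
                i += 1
            else:
                j += 1
    union = total_x + total_y - inter
    return 1.0 - inter / union


@dataclass
class CrossFactorReport:
    prauc: pd.DataFrame  # rows = training factor, cols = test factor
    jaccard_specific: pd.DataFrame | None = None
    jaccard_shared: pd.DataFrame | None = None

    @property
    def off_diagonal_mean_prauc(self) -> float:
        m = self.prauc.to_numpy()
        mask = ~np.eye(m.shape[0], dtype=bool)
        return float(m[mask].mean())


def cross_factor_eval(
    scorers: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    test_sets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    specific_peaks: Mapping[str, Sequence[GenomicInterval]] | None = None,
    shared_peaks: Mapping[str, Sequence[GenomicInterval]] | None = None,
) -> CrossFactorReport:
    """Evaluate every factor's trained scorer on every factor's test set.

    ``scorers`` maps factor -> function producing positive-class scores for a
    feature/encoding matrix; all factors must share one feature schema (a
    shape mismatch raises with a remediation hint). Optional peak sets add
    Jaccard-distance matrices for the specific and shared classes.
    """
    factors = list(scorers)
    if set(factors) != set(test_sets):
        raise ValueError("scorers and test_sets must cover the same factors")
    prauc = pd.DataFrame(index=factors, columns=factors, dtype=float)
    for train_factor in factors:
        for test_factor in factors:
            X, y = test_sets[test_factor]
            try:
                scores = scorers[train_factor](X)
            except ValueError as exc:
                raise ValueError(
                    f"scorer for {train_factor!r} rejected features of "
                    f"{test_factor!r}: {exc}. Cross-factor evaluation needs a "
                    "shared feature schema; recompute motif features against "
                    "a common pooled PWM panel."
                ) from exc
            prauc.loc[train_factor, test_factor] = float(
                average_precision_score(y, scores)
            )

    def jaccard_matrix(peak_sets):
        m = pd.DataFrame(0.0, index=factors, columns=factors)
        for a in factors:
            for b in factors:
                if a != b:
                    m.loc[a, b] = jaccard_distance(peak_sets[a], peak_sets[b])
        return m

    return CrossFactorReport(
        prauc=prauc,
        jaccard_specific=(
            jaccard_matrix(specific_peaks) if specific_peaks is not None else None
        ),
        jaccard_shared=(
            jaccard_matrix(shared_peaks) if shared_peaks is not None else None
        ),
    )


def train_unified(
    datasets: Mapping[str, Mapping[str, tuple]],
    held_out: str,
    train_fn: Callable,
    score_fn: Callable[[object, np.ndarray], np.ndarray],
) -> tuple[object, dict[str, float]]:
    """Leave-one-factor-out pooling protocol.

    ``datasets`` maps factor -> {"train": (X, y, ids), "val": (X, y, ids),
    "test": (X, y, ids)}. Training and validation rows are pooled over every
    factor except ``held_out``; the model from ``train_fn(train, val)`` is
    evaluated on the held-out factor's test split only. Peak-id disjointness
    between the pooled training rows and the held-out test rows is asserted.
    """
    if held_out not in datasets:
        raise ValueError(f"held-out factor {held_out!r} absent from datasets")
    if len(datasets) < 2:
        raise ValueError("need at least two factors")
    train_X, train_y, train_ids = [], [], []
    val_X, val_y = [], []
    for factor, splits in datasets.items():
        if factor == held_out:
            continue
        X, y, ids = splits["train"]
        train_X.append(np.asarray(X))
        train_y.append(np.asarray(y))
        train_ids.extend(ids)
        Xv, yv, _ = splits["val"]
        val_X.append(np.asarray(Xv))
        val_y.append(np.asarray(yv))
    X_test, y_test, test_ids = datasets[held_out]["test"]
    leakage = set(train_ids) & set(test_ids)
    if leakage:
        raise ValueError(f"peak ids shared between training and held-out test: "
                         f"{sorted(leakage)[:5]}...")
    model = train_fn(
        (np.concatenate(train_X), np.concatenate(train_y)),
        (np.concatenate(val_X), np.concatenate(val_y)),
    )
    scores = score_fn(model, np.asarray(X_test))
    from sklearn.metrics import roc_auc_score

    metrics = {
        "AUC": float(roc_auc_score(y_test, scores)),
        "PRAUC": float(average_precision_score(y_test, scores)),
        "n_train": int(sum(len(y) for y in train_y)),
    }
    return model, metrics
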