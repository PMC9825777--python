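"""High-level in-memory plumbing tying the modules together: task label
mapping, bundle encoding and feature-table construction."""

from __future__ import annotations

import numpy as np

from . import feature_gen
from .io_formats import GenomicInterval
from .models import encoding
from .peak_selection import Label, Split
from .synth import ASSAYS, CELL_TYPES, Bundle

__all__ = ["TASK_LABELS", "task_labels", "encode_bundle",
           "bundle_feature_table", "chromosome_splits"]

# binary probability convention: class 1 is the second-listed class of each
# task (task A: B-specific = 1; task B: shared = 1)
TASK_LABELS: dict[str, dict[str, int]] = {
    "A": {"A_SPECIFIC": 0, "B_SPECIFIC": 1},
    "B": {"A_SPECIFIC": 0, "B_SPECIFIC": 0, "SHARED": 1},
    "C": {"A_SPECIFIC": 0, "B_SPECIFIC": 1, "SHARED": 2},
}


def task_labels(labels, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Map site labels to task labels; returns (values, keep mask)."""
    mapping = TASK_LABELS[task]
    names = [l.value if isinstance(l, Label) else str(l) for l in labels]
    keep = np.array([n in mapping for n in names])
    values = np.array([mapping[n] for n in names if n in mapping], dtype=int)
    return values, keep


def _peak_sequences(bundle: Bundle, peaks) -> list[str]:
    return [bundle.genome[p.chrom][p.start : p.end] for p in peaks]


def encode_bundle(
    bundle: Bundle,
    variant: str = "plus",
    peaks: list[GenomicInterval] | None = None,
    transform: bool = True,
    channels: str = "all",
) -> np.ndarray:
    """Encode bundle peaks as (N, L, C) channel matrices.

    ``variant`` is ``plain`` (sequence only), ``plus`` (sequence + DNase) or
    ``all`` (sequence + the full landscape panel). For the ``plus`` variant,
    ``channels`` restricts the accessibility channels for ablations: ``all``
    (both cells + difference), ``diff`` (difference only), ``cellA`` or
    ``cellB`` (one cell's signal only).
    """
    peaks = bundle.peaks if peaks is None else peaks
    seqs = _peak_sequences(bundle, peaks)
    if variant == "plain":
        return np.array([encoding.one_hot(s) for s in seqs])
    if variant == "plus":
        track_a = bundle.tracks[("cellA", "DNase")]
        track_b = bundle.tracks[("cellB", "DNase")]
        rows = []
        for seq, peak in zip(seqs, peaks):
            a = track_a.values(peak.chrom, peak.start, peak.end)
            b = track_b.values(peak.chrom, peak.start, peak.end)
            full = encoding.encode_cnn_plus(seq, a, b, transform=transform)
            if channels == "all":
                rows.append(full)
            elif channels == "diff":
                rows.append(full[:, [0, 1, 2, 3, 6]])
            elif channels == "cellA":
                rows.append(full[:, [0, 1, 2, 3, 4]])
            elif channels == "cellB":
                rows.append(full[:, [0, 1, 2, 3, 5]])
            else:
                raise ValueError(f"unknown channel selection {channels!r}")
        return np.array(rows)
    if variant == "all":
        rows = []
        for seq, peak in zip(seqs, peaks):
            tracks = {
                key: track.values(peak.chrom, peak.start, peak.end)
                for key, track in bundle.tracks.items()
            }
            rows.append(
                encoding.encode_cnn_all(
                    seq, tracks, CELL_TYPES, list(ASSAYS), transform=transform
                )
            )
        return np.array(rows)
    raise ValueError(f"unknown variant {variant!r}")


def bundle_feature_table(
    bundle: Bundle,
    peaks: list[GenomicInterval] | None = None,
    labels=None,
    include_seq: bool = False,
) -> feature_gen.FeatureTable:
    """Motif + chromatin + interaction features (and optionally gapped
    k-mers) for bundle peaks."""
    peaks = bundle.peaks if peaks is None else peaks
    labels = bundle.labels if labels is None else labels
    seqs = _peak_sequences(bundle, peaks)
    blocks = {
        "motif": (
            np.array([feature_gen.motif_features(s, bundle.pwms) for s in seqs]),
            feature_gen.motif_feature_names(bundle.pwms),
        ),
        "chrom": (
            np.array(
                [
                    feature_gen.chromatin_features(
                        p, bundle.tracks, CELL_TYPES, list(ASSAYS)
                    )
                    for p in peaks
                ]
            ),
            feature_gen.chromatin_feature_names(CELL_TYPES, list(ASSAYS)),
        ),
        "hic": (
            np.array(
                [
                    feature_gen.interaction_features(
                        p, bundle.contacts["cellA"], bundle.contacts["cellB"]
                    )
                    for p in peaks
                ]
            ),
            feature_gen.interaction_feature_names(),
        ),
    }
    if include_seq:
        blocks["seq"] = (
            np.array([feature_gen.gapped_kmer_features(s) for s in seqs]),
            feature_gen.gapped_kmer_feature_names(),
        )
    ids = [f"{p.chrom}:{p.start}-{p.end}" for p in peaks]
    label_names = [l.value if isinstance(l, Label) else str(l) for l in labels]
    return feature_gen.assemble_features(
        ids, blocks, labels=label_names, include_seq=include_seq
    )


def chromosome_splits(peaks) -> np.ndarray:
    """Split assignment per peak by the chr8/chr16 test, chr18 validation
    convention."""
    out = []
    for p in peaks:
        if p.chrom in ("chr8", "chr16"):
            out.append(Split.TEST.value)
        elif p.chrom == "chr18":
            out.append(Split.VAL.value)
        elif p.chrom == "chrY":
            out.append(Split.EXCLUDED.value)
        else:
            out.append(Split.TRAIN.value)
    return np.array(out)
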