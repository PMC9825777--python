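"""Channel encodings of sequence and chromatin signal for the CNN models.

Encodings are L x C matrices: the first four channels are the one-hot
sequence; accessibility variants append per-cell signal channels and their
between-cell difference.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = ["one_hot", "encode_cnn_plus", "encode_cnn_all", "scale_signal"]

_ENCODING = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}


def one_hot(seq: str) -> np.ndarray:
    """L x 4 one-hot encoding (A, C, G, T columns); N gives an all-zero row."""
    if not seq:
        return np.zeros((0, 4))
    try:
        return np.array([_ENCODING[b] for b in seq])
    except KeyError:
        for i, b in enumerate(seq):
            if b not in _ENCODING:
                raise ValueError(
                    f"invalid base {b!r} at position {i}"
                ) from None
        raise


def scale_signal(values: np.ndarray, max_value: float | None = None) -> np.ndarray:
    """Variance-stabilize raw signal: arcsinh transform then scale to [0, 1].

    ``max_value`` is the (post-arcsinh) normalizer; pass the training-set
    maximum so that train/val/test share one scale. ``None`` uses the array's
    own maximum.
    """
    transformed = np.arcsinh(np.asarray(values, dtype=float))
    if max_value is None:
        max_value = float(transformed.max())
    if max_value > 0:
        transformed = transformed / max_value
    return transformed


def encode_cnn_plus(
    seq: str,
    dnase_A: np.ndarray | None,
    dnase_B: np.ndarray | None,
    transform: bool = False,
) -> np.ndarray:
    """L x 7 encoding: [one-hot x4, dnase_A, dnase_B, dnase_A - dnase_B].

    Passing ``None`` for both signal arguments reproduces the L x 4
    sequence-only encoding of the plain CNN baseline. ``transform`` applies
    :func:`scale_signal` to each accessibility channel before the difference
    channel is computed.
    """
    onehot = one_hot(seq)
    if dnase_A is None and dnase_B is None:
        return onehot
    if dnase_A is None or dnase_B is None:
        raise ValueError("provide accessibility for both cell types or neither")
    a = np.asarray(dnase_A, dtype=float)
    b = np.asarray(dnase_B, dtype=float)
    if len(seq) != a.size or len(seq) != b.size:
        raise ValueError(
            f"length mismatch: seq={len(seq)}, dnase_A={a.size}, dnase_B={b.size}"
        )
    if transform:
        a, b = scale_signal(a), scale_signal(b)
    return np.column_stack([onehot, a, b, a - b])


def encode_cnn_all(
    seq: str,
    tracks: Mapping[tuple[str, str], np.ndarray],
    cell_types: tuple[str, str],
    assays: Sequence[str],
    transform: bool = False,
) -> np.ndarray:
    """L x (4 + 3 * n_assays) encoding mirroring the L x 7 design per assay.

    ``tracks`` maps (cell_type, assay) -> per-base values over the peak.
    Channels: one-hot x4, then per assay in order (cell A, cell B, A - B).
    With 15 assays the result has 49 channels.
    """
    blocks = [one_hot(seq)]
    cell_a, cell_b = cell_types
    for assay in assays:
        for cell in cell_types:
            if (cell, assay) not in tracks:
                raise KeyError(f"missing track for cell {cell!r}, assay {assay!r}")
        a = np.asarray(tracks[(cell_a, assay)], dtype=float)
        b = np.asarray(tracks[(cell_b, assay)], dtype=float)
        if a.size != len(seq) or b.size != len(seq):
            raise ValueError(f"track length mismatch for assay {assay!r}")
        if transform:
            a, b = scale_signal(a), scale_signal(b)
        blocks.append(np.column_stack([a, b, a - b]))
    return np.hstack(blocks)
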