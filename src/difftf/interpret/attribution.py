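"""Reference-based per-position contribution scores for the CNN models.

Contributions are propagated backward through the network with the rescale
rule: affine layers split an output's contribution across inputs in
proportion to each input's weighted activation difference from the
reference, and elementwise nonlinearities pass contributions through
unchanged. Because every layer redistributes its incoming contribution
exactly, the per-input contributions sum to the difference between the
model's logit on the input and on the reference (completeness), which is
checked on every call.

Two references are supported: the input with its sequence channels zeroed
(``sequence_zeroed``) and the input with its chromatin channels zeroed
(``chromatin_zeroed``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..models.nn import Conv1D, ConvNet, Dense, Dropout, Flatten, MaxPool1D, ReLU

__all__ = ["ContributionProfile", "attribute", "rescale_contributions",
           "CompletenessError"]

REFERENCE_KINDS = ("sequence_zeroed", "chromatin_zeroed")

_EPS = 1e-12


class CompletenessError(RuntimeError):
    """Raised when contributions fail to sum to the output difference."""


@dataclass
class ContributionProfile:
    peak_id: str
    reference_kind: str
    contributions: np.ndarray  # length L, summed over channels
    per_channel: np.ndarray  # C x L
    completeness_gap: float


def _safe_ratio(contrib: np.ndarray, delta: np.ndarray) -> np.ndarray:
    scale = max(1.0, float(np.abs(delta).max(initial=0.0)))
    mask = np.abs(delta) > _EPS * scale
    out = np.zeros_like(delta)
    out[mask] = contrib[mask] / delta[mask]
    return out


def _backprop_dense(layer: Dense, d_in, d_out, contrib):
    ratio = _safe_ratio(contrib, d_out)  # (1, out)
    return d_in * (ratio @ layer.W)


def _backprop_conv(layer: Conv1D, d_in, d_out, contrib):
    k = layer.kernel
    ratio = _safe_ratio(contrib, d_out)  # (1, O, L')
    padded = np.pad(ratio, ((0, 0), (0, 0), (k - 1, k - 1)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, k, axis=2)
    spread = np.einsum("nopj,ocj->ncp", windows, layer.W[:, :, ::-1],
                       optimize=True)
    return d_in * spread


def _backprop_maxpool(layer: MaxPool1D, d_in, d_out, contrib):
    p = layer.width
    n, c, n_out = contrib.shape
    trimmed = d_in[:, :, : n_out * p].reshape(n, c, n_out, p)
    sums = trimmed.sum(axis=3, keepdims=True)
    abs_sums = np.abs(trimmed).sum(axis=3, keepdims=True)
    shares = np.where(
        np.abs(sums) > _EPS,
        trimmed / np.where(np.abs(sums) > _EPS, sums, 1.0),
        np.where(
            abs_sums > _EPS,
            np.abs(trimmed) / np.where(abs_sums > _EPS, abs_sums, 1.0),
            1.0 / p,
        ),
    )
    out = np.zeros_like(d_in)
    out[:, :, : n_out * p] = (shares * contrib[:, :, :, None]).reshape(n, c, -1)
    return out


def rescale_contributions(
    model: ConvNet, x: np.ndarray, reference: np.ndarray, output_index: int = 0
) -> tuple[np.ndarray, float]:
    """Per-channel, per-position contributions of ``x - reference`` to the
    chosen output logit.

    ``x`` and ``reference`` are C x L single examples. Returns the C x L
    contribution matrix and the achieved output delta (logit(x) minus
    logit(reference))."""
    xb, rb = x[None], reference[None]
    acts_x = model.forward_trace(xb)
    acts_r = model.forward_trace(rb)
    deltas = [ax - ar for ax, ar in zip(acts_x, acts_r)]
    output_delta = float(deltas[-1][0, output_index])
    contrib = np.zeros_like(deltas[-1])
    contrib[0, output_index] = output_delta
    for layer, d_in, d_out in zip(
        reversed(model.layers), reversed(deltas[:-1]), reversed(deltas[1:])
    ):
        if isinstance(layer, (ReLU, Dropout)):
            pass  # elementwise: contribution carried through unchanged
        elif isinstance(layer, Flatten):
            contrib = contrib.reshape(d_in.shape)
        elif isinstance(layer, Dense):
            contrib = _backprop_dense(layer, d_in, d_out, contrib)
        elif isinstance(layer, Conv1D):
            contrib = _backprop_conv(layer, d_in, d_out, contrib)
        elif isinstance(layer, MaxPool1D):
            contrib = _backprop_maxpool(layer, d_in, d_out, contrib)
        else:  # pragma: no cover - guards future layer types
            raise TypeError(f"no rescale rule for layer {type(layer).__name__}")
    return contrib[0], output_delta


def make_reference(
    encoded: np.ndarray, reference_kind: str, n_seq_channels: int = 4
) -> np.ndarray:
    """Build the attribution reference for an L x C encoded example."""
    if reference_kind not in REFERENCE_KINDS:
        raise ValueError(
            f"reference_kind must be one of {REFERENCE_KINDS}, got {reference_kind!r}"
        )
    ref = np.array(encoded, dtype=float, copy=True)
    if reference_kind == "sequence_zeroed":
        ref[:, :n_seq_channels] = 0.0
    else:
        ref[:, n_seq_channels:] = 0.0
    return ref


def attribute(
    model: ConvNet,
    encoded: np.ndarray,
    reference_kind: str,
    peak_id: str = "",
    n_seq_channels: int = 4,
    output_index: int = 0,
    tol: float = 1e-4,
) -> ContributionProfile:
    """Per-position contribution profile of one L x C encoded example.

    The reference zeroes either the sequence channels or the chromatin
    channels; the per-channel contribution matrix is summed over channels to
    a length-L vector. Raises :class:`CompletenessError` if the
    contributions do not add up to the logit difference within ``tol``.
    """
    if encoded.ndim != 2:
        raise ValueError("expected one L x C encoded example")
    if encoded.shape[1] != getattr(model, "in_channels", encoded.shape[1]):
        raise ValueError(
            f"example has {encoded.shape[1]} channels but the model expects "
            f"{model.in_channels}"
        )
    ref = make_reference(encoded, reference_kind, n_seq_channels)
    per_channel, output_delta = rescale_contributions(
        model, encoded.T, ref.T, output_index
    )
    gap = abs(float(per_channel.sum()) - output_delta)
    if gap > tol * max(1.0, abs(output_delta)):
        raise CompletenessError(
            f"contributions sum to {per_channel.sum():.6g} but the logit "
            f"difference is {output_delta:.6g} (gap {gap:.3g})"
        )
    return ContributionProfile(
        peak_id=peak_id,
        reference_kind=reference_kind,
        contributions=per_channel.sum(axis=0),
        per_channel=per_channel,
        completeness_gap=gap,
    )
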