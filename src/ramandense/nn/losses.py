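"""Softmax and categorical cross-entropy."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "categorical_cross_entropy", "softmax_cross_entropy_with_logits"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, computed with max-subtraction for stability.

    Invariant to adding a constant to every logit of a row; rows sum to 1.
    """
    z = np.asarray(logits, dtype=float)
    squeeze = z.ndim == 1
    if squeeze:
        z = z[None]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def categorical_cross_entropy(
    y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-7
) -> float:
    """-sum_i y_i log y'_i, averaged over rows for batched input.

    Predictions are clipped to ``[eps, 1]`` so a confidently wrong model
    yields a large finite loss instead of infinity.
    """
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    p = np.clip(p, eps, 1.0)
    if t.ndim == 1:
        return float(-(t * np.log(p)).sum())
    return float(-(t * np.log(p)).sum(axis=1).mean())


def softmax_cross_entropy_with_logits(
    logits: np.ndarray, y_true: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fused loss for training: returns (mean loss, probabilities, dlogits).

    The gradient of the mean cross-entropy w.r.t. the logits is
    ``(p - y)/batch``, which avoids the clipping kink in the separate
    formulation.
    """
    p = softmax(logits)
    t = np.asarray(y_true, dtype=p.dtype)
    n = p.shape[0]
    loss = float(-(t * np.log(np.clip(p, 1e-12, 1.0))).sum(axis=1).mean())
    dlogits = (p - t) / n
    return loss, p, dlogits.astype(logits.dtype)
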