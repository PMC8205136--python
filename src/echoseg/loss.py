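"""Expanded (ternary) cross-entropy loss over grey-level probability labels.

For a pixel with per-channel targets y^(k) in {0, 0.5, 1} and predictions
p^(k), the per-pixel information-entropy sums are

    E  = sum_k y^(k) * log p^(k)
    E' = sum_k (1 - y^(k)) * log(1 - p^(k)),        k = 1..3,

and the expanded cross-entropy of a batch of N elements is

    ECE = -(1/N) * sum_i (E_i + E'_i),

where within an element the per-pixel channel sums are averaged over pixels so
the loss magnitude is independent of image resolution.  On each channel the
per-pixel loss is the binary-cross-entropy form

    loss = -y * log p - (1 - y) * log(1 - p),

whose minimiser is p -> 1 for y = 1, p = 0.5 for y = 0.5 (minimum value
-0.5 * ln(1/4) = ln 2) and p -> 0 for y = 0.  Because the three channels carry
the same target, the 3-channel ECE at identical per-channel (y, p) is exactly
3x the single-channel binary cross-entropy — in value and in gradient — which
is the "expanded" update-rate property.

Natural logarithms throughout; predictions are clipped to
(eps, 1 - eps) with eps = 1e-7 before taking logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "DEFAULT_EPS",
    "pixel_entropy_terms",
    "expanded_cross_entropy",
    "expanded_cross_entropy_grad",
    "binary_cross_entropy",
    "per_pixel_case_loss",
    "update_rate_ratio",
    "BenignOptimum",
    "constrained_benign_minimum",
]

DEFAULT_EPS = 1e-7

_VALID_TARGETS = (0.0, 0.5, 1.0)


def _clip(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def _check_pair(targets: np.ndarray, preds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    targets = np.asarray(targets, dtype=float)
    preds = np.asarray(preds, dtype=float)
    if targets.shape != preds.shape:
        raise ValueError(
            f"target shape {targets.shape} does not match prediction shape "
            f"{preds.shape}")
    if targets.shape[-1] != 3:
        raise ValueError(
            f"expected 3 channels on the last axis, got {targets.shape[-1]}")
    if np.isnan(targets).any() or np.isnan(preds).any():
        raise ValueError("NaN values in targets or predictions")
    return targets, preds


def pixel_entropy_terms(y, p, eps: float = DEFAULT_EPS):
    """Per-pixel entropy sums (E, E') over the three channels.

    ``y`` and ``p`` are arrays whose last axis holds the 3 channels; the two
    sums are returned with that axis reduced.
    """
    y, p = _check_pair(y, p)
    p = _clip(p, eps)
    e = (y * np.log(p)).sum(axis=-1)
    e_prime = ((1.0 - y) * np.log1p(-p)).sum(axis=-1)
    return e, e_prime


def expanded_cross_entropy(targets, preds, eps: float = DEFAULT_EPS) -> float:
    """ECE of a batch: -(1/N) * sum_i mean-over-pixels(E_i + E'_i).

    ``targets`` and ``preds`` have shape ``(N, ..., 3)``: a leading batch axis,
    any number of pixel axes, and the channel axis last.  ``(3,)`` inputs are
    treated as a single pixel.
    """
    targets, preds = _check_pair(targets, preds)
    e, e_prime = pixel_entropy_terms(targets, preds, eps)
    per_pixel = -(e + e_prime)
    if per_pixel.ndim == 0:
        return float(per_pixel)
    # mean over pixel axes within each batch element, then mean over the batch
    per_element = per_pixel.reshape(per_pixel.shape[0], -1).mean(axis=1)
    return float(per_element.mean())


def expanded_cross_entropy_grad(targets, preds, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Gradient of :func:`expanded_cross_entropy` w.r.t. the predictions."""
    targets, preds = _check_pair(targets, preds)
    clipped = _clip(preds, eps)
    g = -targets / clipped + (1.0 - targets) / (1.0 - clipped)
    # zero gradient where the clip is active
    g[(preds < eps) | (preds > 1.0 - eps)] = 0.0
    if g.ndim > 1:
        n_pixels = int(np.prod(g.shape[1:-1])) or 1
        g = g / (g.shape[0] * n_pixels)
    return g


def binary_cross_entropy(y: float, p: float, eps: float = DEFAULT_EPS) -> float:
    """Single-channel binary cross-entropy -y log p - (1-y) log(1-p)."""
    p = float(np.clip(p, eps, 1.0 - eps))
    return float(-y * math.log(p) - (1.0 - y) * math.log(1.0 - p))


def per_pixel_case_loss(y_value: float, p, eps: float = DEFAULT_EPS):
    """Per-channel loss evaluated through its three-case analysis.

    y = 1  ->  -log p            (minimised as p -> 1)
    y = 0.5->  -0.5 log p(1-p)   (minimised at p = 0.5, value ln 2)
    y = 0  ->  -log(1 - p)       (minimised as p -> 0)

    Agrees with :func:`binary_cross_entropy` to machine precision.  ``p`` may
    be a scalar or an array (for, e.g., grid searches over the unit interval).
    """
    if y_value not in _VALID_TARGETS:
        raise ValueError(
            f"grey-level probability target must be one of {{0, 0.5, 1}}, "
            f"got {y_value!r}")
    scalar = np.isscalar(p)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    if y_value == 1.0:
        out = -np.log(p)
    elif y_value == 0.0:
        out = -np.log1p(-p)
    else:
        out = -0.5 * np.log(p * (1.0 - p))
    return float(out) if scalar else out


def update_rate_ratio(y: float, p: float, eps: float = DEFAULT_EPS) -> tuple[float, float]:
    """(loss ratio, gradient ratio) of 3-channel ECE to 1-channel BCE.

    Both ratios equal 3 for any target/prediction pair with the prediction
    strictly inside the clipping interval, because the three channels repeat
    the same term.
    """
    y3 = np.full(3, y)
    p3 = np.full(3, p)
    ece = expanded_cross_entropy(y3, p3, eps)
    bce = binary_cross_entropy(y, p, eps)
    g3 = expanded_cross_entropy_grad(y3, p3, eps)
    pc = float(np.clip(p, eps, 1.0 - eps))
    g1 = -y / pc + (1.0 - y) / (1.0 - pc)
    return ece / bce, float(g3.sum()) / g1


@dataclass(frozen=True)
class BenignOptimum:
    """Solution of the benign-label loss minimisation under a softmax head."""

    p: np.ndarray          #: per-channel optimum (sums to 1)
    grey: float            #: channel-mean grey value, mean(p) * 255
    alpha: float           #: grey reduction rate, grey / 127.5
    loss: float            #: minimised 3-channel loss value


def constrained_benign_minimum(eps: float = 1e-9) -> BenignOptimum:
    """Minimise the 3-channel benign loss subject to the softmax constraint.

    Solves min_p sum_k [-0.5 log p_k - 0.5 log(1 - p_k)] subject to
    p_1 + p_2 + p_3 = 1 with 0 < p_k < 1.  The objective is strictly convex
    on the simplex, so the optimum is unique: p = (1/3, 1/3, 1/3), grey
    mean(p) * 255 = 85 and grey reduction rate alpha = 85 / 127.5 ≈ 0.667.
    Solved numerically (SLSQP) rather than asserted.
    """

    def objective(p: np.ndarray) -> float:
        return float(-0.5 * (np.log(p) + np.log1p(-p)).sum())

    def gradient(p: np.ndarray) -> np.ndarray:
        return -0.5 / p + 0.5 / (1.0 - p)

    x0 = np.array([0.2, 0.3, 0.5])
    res = optimize.minimize(
        objective, x0, jac=gradient, method="SLSQP",
        bounds=[(eps, 1.0 - eps)] * 3,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones(3)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(
            f"constrained benign minimisation did not converge: {res.message} "
            f"(nit={res.nit}, x={res.x})")
    p_star = res.x
    grey = float(p_star.mean() * 255.0)
    return BenignOptimum(p=p_star, grey=grey, alpha=grey / 127.5,
                         loss=objective(p_star))
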