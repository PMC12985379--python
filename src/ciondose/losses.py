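"""Training losses: MSE plus three targeted components.

The composite loss is

    L = MSE + w_mask * MaskedMSE + w_depth * DepthLoss + w_region * RegionMaskedMSE

where MaskedMSE averages only voxels whose squared error exceeds a small
threshold (sharpening attention on the Bragg-peak region), DepthLoss is the
MSE of forward depth differences (penalizing wrong gradients along the beam
axis), and RegionMaskedMSE averages only voxels whose ground-truth value
exceeds 60% of the sample maximum (the peak region itself).

All functions accept either numpy arrays or autodiff Tensors; the selection
masks are treated as constants of the current iterate, so their gradient
contribution is zero (they are piecewise constant in the prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

#: Default squared-error threshold, in each target's scaled label units.
DEFAULT_EPS_SQ = 0.001
#: Default high-value region threshold as a fraction of the sample maximum.
DEFAULT_THETA_FRAC = 0.6


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three auxiliary components, each in [0, 1]."""

    w_mask: float = 0.0
    w_depth: float = 0.0
    w_region: float = 0.0

    def __post_init__(self) -> None:
        for w in (self.w_mask, self.w_depth, self.w_region):
            if not (0.0 <= w <= 1.0):
                raise ValueError("loss weights must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_mask, self.w_depth, self.w_region)


@dataclass(frozen=True)
class LossThresholds:
    eps_sq: float = DEFAULT_EPS_SQ
    theta_frac: float = DEFAULT_THETA_FRAC

    def __post_init__(self) -> None:
        if self.eps_sq <= 0:
            raise ValueError("eps_sq must be > 0")
        if not (0.0 < self.theta_frac < 1.0):
            raise ValueError("theta_frac must be in (0, 1)")


def weight_lattice(step: float = 0.2) -> list[LossWeights]:
    """The grid-search lattice: each weight in {0, 0.2, ..., 1.0}."""
    levels = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return [LossWeights(a, b, c) for a in levels for b in levels for c in levels]


def _raw(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _check_shapes(y, y_hat) -> None:
    if _raw(y).shape != _raw(y_hat).shape:
        raise ValueError(
            f"shape mismatch: {_raw(y).shape} vs {_raw(y_hat).shape}"
        )


def _scalar(x):
    return float(x) if not isinstance(x, Tensor) else x


def mse(y, y_hat):
    """Mean squared error over all voxels."""
    _check_shapes(y, y_hat)
    d = y_hat - y
    return _scalar((d * d).mean())


def masked_mse(y, y_hat, eps_sq: float = DEFAULT_EPS_SQ):
    """MSE over only the voxels whose squared error exceeds ``eps_sq``.

    Returns 0 when no voxel exceeds the threshold.
    """
    _check_shapes(y, y_hat)
    err2 = (_raw(y_hat) - _raw(y)) ** 2
    sel = err2 > eps_sq
    n = int(sel.sum())
    if n == 0:
        return 0.0
    d = (y_hat - y) * (Tensor(sel.astype(float)) if isinstance(y_hat, Tensor)
                       or isinstance(y, Tensor) else sel.astype(float))
    return _scalar((d * d).sum() * (1.0 / n))


def depth_gradient_loss(y, y_hat, dz: float = 1.0):
    """MSE of forward depth differences (last axis is depth).

    Voxel i is paired with its neighbour one step deeper; the mean runs over
    the voxels that have such a neighbour. Invariant under adding a constant
    to the prediction.
    """
    _check_shapes(y, y_hat)
    if _raw(y).shape[-1] < 2:
        raise ValueError("depth axis must have length >= 2")
    gy = (y[..., 1:] - y[..., :-1]) * (1.0 / dz)
    gyh = (y_hat[..., 1:] - y_hat[..., :-1]) * (1.0 / dz)
    d = gyh - gy
    return _scalar((d * d).mean())


def region_masked_mse(y, y_hat, theta_frac: float = DEFAULT_THETA_FRAC):
    """MSE over voxels where the ground truth exceeds ``theta_frac * max(y)``.

    The region is defined by the ground truth only, never by the prediction.
    """
    _check_shapes(y, y_hat)
    yr = _raw(y)
    ymax = yr.max()
    if ymax <= 0:
        raise ValueError("region_masked_mse requires max(y) > 0")
    sel = yr > theta_frac * ymax
    l = int(sel.sum())
    if l == 0:
        return 0.0
    d = (y_hat - y) * (Tensor(sel.astype(float)) if isinstance(y_hat, Tensor)
                       or isinstance(y, Tensor) else sel.astype(float))
    return _scalar((d * d).sum() * (1.0 / l))


def custom_loss(y, y_hat, weights: LossWeights,
                thresholds: LossThresholds = LossThresholds()):
    """Weighted sum of the four components; zero weights reduce to plain MSE."""
    total = mse(y, y_hat)
    if weights.w_mask:
        total = total + weights.w_mask * masked_mse(y, y_hat, thresholds.eps_sq)
    if weights.w_depth:
        total = total + weights.w_depth * depth_gradient_loss(y, y_hat)
    if weights.w_region:
        total = total + weights.w_region * region_masked_mse(
            y, y_hat, thresholds.theta_frac)
    return total
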