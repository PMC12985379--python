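"""Conversion of scored volumes into normalized, cropped training samples.

The pipeline is: crop to the model grid (lateral window centered on the
beam axis, fixed depth extent anchored at the proximal face), normalize the
CT window and the beam energy to [0, 1], threshold-mask the labels at 1% of
the dose maximum, and scale alpha by 10 and beta by 1e3 so that all three
label ranges are of order unity-to-tens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import physics
from .grids import CTVolume, DegenerateInputError, FieldVolume

#: Default model grid (lateral, lateral, depth) in 1 mm voxels.
MODEL_GRID = (24, 24, 240)

#: CT normalization window in HU.
HU_WINDOW = (-1000.0, 3000.0)

#: Label scaling factors applied before training (dose unscaled).
LABEL_SCALE = {"dose": 1.0, "alpha": 10.0, "beta": 1.0e3}

#: Mask threshold as a fraction of the thresholding-dose maximum.
MASK_THRESHOLD_FRACTION = 0.01

HU_AIR_PAD = -1000.0


@dataclass
class MaskVolume:
    """Boolean region above 1% of a dose maximum.

    ``source`` records whether the thresholding dose was the ground truth
    ("MC") or the dose-model prediction ("AI").
    """

    mask: np.ndarray
    source: str
    threshold_fraction: float = MASK_THRESHOLD_FRACTION

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.source not in ("MC", "AI"):
            raise ValueError(f"mask source must be 'MC' or 'AI', got {self.source!r}")


@dataclass
class TrainingSample:
    """One model input/label pair on the model grid."""

    ct_norm: np.ndarray        # in [0, 1]
    energy_norm: float         # in [0, 1]
    label: np.ndarray          # dose (Gy), alpha x 10, or beta x 1e3; masked
    mask: np.ndarray           # bool
    target: str                # dose | alpha | beta
    mask_kind: str             # MC | AI
    energy: float = float("nan")  # MeV/u, for bookkeeping

    def __post_init__(self) -> None:
        if not (self.ct_norm.shape == self.label.shape == self.mask.shape):
            raise ValueError("ct_norm, label and mask shapes must agree")
        if self.ct_norm.min() < 0 or self.ct_norm.max() > 1:
            raise ValueError("ct_norm must lie in [0, 1]")
        if np.any(self.label[~self.mask] != 0):
            raise ValueError("label must be zero outside the mask")


def crop_to_model_grid(
    vol: CTVolume | FieldVolume,
    lateral_center: tuple[float, float] = (0.0, 0.0),
    grid: tuple[int, int, int] = MODEL_GRID,
):
    """Crop to the model grid: symmetric lateral window, proximal-anchored depth.

    The lateral crop is centered on the beam axis. Depth keeps the first
    ``grid[2]`` slices from the proximal face; shorter volumes are padded
    distally with air (CT) or zeros (fields).
    """
    is_ct = isinstance(vol, CTVolume)
    arr = vol.hu if is_ct else vol.values
    nx, ny, nz = arr.shape
    gx, gy, gz = grid
    if nx < gx or ny < gy:
        raise ValueError(f"lateral extent {(nx, ny)} smaller than crop {(gx, gy)}")
    cx = (nx - 1) / 2.0 + lateral_center[0]
    cy = (ny - 1) / 2.0 + lateral_center[1]
    x0 = int(round(cx - (gx - 1) / 2.0))
    y0 = int(round(cy - (gy - 1) / 2.0))
    x0 = min(max(x0, 0), nx - gx)
    y0 = min(max(y0, 0), ny - gy)
    out = arr[x0:x0 + gx, y0:y0 + gy, :gz]
    if nz < gz:
        pad_val = HU_AIR_PAD if is_ct else 0.0
        pad = np.full((gx, gy, gz - nz), pad_val, dtype=out.dtype)
        out = np.concatenate([out, pad], axis=2)
    out = out.copy()
    if is_ct:
        return CTVolume(hu=out, spacing=vol.spacing)
    return FieldVolume(values=out, quantity=vol.quantity, spacing=vol.spacing)


def normalize_ct(ct: CTVolume | np.ndarray) -> np.ndarray:
    """Affine map of the HU window [-1000, 3000] to [0, 1], clipped."""
    hu = ct.hu if isinstance(ct, CTVolume) else np.asarray(ct, dtype=float)
    lo, hi = HU_WINDOW
    return np.clip((hu - lo) / (hi - lo), 0.0, 1.0)


def denormalize_ct(ct_norm: np.ndarray) -> np.ndarray:
    lo, hi = HU_WINDOW
    return np.asarray(ct_norm) * (hi - lo) + lo


def normalize_energy(energy: float) -> float:
    """Map beam energy linearly from [115, 260] MeV/u to [0, 1]."""
    physics.check_energy(energy)
    return (energy - physics.ENERGY_MIN) / (physics.ENERGY_MAX - physics.ENERGY_MIN)


def denormalize_energy(energy_norm: float) -> float:
    return physics.ENERGY_MIN + energy_norm * (physics.ENERGY_MAX - physics.ENERGY_MIN)


def threshold_mask(dose: FieldVolume | np.ndarray, source: str) -> MaskVolume:
    """Boolean mask of voxels above 1% of the dose maximum."""
    values = dose.values if isinstance(dose, FieldVolume) else np.asarray(dose)
    m = values.max()
    if m <= 0:
        raise DegenerateInputError("cannot threshold an all-zero dose")
    return MaskVolume(mask=values > MASK_THRESHOLD_FRACTION * m, source=source)


def scale_labels(field: FieldVolume | np.ndarray, quantity: str | None = None) -> np.ndarray:
    """Scale a label field for training: dose x1, alpha x10, beta x1e3."""
    if isinstance(field, FieldVolume):
        quantity = field.quantity
        values = field.values
    else:
        values = np.asarray(field)
    if quantity not in LABEL_SCALE:
        raise ValueError(f"unknown label quantity {quantity!r}")
    return values * LABEL_SCALE[quantity]


def unscale_labels(label: np.ndarray, quantity: str) -> np.ndarray:
    """Exact inverse of :func:`scale_labels`."""
    if quantity not in LABEL_SCALE:
        raise ValueError(f"unknown label quantity {quantity!r}")
    return np.asarray(label) / LABEL_SCALE[quantity]


def make_training_sample(
    ct: CTVolume,
    target_field: FieldVolume,
    dose_for_mask: FieldVolume,
    energy: float,
    mask_kind: str = "MC",
    lateral_center: tuple[float, float] = (0.0, 0.0),
    grid: tuple[int, int, int] = MODEL_GRID,
) -> TrainingSample:
    """Crop, normalize, mask and scale one (CT, label) pair.

    ``dose_for_mask`` supplies the thresholding dose: the ground-truth dose
    for an "MC" mask, the dose-model prediction for an "AI" mask.
    """
    ct_c = crop_to_model_grid(ct, lateral_center, grid)
    lab_c = crop_to_model_grid(target_field, lateral_center, grid)
    dose_c = crop_to_model_grid(dose_for_mask, lateral_center, grid)
    mask = threshold_mask(dose_c, source=mask_kind).mask
    label = scale_labels(lab_c) * mask
    return TrainingSample(
        ct_norm=normalize_ct(ct_c).astype(np.float32),
        energy_norm=float(normalize_energy(energy)),
        label=label.astype(np.float32),
        mask=mask,
        target=target_field.quantity,
        mask_kind=mask_kind,
        energy=float(energy),
    )
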