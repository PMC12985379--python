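"""Volume containers shared by the simulator, preprocessing and evaluation.

All grids are 3D numpy arrays with 1 mm isotropic spacing by convention.
Axis 2 is beam depth; index 0 along that axis is the proximal face
(where the pencil beam enters). Axes 0 and 1 are the lateral directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

#: HU below this value counts as air (air is ~ -1000 HU).
AIR_HU_THRESHOLD = -900.0

VALID_QUANTITIES = ("dose", "alpha", "beta")

QUANTITY_UNITS = {
    "dose": "Gy/1e7 primaries",
    "alpha": "1/Gy",
    "beta": "1/Gy^2",
}


class DegenerateInputError(ValueError):
    """Raised for inputs that are formally valid but physically empty."""


@dataclass
class CTVolume:
    """A Hounsfield-unit grid in beam-eye-view orientation."""

    hu: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise ValueError(f"CT grid must be 3D, got shape {self.hu.shape}")
        if np.any(self.hu < HU_MIN) or np.any(self.hu > HU_MAX):
            raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def n_depth(self) -> int:
        return self.hu.shape[2]


@dataclass
class FieldVolume:
    """A scalar field (dose, alpha or beta) on the same geometry as a CT."""

    values: np.ndarray
    quantity: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = field(default="")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"field grid must be 3D, got shape {self.values.shape}")
        if self.quantity not in VALID_QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if not self.units:
            self.units = QUANTITY_UNITS[self.quantity]
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("field values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape
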