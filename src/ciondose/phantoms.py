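"""Heterogeneous CT phantom generation.

Stands in for beams-eye-view patient CT subvolumes: water background with
optional transverse bone slabs and embedded air cavities, on a 1 mm grid
with the beam entering at depth index 0.
"""

from __future__ import annotations

import numpy as np

from .grids import AIR_HU_THRESHOLD, CTVolume, DegenerateInputError

COMPLEXITIES = ("homogeneous", "layered", "cavity", "mixed")

HU_WATER = 0.0
HU_AIR = -1000.0


def _add_bone_slabs(hu: np.ndarray, rng: np.random.Generator) -> None:
    nz = hu.shape[2]
    n_slabs = rng.integers(1, 4)
    for _ in range(n_slabs):
        thickness = int(rng.integers(3, 16))
        z0 = int(rng.integers(2, max(3, nz - thickness - 2)))
        hu_bone = float(rng.uniform(700.0, 1200.0))
        hu[:, :, z0:z0 + thickness] = hu_bone


def _add_air_cavities(hu: np.ndarray, rng: np.random.Generator) -> None:
    nx, ny, nz = hu.shape
    n_cav = rng.integers(1, 3)
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    for _ in range(n_cav):
        # semi-axes kept small enough that water background always remains
        ax = float(rng.uniform(3.0, max(4.0, nx / 4)))
        ay = float(rng.uniform(3.0, max(4.0, ny / 4)))
        az = float(rng.uniform(5.0, nz / 5))
        cx = float(rng.uniform(ax + 1, nx - ax - 1))
        cy = float(rng.uniform(ay + 1, ny - ay - 1))
        cz = float(rng.uniform(az + 2, nz - az - 2))
        inside = (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
                  + ((zz - cz) / az) ** 2) <= 1.0
        hu[inside] = HU_AIR


def generate_phantom(
    seed: int,
    complexity: str,
    shape: tuple[int, int] = (48, 48),
    depth_range: tuple[int, int] = (260, 360),
) -> CTVolume:
    """Generate a deterministic synthetic phantom.

    ``complexity`` is one of ``homogeneous`` (all water), ``layered`` (1-3
    transverse bone slabs), ``cavity`` (1-2 embedded air ellipsoids) or
    ``mixed`` (both). The depth extent is drawn from ``depth_range``.
    """
    if complexity not in COMPLEXITIES:
        raise ValueError(
            f"unknown complexity {complexity!r}; expected one of {COMPLEXITIES}"
        )
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    nz = int(rng.integers(depth_range[0], depth_range[1] + 1))
    hu = np.full(shape + (nz,), HU_WATER, dtype=np.float32)
    if complexity in ("layered", "mixed"):
        _add_bone_slabs(hu, rng)
    if complexity in ("cavity", "mixed"):
        _add_air_cavities(hu, rng)
    return CTVolume(hu=hu)


def remove_proximal_air_slices(ct: CTVolume) -> CTVolume:
    """Drop leading depth slices in which every voxel is air (HU < -900)."""
    all_air = np.all(ct.hu < AIR_HU_THRESHOLD, axis=(0, 1))
    if np.all(all_air):
        raise DegenerateInputError("phantom contains only air")
    first_keep = int(np.argmin(all_air))
    if first_keep == 0:
        return ct
    return CTVolume(hu=ct.hu[:, :, first_keep:].copy(), spacing=ct.spacing)
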