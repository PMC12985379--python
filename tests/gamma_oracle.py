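"""Independent brute-force gamma-index oracles.

Written deliberately as per-voxel window scans (the production code scans
displacements over whole volumes), so the two routes share no logic beyond
the gamma definition itself.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def gamma_bruteforce_voxel(
    ref: np.ndarray,
    evl: np.ndarray,
    dose_crit_frac: float,
    dta_mm: float,
    low_frac: float,
    search_radius_mm: float,
) -> tuple[float | None, np.ndarray]:
    """Voxel-center gamma by nested per-voxel neighbourhood scan (1 mm grid)."""
    ref = np.asarray(ref, dtype=float)
    evl = np.asarray(evl, dtype=float)
    dd = dose_crit_frac * ref.max()
    n = int(np.floor(search_radius_mm))
    offs = [(i, j, k)
            for i in range(-n, n + 1)
            for j in range(-n, n + 1)
            for k in range(-n, n + 1)
            if i * i + j * j + k * k <= search_radius_mm**2 + 1e-12]
    gamma_map = np.full(ref.shape, np.nan)
    nx, ny, nz = ref.shape
    thresh = low_frac * ref.max()
    n_eval = 0
    n_pass = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if ref[x, y, z] <= thresh:
                    continue
                best = np.inf
                for i, j, k in offs:
                    xx, yy, zz = x + i, y + j, z + k
                    if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                        continue
                    g2 = ((evl[xx, yy, zz] - ref[x, y, z]) / dd) ** 2 \
                        + (i * i + j * j + k * k) / dta_mm**2
                    if g2 < best:
                        best = g2
                gamma_map[x, y, z] = np.sqrt(best)
                n_eval += 1
                if best <= 1.0 + 2e-9:
                    n_pass += 1
    if n_eval == 0:
        return None, gamma_map
    return 100.0 * n_pass / n_eval, gamma_map


def gamma_dense_interpolated(
    ref: np.ndarray,
    evl: np.ndarray,
    dose_crit_frac: float,
    dta_mm: float,
    low_frac: float,
    search_radius_mm: float,
    step_mm: float,
) -> float | None:
    """Interpolated gamma by dense per-voxel displacement sampling.

    For every evaluated reference voxel, the evaluated volume is sampled
    trilinearly on the full displacement ball at ``step_mm`` spacing and
    the minimum gamma is taken; no early termination, no shared code with
    the production displacement-scan implementation.
    """
    ref = np.asarray(ref, dtype=float)
    evl = np.asarray(evl, dtype=float)
    dd = dose_crit_frac * ref.max()
    n = int(np.floor(search_radius_mm / step_mm))
    ax = np.arange(-n, n + 1) * step_mm
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= search_radius_mm**2 + 1e-12
    disp = np.stack([dx[keep], dy[keep], dz[keep]])  # (3, M)
    dist2 = (disp**2).sum(axis=0) / dta_mm**2

    voxels = np.argwhere(ref > low_frac * ref.max())
    if len(voxels) == 0:
        return None
    n_pass = 0
    for vx in voxels:
        pts = vx[:, None] + disp
        vals = ndimage.map_coordinates(evl, pts, order=1, mode="constant",
                                       cval=np.nan)
        with np.errstate(invalid="ignore"):
            g2 = ((vals - ref[tuple(vx)]) / dd) ** 2 + dist2
        if np.nanmin(g2) <= 1.0 + 2e-9:
            n_pass += 1
    return 100.0 * n_pass / len(voxels)
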