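"""Physics evaluation suite for predicted beamlet volumes.

Implements 3D gamma-index analysis (global dose criterion, with both a
trilinear-interpolation search and an exact voxel-center mode), isodose
Dice coefficients, integrated depth-dose metrics (R80 range, peak dose
difference, RMSE), mask-discrepancy accounting, Monte-Carlo-dropout
summaries and the linear-quadratic RBE-weighted dose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import FieldVolume
from .preprocess import MaskVolume, threshold_mask

# ---------------------------------------------------------------------------
# Gamma analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaParams:
    """Criteria of the gamma test (global dose normalization)."""

    dose_criterion: float = 0.01        # fraction of the reference maximum
    distance_criterion: float = 1.0     # mm
    low_dose_threshold: float = 0.10    # fraction of the reference maximum
    search_radius: float = 3.0          # mm
    interp_step: float = 0.25           # mm

    def __post_init__(self) -> None:
        if self.dose_criterion <= 0 or self.distance_criterion <= 0:
            raise ValueError("criteria must be > 0")
        if self.search_radius < self.distance_criterion:
            raise ValueError("search_radius must be >= distance_criterion")
        if self.interp_step > self.distance_criterion:
            raise ValueError("interp_step must be <= distance_criterion")


def _as_array(vol) -> np.ndarray:
    return vol.values if isinstance(vol, FieldVolume) else np.asarray(vol, dtype=float)


def _displacements(radius: float, step: float) -> np.ndarray:
    """All displacement vectors within ``radius``, sorted by length."""
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    disp = np.array(list(itertools.product(axis, axis, axis)))
    d2 = (disp**2).sum(axis=1)
    keep = d2 <= radius**2 + 1e-12
    disp = disp[keep]
    order = np.argsort(d2[keep], kind="stable")
    return disp[order]


def gamma_pass_rate(
    ref,
    evl,
    params: GammaParams = GammaParams(),
    scope_mask: MaskVolume | np.ndarray | None = None,
    mode: str = "interpolated",
) -> tuple[float | None, np.ndarray]:
    """Gamma pass rate (percent) and the per-voxel gamma map.

    For every reference voxel inside ``scope_mask`` (if given) and above the
    low-dose threshold, the gamma index is the minimum over displacements r
    within the search radius of

        sqrt((dD / (dose_criterion * max(ref)))^2 + (|r| / dta)^2)

    where dD is the difference between the reference voxel and the evaluated
    volume sampled at the displaced position. ``mode="interpolated"``
    samples the evaluated volume trilinearly on an ``interp_step`` grid;
    ``mode="voxel"`` restricts displacements to voxel centers (the exact,
    brute-force-comparable mode). Voxels outside the evaluated set hold NaN
    in the gamma map. Returns (None, map) when no voxel qualifies.
    """
    ref_a = _as_array(ref)
    evl_a = _as_array(evl)
    if ref_a.shape != evl_a.shape:
        raise ValueError(f"grid mismatch: {ref_a.shape} vs {evl_a.shape}")
    if mode not in ("interpolated", "voxel"):
        raise ValueError(f"unknown gamma mode {mode!r}")
    ref_max = ref_a.max()
    if ref_max <= 0:
        raise ValueError("reference maximum must be > 0")

    if scope_mask is not None:
        sm = scope_mask.mask if isinstance(scope_mask, MaskVolume) else \
            np.asarray(scope_mask, dtype=bool)
        ref_a = np.where(sm, ref_a, 0.0)
        evl_a = np.where(sm, evl_a, 0.0)
    else:
        sm = np.ones(ref_a.shape, dtype=bool)

    evaluated = sm & (ref_a > params.low_dose_threshold * ref_max)
    gamma_map = np.full(ref_a.shape, np.nan)
    if not evaluated.any():
        return None, gamma_map

    dd_norm = params.dose_criterion * ref_max
    dta = params.distance_criterion
    step = 1.0 if mode == "voxel" else params.interp_step
    disps = _displacements(params.search_radius, step)

    ref_vals = ref_a[evaluated]
    best = np.full(ref_vals.shape, np.inf)
    idx = np.argwhere(evaluated).T.astype(float)  # (3, n) voxel coords (1 mm)

    for disp in disps:
        r2 = float((disp**2).sum()) / dta**2
        if r2 >= best.max() ** 2:
            break  # further displacements cannot improve any voxel
        if mode == "voxel" or np.allclose(disp % 1.0, 0.0):
            sh = disp.astype(int)
            src = idx + sh[:, None]
            inb = np.all((src >= 0) & (src <= (np.array(ref_a.shape) - 1)[:, None]),
                         axis=0)
            vals = np.full(ref_vals.shape, np.nan)
            s = src[:, inb].astype(int)
            vals[inb] = evl_a[s[0], s[1], s[2]]
        else:
            src = idx + disp[:, None]
            vals = ndimage.map_coordinates(evl_a, src, order=1, mode="constant",
                                           cval=np.nan)
        with np.errstate(invalid="ignore"):
            g2 = ((vals - ref_vals) / dd_norm) ** 2 + r2
        improved = g2 < best**2
        best[improved] = np.sqrt(g2[improved])

    gamma_map[evaluated] = best
    gpr = 100.0 * float((best <= 1.0 + 1e-9).sum()) / best.size
    return gpr, gamma_map


# ---------------------------------------------------------------------------
# Dice, IDD, R80
# ---------------------------------------------------------------------------


def dice_isodose(ref_dose, eval_dose, level_frac: float) -> tuple[float | None, int]:
    """Dice overlap of the isodose regions above ``level_frac`` of each maximum.

    Each volume is thresholded against its own maximum. Also returns the
    number of reference voxels in the region. Returns (None, 0) when both
    regions are empty.
    """
    a = _as_array(ref_dose)
    b = _as_array(eval_dose)
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    if a.max() <= 0:
        raise ValueError("reference maximum must be > 0")
    set_a = a > level_frac * a.max()
    set_b = b > level_frac * b.max()
    na, nb = int(set_a.sum()), int(set_b.sum())
    if na + nb == 0:
        return None, 0
    dice = 2.0 * float((set_a & set_b).sum()) / (na + nb)
    return dice, na


def idd(dose) -> np.ndarray:
    """Integrated depth dose: the lateral sum per depth slice (float64)."""
    return _as_array(dose).sum(axis=(0, 1), dtype=np.float64)


def r80(profile: np.ndarray, depth: np.ndarray | None = None) -> float:
    """Distal depth (mm) where the profile falls to 80% of its maximum.

    Scanning from the distal end, the first linear-interpolated crossing of
    0.8 * max is returned.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise ValueError("profile must have at least 2 points")
    if profile.max() <= 0:
        raise ValueError("profile maximum must be > 0")
    if depth is None:
        depth = np.arange(profile.size, dtype=float)
    level = 0.8 * profile.max()
    for k in range(profile.size - 2, -1, -1):
        lo, hi = profile[k + 1], profile[k]
        if lo < level <= hi:
            t = (hi - level) / (hi - lo)
            return float(depth[k] + t * (depth[k + 1] - depth[k]))
    # profile never drops below 80% distally; return the last depth
    return float(depth[-1])


def idd_metrics(ref_profile: np.ndarray, eval_profile: np.ndarray
                ) -> tuple[float, float, float]:
    """(delta_R80 mm, delta_Dmax %, RMSE %) between two depth-dose profiles.

    delta_R80 = R80(eval) - R80(ref); delta_Dmax is the relative difference
    of the profile maxima; RMSE is normalized by the reference maximum.
    """
    ref_profile = np.asarray(ref_profile, dtype=float)
    eval_profile = np.asarray(eval_profile, dtype=float)
    if ref_profile.shape != eval_profile.shape:
        raise ValueError("profiles must share the depth grid")
    d_r80 = r80(eval_profile) - r80(ref_profile)
    ref_max = ref_profile.max()
    d_dmax = 100.0 * (eval_profile.max() - ref_max) / ref_max
    rmse = 100.0 * np.sqrt(np.mean((eval_profile - ref_profile) ** 2)) / ref_max
    return float(d_r80), float(d_dmax), float(rmse)


def rmse_3d_percent(ref, evl) -> float:
    """3D RMSE as a percentage of the reference-volume maximum."""
    a, b = _as_array(ref), _as_array(evl)
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    return 100.0 * float(np.sqrt(np.mean((b - a) ** 2)) / a.max())


# ---------------------------------------------------------------------------
# Mask discrepancy and MCD summaries
# ---------------------------------------------------------------------------


def mask_discrepancy(mc_mask: MaskVolume, ai_mask: MaskVolume, gt_dose
                     ) -> tuple[float, float, float, float]:
    """(lost_fraction, lost_dose_mean, lost_dose_std, gained_fraction).

    Lost voxels are in the MC mask but not the AI mask (fraction of MC-mask
    voxels); gained is the reverse. Mean/std are of the ground-truth dose
    over the lost voxels.
    """
    mc = mc_mask.mask
    ai = ai_mask.mask
    if mc.shape != ai.shape:
        raise ValueError("mask grid mismatch")
    n_mc = int(mc.sum())
    if n_mc == 0:
        raise ValueError("empty MC mask")
    lost = mc & ~ai
    gained = ai & ~mc
    dose = _as_array(gt_dose)
    lost_dose = dose[lost]
    lost_mean = float(lost_dose.mean()) if lost_dose.size else 0.0
    lost_std = float(lost_dose.std()) if lost_dose.size else 0.0
    return (float(lost.sum()) / n_mc, lost_mean, lost_std,
            float(gained.sum()) / n_mc)


@dataclass
class McdSummary:
    """Per-voxel statistics and per-run gamma pass rates of an MCD stack."""

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    gpr_runs: dict[str, list[float]]
    gpr_mean: dict[str, float]
    gpr_std: dict[str, float]


def mcd_summary(
    runs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    ref: dict[str, np.ndarray],
    params: GammaParams = GammaParams(),
    mode: str = "voxel",
) -> McdSummary:
    """Summarize a Monte-Carlo-dropout stack against ground truth.

    ``runs`` is a list of (dose, alpha, beta) triples; ``ref`` maps quantity
    name to the ground-truth volume. Computes per-voxel mean/std over runs
    and the gamma pass rate of every individual run.
    """
    if len(runs) < 2:
        raise ValueError("MCD stack must contain at least 2 runs")
    quantities = ("dose", "alpha", "beta")
    stacks = {q: np.stack([r[i] for r in runs]) for i, q in enumerate(quantities)}
    for q in quantities:
        if q in ref and stacks[q].shape[1:] != np.asarray(ref[q]).shape:
            raise ValueError(f"{q} stack/reference shape mismatch")
    mean = {q: stacks[q].mean(axis=0) for q in quantities}
    std = {q: stacks[q].std(axis=0) for q in quantities}
    gpr_runs: dict[str, list[float]] = {}
    for q in quantities:
        if q not in ref:
            continue
        vals = []
        for k in range(len(runs)):
            g, _ = gamma_pass_rate(ref[q], stacks[q][k], params, mode=mode)
            vals.append(g)
        gpr_runs[q] = vals
    gpr_mean = {q: float(np.mean(v)) for q, v in gpr_runs.items()}
    gpr_std = {q: float(np.std(v)) for q, v in gpr_runs.items()}
    return McdSummary(mean=mean, std=std, gpr_runs=gpr_runs,
                      gpr_mean=gpr_mean, gpr_std=gpr_std)


# ---------------------------------------------------------------------------
# RBE-weighted dose
# ---------------------------------------------------------------------------


def rbe_weighted_dose(d, alpha, beta, alpha_x: float, beta_x: float) -> np.ndarray:
    """Photon-equivalent dose from the linear-quadratic model.

    Solves alpha_x D + beta_x D^2 = alpha d + beta d^2 for D:

        D_RBE = (sqrt(alpha_x^2 + 4 beta_x (alpha d + beta d^2)) - alpha_x)
                / (2 beta_x)

    Zero where d is zero; monotone increasing in d.
    """
    if beta_x <= 0:
        raise ValueError("beta_x must be > 0")
    d = _as_array(d)
    alpha = _as_array(alpha)
    beta = _as_array(beta)
    effect = alpha * d + beta * d**2
    return (np.sqrt(alpha_x**2 + 4.0 * beta_x * effect) - alpha_x) / (2.0 * beta_x)


# ---------------------------------------------------------------------------
# Per-beamlet report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """All per-beamlet metrics for one quantity triple."""

    gpr_percent: dict[str, float | None]
    dice: dict[float, float | None]
    dice_n_ref: dict[float, int]
    delta_r80_mm: float
    delta_dmax_percent: float
    rmse_idd_percent: float
    rmse_3d_percent: dict[str, float]
    lost_voxel_fraction: float
    lost_dose_mean: float
    lost_dose_std: float
    gained_voxel_fraction: float


DICE_LEVELS = (0.01, 0.30, 0.70)


def evaluate_beamlet(
    gt: dict[str, np.ndarray],
    pred: dict[str, np.ndarray],
    params: GammaParams = GammaParams(),
    mode: str = "voxel",
) -> EvalReport:
    """Full evaluation of one predicted beamlet against its ground truth.

    Gamma pass rates use the AI dose mask (from the predicted dose) as scope
    on both volumes; IDD metrics apply the MC mask to the ground truth and
    the AI mask to the prediction before profiling.
    """
    ai_mask = threshold_mask(pred["dose"], source="AI")
    mc_mask = threshold_mask(gt["dose"], source="MC")

    gprs = {}
    for q in ("dose", "alpha", "beta"):
        if q in pred and q in gt:
            g, _ = gamma_pass_rate(gt[q], pred[q], params,
                                   scope_mask=ai_mask, mode=mode)
            gprs[q] = g

    dice, dice_n = {}, {}
    for lv in DICE_LEVELS:
        dv, na = dice_isodose(gt["dose"], pred["dose"], lv)
        dice[lv], dice_n[lv] = dv, na

    ref_idd = idd(np.where(mc_mask.mask, _as_array(gt["dose"]), 0.0))
    ai_idd = idd(np.where(ai_mask.mask, _as_array(pred["dose"]), 0.0))
    d_r80, d_dmax, rmse_idd = idd_metrics(ref_idd, ai_idd)

    rmse3 = {q: rmse_3d_percent(gt[q], pred[q])
             for q in ("dose", "alpha", "beta") if q in pred and q in gt}

    lost, lmean, lstd, gained = mask_discrepancy(mc_mask, ai_mask, gt["dose"])
    return EvalReport(
        gpr_percent=gprs, dice=dice, dice_n_ref=dice_n,
        delta_r80_mm=d_r80, delta_dmax_percent=d_dmax,
        rmse_idd_percent=rmse_idd, rmse_3d_percent=rmse3,
        lost_voxel_fraction=lost, lost_dose_mean=lmean, lost_dose_std=lstd,
        gained_voxel_fraction=gained,
    )


def summarize_gpr(values: list[float]) -> dict[str, float]:
    """Median/min/10%-tile/90%-tile/max summary of a metric list."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return {
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "p10": float(np.percentile(arr, 10)),
        "p90": float(np.percentile(arr, 90)),
        "max": float(arr.max()),
    }
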