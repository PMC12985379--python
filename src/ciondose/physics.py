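"""Analytic beamlet physics surrogate.

The quantities a Monte Carlo engine would transport are replaced here by a
closed-form model with the right qualitative structure for a carbon pencil
beam:

* a power-law range-energy relation ``R(E) = a * E**p``,
* a depth-dose (integrated over the lateral plane) with an entrance plateau,
  a sharp Bragg peak whose width grows with momentum spread, and a fragment
  tail extending beyond the primary range,
* per-species linear-quadratic coefficients ``alpha_i``/``beta_i`` looked up
  as monotone functions of residual range, so that alpha rises towards the
  Bragg peak (LEM-like behaviour),
* dose-weighted mixed-field averaging of alpha and sqrt(beta) over species
  (the TRiP98 convention).

Depth is always expressed as water-equivalent depth (WED, mm); the mapping
from geometric depth to WED happens in :mod:`ciondose.beamlets` via the
HU -> relative-stopping-power curve below.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Energy range and range-energy relation
# ---------------------------------------------------------------------------

ENERGY_MIN = 115.0  # MeV/u
ENERGY_MAX = 260.0  # MeV/u

# R(E) = RANGE_A * E**RANGE_P, fitted to R(115) = 30 mm, R(260) = 130 mm water.
RANGE_P = np.log(130.0 / 30.0) / np.log(260.0 / 115.0)
RANGE_A = 30.0 / 115.0**RANGE_P

#: Water-equivalent thickness of the beam nozzle (PMMA slab + air gap),
#: folded into a constant offset instead of explicit transport.
NOZZLE_WED_MM = 4.6

#: Global scale converting the normalized depth-dose shape to
#: Gy*mm^2 per 1e7 primaries.
IDD_SCALE = 25.0

DEFAULT_MOMENTUM_SPREAD = 0.005


def range_from_energy(energy: float | np.ndarray) -> float | np.ndarray:
    """Primary carbon range in water (mm) for a beam energy in MeV/u."""
    return RANGE_A * np.asarray(energy, dtype=float) ** RANGE_P


def check_energy(energy: float) -> None:
    if not (ENERGY_MIN <= energy <= ENERGY_MAX):
        raise ValueError(
            f"energy {energy} MeV/u outside supported range "
            f"[{ENERGY_MIN}, {ENERGY_MAX}]"
        )


def peak_sigma(energy: float, momentum_spread: float) -> float:
    """Bragg-peak width (mm, 1 sigma in WED) from straggling + momentum spread.

    Range straggling is taken proportional to range; the momentum-spread
    contribution uses dR/R ~= 2 p dE/E ~= 3.6 dp/p for R ~ E^1.8.
    """
    r = range_from_energy(energy)
    straggle = 0.012 * r
    mom = 2.0 * RANGE_P * momentum_spread * r
    return float(np.sqrt(0.8**2 + straggle**2 + mom**2))


# ---------------------------------------------------------------------------
# HU -> relative stopping power
# ---------------------------------------------------------------------------

# Piecewise-linear HU -> RSP calibration (standard clinical shape).
_HU_KNOTS = np.array([-1000.0, 0.0, 1000.0, 3000.0])
_RSP_KNOTS = np.array([0.001, 1.0, 1.55, 2.3])


def hu_to_rsp(hu: np.ndarray) -> np.ndarray:
    """Relative stopping power from Hounsfield units (piecewise linear)."""
    return np.interp(np.asarray(hu, dtype=float), _HU_KNOTS, _RSP_KNOTS)


# ---------------------------------------------------------------------------
# Depth-dose shape
# ---------------------------------------------------------------------------

# Normalized amplitudes of the three modelled components (primary carbon and
# two effective fragment groups). The entrance total is ~0.72 and the peak
# total ~3.3, giving a peak-to-entrance ratio of ~4.5.
_PRIMARY_PLATEAU = 0.70
_PRIMARY_PEAK_AMP = 2.5
_FRAG1_AMP = 0.15  # light fragments, long tail
_FRAG2_AMP = 0.10  # heavier fragments, shorter tail
_FRAG1_TAIL_MM = 25.0
_FRAG2_TAIL_MM = 12.0

#: Primary dose is identically zero beyond ``R + PRIMARY_CUTOFF_MM``.
PRIMARY_CUTOFF_MM = 5.0


def _primary_idd(wed: np.ndarray, r: float, sigma: float) -> np.ndarray:
    wed = np.asarray(wed, dtype=float)
    plateau = _PRIMARY_PLATEAU * (1.0 + 0.4 * (wed / r) ** 2)
    falloff = 1.0 / (1.0 + np.exp((wed - r) / (0.6 * sigma)))
    peak = _PRIMARY_PEAK_AMP * np.exp(-0.5 * ((wed - r) / sigma) ** 2)
    d = plateau * falloff + peak
    # Hard range cut with a cosine taper so the primary is exactly zero
    # beyond R + PRIMARY_CUTOFF_MM.
    t0, t1 = r + 2.0, r + PRIMARY_CUTOFF_MM
    taper = np.clip((t1 - wed) / (t1 - t0), 0.0, 1.0)
    d = d * (0.5 - 0.5 * np.cos(np.pi * taper))
    d[wed >= t1] = 0.0
    return d


def _fragment_idd(wed: np.ndarray, r: float, amp: float, tail_mm: float,
                  buildup_exp: float) -> np.ndarray:
    wed = np.asarray(wed, dtype=float)
    inside = amp * (np.clip(wed, 0.0, r) / r) ** buildup_exp
    tail = np.where(wed > r, np.exp(-(wed - r) / tail_mm), 1.0)
    return inside * tail


def species_idd(
    wed: np.ndarray, energy: float,
    momentum_spread: float = DEFAULT_MOMENTUM_SPREAD,
) -> np.ndarray:
    """Per-species integrated depth dose at the given WED positions.

    Returns an array of shape ``(3, len(wed))`` (primary carbon, light
    fragments, heavy fragments) in Gy*mm^2 per 1e7 primaries.
    """
    check_energy(energy)
    if momentum_spread < 0:
        raise ValueError("momentum_spread must be >= 0")
    r = float(range_from_energy(energy))
    sigma = peak_sigma(energy, momentum_spread)
    prim = _primary_idd(wed, r, sigma)
    f1 = _fragment_idd(wed, r, _FRAG1_AMP, _FRAG1_TAIL_MM, 1.2)
    f2 = _fragment_idd(wed, r, _FRAG2_AMP, _FRAG2_TAIL_MM, 1.5)
    return IDD_SCALE * np.stack([prim, f1, f2])


def depth_dose_curve(
    energy: float,
    momentum_spread: float = DEFAULT_MOMENTUM_SPREAD,
    wed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total integrated depth dose versus water-equivalent depth.

    Returns ``(wed, idd)``; when ``wed`` is not given, a 0.1 mm grid from 0
    to R + 60 mm is used. Units: Gy*mm^2 per 1e7 primaries.
    """
    check_energy(energy)
    if wed is None:
        r = float(range_from_energy(energy))
        wed = np.arange(0.0, r + 60.0, 0.1)
    wed = np.asarray(wed, dtype=float)
    return wed, species_idd(wed, energy, momentum_spread).sum(axis=0)


# ---------------------------------------------------------------------------
# Lateral spread
# ---------------------------------------------------------------------------

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548
#: Small-angle scattering growth rate (dimensionless, sigma grows as k*z).
LATERAL_GROWTH_K = 0.02


def fwhm_at_energy(energy: float) -> float:
    """Entrance FWHM (mm): linear 8 mm @ 115 MeV/u -> 5 mm @ 260 MeV/u."""
    check_energy(energy)
    frac = (energy - ENERGY_MIN) / (ENERGY_MAX - ENERGY_MIN)
    return 8.0 - 3.0 * frac


def lateral_sigma(depth, fwhm0: float, k: float = LATERAL_GROWTH_K):
    """Gaussian lateral sigma (mm) at geometric depth (mm).

    sigma(z) = sqrt(sigma0^2 + (k z)^2) with sigma0 = fwhm0 / 2.3548.
    """
    if fwhm0 <= 0:
        raise ValueError("fwhm0 must be > 0")
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be >= 0")
    sigma0 = fwhm0 * FWHM_TO_SIGMA
    return np.sqrt(sigma0**2 + (k * depth) ** 2)


# ---------------------------------------------------------------------------
# Per-species LQ coefficients and mixed-field averaging
# ---------------------------------------------------------------------------

# Residual-range (mm) -> alpha (1/Gy) and beta (1/Gy^2) lookup tables,
# one per modelled species. Alpha rises steeply as residual range -> 0
# (towards the Bragg peak); beta varies mildly.
_RR_KNOTS = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 50.0, 150.0])

_ALPHA_TABLES = np.array([
    [1.50, 1.30, 0.90, 0.60, 0.45, 0.35, 0.30],  # primary carbon
    [0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.18],  # light fragments
    [0.80, 0.70, 0.55, 0.45, 0.35, 0.28, 0.25],  # heavy fragments
])

_BETA_TABLES = np.array([
    [0.030, 0.028, 0.025, 0.022, 0.020, 0.018, 0.017],
    [0.012, 0.012, 0.011, 0.011, 0.010, 0.010, 0.010],
    [0.020, 0.019, 0.018, 0.017, 0.016, 0.015, 0.015],
])

N_SPECIES = 3


def species_alpha_beta(wed: np.ndarray, energy: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-species alpha and beta at the given WED positions.

    Residual range is measured against the primary range and clamped at 0,
    so the tables saturate at their peak values beyond the range.
    Returns two arrays of shape ``(3, len(wed))``.
    """
    check_energy(energy)
    r = float(range_from_energy(energy))
    rr = np.clip(r - np.asarray(wed, dtype=float), 0.0, None)
    alpha = np.stack([np.interp(rr, _RR_KNOTS, t) for t in _ALPHA_TABLES])
    beta = np.stack([np.interp(rr, _RR_KNOTS, t) for t in _BETA_TABLES])
    return alpha, beta


def mix_alpha_beta(
    dose: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    convention: str = "sqrt_beta",
) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-field LQ coefficients by dose averaging over species.

    ``dose``, ``alpha``, ``beta`` have a leading species axis; averaging is
    over that axis. alpha is dose-averaged directly. For beta the default
    averages sqrt(beta) and squares the result (TRiP98 convention);
    ``convention="beta"`` dose-averages beta itself.

    Voxels with zero total dose are undefined: NaN is returned there and the
    caller must mask them.
    """
    dose = np.asarray(dose, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if convention not in ("sqrt_beta", "beta"):
        raise ValueError(f"unknown mixing convention {convention!r}")
    if np.any(dose < 0) or np.any(alpha < 0) or np.any(beta < 0):
        raise ValueError("dose, alpha, beta must be non-negative")
    total = dose.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mix = (alpha * dose).sum(axis=0) / total
        if convention == "sqrt_beta":
            beta_mix = ((np.sqrt(beta) * dose).sum(axis=0) / total) ** 2
        else:
            beta_mix = (beta * dose).sum(axis=0) / total
    alpha_mix = np.where(total > 0, alpha_mix, np.nan)
    beta_mix = np.where(total > 0, beta_mix, np.nan)
    return alpha_mix, beta_mix
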