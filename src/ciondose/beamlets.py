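"""Per-beamlet ground-truth generation on CT phantoms.

Combines the analytic depth-dose/lateral-spread model with per-voxel
mixed-field alpha/beta averaging to produce the (dose, alpha, beta) volume
triple a Monte Carlo engine would score for one pencil beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physics
from .grids import CTVolume, FieldVolume


class BraggPeakOutsideError(ValueError):
    """The Bragg peak of the requested energy falls beyond the phantom."""


class LadderExhaustedError(RuntimeError):
    """No energy on the ladder is both under its count cap and in-phantom."""


@dataclass(frozen=True)
class BeamletSpec:
    """One pencil beam: energy, entrance position and beam-shape parameters."""

    energy: float  # MeV/u
    lateral_center: tuple[float, float] = (0.0, 0.0)  # mm, relative to grid center
    fwhm0: float | None = None  # mm at entrance; None -> energy-dependent default
    momentum_spread: float = physics.DEFAULT_MOMENTUM_SPREAD
    seed: int = 0

    def __post_init__(self) -> None:
        physics.check_energy(self.energy)
        if self.fwhm0 is not None and self.fwhm0 <= 0:
            raise ValueError("fwhm0 must be > 0")
        if self.momentum_spread < 0:
            raise ValueError("momentum_spread must be >= 0")

    @property
    def fwhm(self) -> float:
        if self.fwhm0 is not None:
            return self.fwhm0
        return physics.fwhm_at_energy(self.energy)


def lateral_center_indices(
    ct_shape: tuple[int, int, int], lateral_center: tuple[float, float]
) -> tuple[float, float]:
    """Beam-axis position in (fractional) voxel indices on axes 0 and 1."""
    cx = (ct_shape[0] - 1) / 2.0 + lateral_center[0]
    cy = (ct_shape[1] - 1) / 2.0 + lateral_center[1]
    if not (0 <= cx <= ct_shape[0] - 1 and 0 <= cy <= ct_shape[1] - 1):
        raise ValueError("lateral_center outside the lateral extent")
    return cx, cy


def water_equivalent_depth(
    ct: CTVolume, lateral_center: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Cumulative water-equivalent depth (mm) along the beam axis.

    Element ``k`` is the WED at the distal face of voxel ``k``, i.e. the sum
    of relative stopping power over voxels ``0..k`` (1 mm voxels). An
    all-water column therefore gives ``wed[k] = k + 1``, so WED(z) = z.
    """
    cx, cy = lateral_center_indices(ct.shape, lateral_center)
    column = ct.hu[int(round(cx)), int(round(cy)), :]
    rsp = physics.hu_to_rsp(column)
    return np.cumsum(rsp)


def wed_at_voxel_centers(ct: CTVolume, lateral_center=(0.0, 0.0)) -> np.ndarray:
    """WED at the centers of the depth voxels along the beam axis."""
    cx, cy = lateral_center_indices(ct.shape, lateral_center)
    column = ct.hu[int(round(cx)), int(round(cy)), :]
    rsp = physics.hu_to_rsp(column)
    return np.cumsum(rsp) - 0.5 * rsp


def peak_depth_index(ct: CTVolume, spec: BeamletSpec) -> int:
    """Depth index of the Bragg peak; raises if it lies beyond the phantom."""
    wed = wed_at_voxel_centers(ct, spec.lateral_center) + physics.NOZZLE_WED_MM
    r = float(physics.range_from_energy(spec.energy))
    if wed[-1] < r:
        raise BraggPeakOutsideError(
            f"Bragg peak at WED {r:.1f} mm exceeds phantom WED {wed[-1]:.1f} mm"
        )
    _, idd = physics.depth_dose_curve(spec.energy, spec.momentum_spread, wed=wed)
    return int(np.argmax(idd))


def generate_ground_truth(
    ct: CTVolume,
    beam: BeamletSpec,
    convention: str = "sqrt_beta",
    noise_sigma: float = 0.0,
) -> tuple[FieldVolume, FieldVolume, FieldVolume]:
    """Score dose, alpha and beta for one beamlet on the CT grid.

    Dose is the per-species integrated depth dose (evaluated at the WED of
    each depth voxel, offset by the nozzle's water-equivalent thickness)
    spread laterally with a Gaussian; fragments are given wider lateral
    profiles than the primary. Alpha/beta are the per-voxel dose-weighted
    mixes of the species tables; they are zero where the dose is zero.
    Deterministic given ``(ct, beam)``; optional additive Gaussian noise on
    the dose (fraction of the dose maximum) emulates MC statistics.
    """
    nx, ny, nz = ct.shape
    wed = wed_at_voxel_centers(ct, beam.lateral_center) + physics.NOZZLE_WED_MM
    r = float(physics.range_from_energy(beam.energy))
    if wed[-1] < r:
        raise BraggPeakOutsideError(
            f"Bragg peak at WED {r:.1f} mm exceeds phantom WED {wed[-1]:.1f} mm"
        )

    # species depth profiles (3, nz), Gy*mm^2 / 1e7 primaries
    idd = physics.species_idd(wed, beam.energy, beam.momentum_spread)
    alpha_sp, beta_sp = physics.species_alpha_beta(wed, beam.energy)

    # lateral Gaussian per species; fragments spread wider than the primary
    cx, cy = lateral_center_indices(ct.shape, beam.lateral_center)
    z = np.arange(nz, dtype=float)
    sigma = physics.lateral_sigma(z, beam.fwhm)  # (nz,)
    widen = np.array([1.0, 2.0, 1.5])  # per-species lateral scale
    x = np.arange(nx, dtype=float) - cx
    y = np.arange(ny, dtype=float) - cy
    dose_sp = np.empty((3, nx, ny, nz), dtype=float)
    for s in range(3):
        sig = sigma * widen[s]  # (nz,)
        gx = np.exp(-0.5 * (x[:, None] / sig[None, :]) ** 2)  # (nx, nz)
        gy = np.exp(-0.5 * (y[:, None] / sig[None, :]) ** 2)  # (ny, nz)
        norm = idd[s] / (2.0 * np.pi * sig**2)  # (nz,)
        dose_sp[s] = norm[None, None, :] * gx[:, None, :] * gy[None, :, :]

    dose = dose_sp.sum(axis=0)
    alpha_mix, beta_mix = physics.mix_alpha_beta(
        dose_sp,
        alpha_sp[:, None, None, :] * np.ones_like(dose_sp),
        beta_sp[:, None, None, :] * np.ones_like(dose_sp),
        convention=convention,
    )
    alpha = np.where(dose > 0, alpha_mix, 0.0)
    beta = np.where(dose > 0, beta_mix, 0.0)

    if noise_sigma > 0:
        rng = np.random.default_rng(beam.seed)
        dose = np.clip(
            dose + rng.normal(0.0, noise_sigma * dose.max(), dose.shape), 0.0, None
        )

    return (
        FieldVolume(values=dose, quantity="dose", spacing=ct.spacing),
        FieldVolume(values=alpha, quantity="alpha", spacing=ct.spacing),
        FieldVolume(values=beta, quantity="beta", spacing=ct.spacing),
    )


@dataclass
class EnergyLadder:
    """Discrete accelerator energies with per-energy usage counts."""

    energies: np.ndarray = field(
        default_factory=lambda: np.linspace(physics.ENERGY_MIN, physics.ENERGY_MAX, 30)
    )
    counts: np.ndarray | None = None
    cap_fraction: float = 0.99

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) == 0:
            raise ValueError("energy ladder is empty")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energies must be strictly increasing")
        if (self.energies[0] < physics.ENERGY_MIN
                or self.energies[-1] > physics.ENERGY_MAX):
            raise ValueError("ladder energies outside the supported range")
        if self.counts is None:
            self.counts = np.zeros(len(self.energies), dtype=int)
        else:
            self.counts = np.asarray(self.counts, dtype=int)
            if self.counts.shape != self.energies.shape or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative, one per energy")

    def eligible(self) -> np.ndarray:
        """Energies not over-represented relative to the rest of the ladder.

        An energy is excluded once its count exceeds ``cap_fraction`` times
        the maximum count over the ladder; the least-used energies always
        stay eligible (when all counts are equal, no cap binds).
        """
        cap = self.cap_fraction * self.counts.max()
        return (self.counts <= cap) | (self.counts == self.counts.min())


def sample_energy(
    ladder: EnergyLadder,
    ct: CTVolume,
    lateral_center: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
    relax_cap: bool = False,
) -> float:
    """Draw an energy uniformly among eligible ladder entries.

    An energy is eligible when its usage count is within the 99%-of-maximum
    cap and its Bragg peak lies inside the phantom (peak-outside energies
    are effectively resampled by exclusion). The drawn energy's count is
    incremented. With ``relax_cap`` the count cap is ignored when it would
    otherwise leave no eligible energy (useful for small datasets, where a
    short phantom's few feasible energies may all sit at the cap).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # same in-phantom criterion as generate_ground_truth (voxel-center WED)
    wed_total = (wed_at_voxel_centers(ct, lateral_center)[-1]
                 + physics.NOZZLE_WED_MM)
    fits = physics.range_from_energy(ladder.energies) <= wed_total
    mask = ladder.eligible() & fits
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        if not fits.any():
            raise LadderExhaustedError(
                "no ladder energy places a Bragg peak inside the phantom")
        if not relax_cap:
            raise LadderExhaustedError(
                "all in-phantom energies are at the count cap")
        idx = np.flatnonzero(fits)
    choice = int(rng.choice(idx))
    ladder.counts[choice] += 1
    return float(ladder.energies[choice])
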