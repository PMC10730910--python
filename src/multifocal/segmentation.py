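"""Pupil segmentation: assembling multifocal wavefronts from annular zones.

A multifocal lens wavefront W_CL is built by creating one monofocal
defocus wavefront per radial zone (its power read off the sagittal
profile), masking each to its annulus, and summing the disjoint pieces:

    W_CL = sum_l w_l(D_l) * sigma_l,

where sigma_l is the indicator of the annulus [R l/n, R (l+1)/n).
Annuli are half-open with the outermost boundary closed, so the masks
partition the pupil disk exactly — no gaps, no double counting.  No
piston matching is applied at zone boundaries: the OPD steps between
zones are part of the model.

Eye aberrations enter as a pupil-plane superposition W_T = W_CL + W_Eye
over the effective aperture R = min(pupil radius, measured lens radius).
The eye wavefront is synthesized over its own measurement pupil and
cropped spatially to R (coefficients are never rescaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profiles import EyeRecord, SagittalProfile, annulus_powers
from .zernike import (
    GridSpec,
    WavefrontMap,
    defocus_coeff_from_diopters,
    wavefront_from_coeffs,
    zernike_value,
)

__all__ = [
    "AnnularMask",
    "MultifocalAssembly",
    "annular_mask",
    "zone_index_map",
    "build_multifocal_wavefront",
    "eye_wavefront",
    "combine_with_eye",
]


@dataclass
class AnnularMask:
    """Binary indicator of one annular zone on a computation grid."""

    indicator: np.ndarray
    zone_index: int
    n_zones: int
    aperture_radius_mm: float
    grid: GridSpec


def zone_index_map(grid: GridSpec, aperture_radius_mm: float, n_zones: int) -> np.ndarray:
    """Per-pixel zone index (0..n-1) inside the aperture, -1 outside.

    Membership is by pixel center: zone l covers radii in
    [R l/n, R (l+1)/n), ties at interior boundaries going to the outer
    zone, and the outermost boundary (radius exactly R) closed.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    r, _ = grid.radial_coords(aperture_radius_mm)
    inside = r <= aperture_radius_mm
    zones = np.full(r.shape, -1, dtype=int)
    zones[inside] = np.minimum(
        (r[inside] * n_zones / aperture_radius_mm).astype(int), n_zones - 1
    )
    return zones


def annular_mask(
    l: int, n_zones: int, aperture_radius_mm: float, grid: GridSpec
) -> AnnularMask:
    """Masking function sigma_l: 1 on annulus l of n, 0 elsewhere."""
    if not 0 <= l <= n_zones - 1:
        raise IndexError(f"zone index {l} out of range for n={n_zones}")
    zones = zone_index_map(grid, aperture_radius_mm, n_zones)
    return AnnularMask(zones == l, l, n_zones, aperture_radius_mm, grid)


@dataclass
class MultifocalAssembly:
    """An assembled multifocal wavefront with its construction metadata."""

    wavefront: WavefrontMap
    zone_powers_d: np.ndarray
    n_zones: int
    aperture_radius_mm: float
    eye: EyeRecord | None = None

    def save_npz(self, path) -> None:
        """Export the OPD matrix with metadata for inspection/plotting."""
        np.savez(
            Path(path),
            opd_um=self.wavefront.opd,
            zone_powers_d=self.zone_powers_d,
            n_zones=self.n_zones,
            aperture_radius_mm=self.aperture_radius_mm,
            matrix_size=self.wavefront.grid.matrix_size,
            pupil_fill=self.wavefront.grid.pupil_fill,
            wavelength_nm=self.wavefront.grid.wavelength_nm,
        )


def _defocus_basis(grid: GridSpec, aperture_radius_mm: float):
    """(Z_2^0 map over the aperture, pupil mask); zeros outside."""
    r, _ = grid.radial_coords(aperture_radius_mm)
    mask = r <= aperture_radius_mm
    rho = np.zeros_like(r)
    rho[mask] = r[mask] / aperture_radius_mm
    z20 = np.zeros_like(r)
    z20[mask] = zernike_value(2, 0, rho[mask], 0.0)
    return z20, mask


def default_zone_count(profile: SagittalProfile, aperture_radius_mm: float) -> int:
    """One zone per profile sample inside the aperture (instrument-native)."""
    return max(1, profile.samples_within(aperture_radius_mm))


def build_multifocal_wavefront(
    profile: SagittalProfile,
    aperture_radius_mm: float,
    n_zones: int | None = None,
    grid: GridSpec | None = None,
    extra_opd: np.ndarray | None = None,
) -> MultifocalAssembly:
    """Assemble W_CL from a sagittal profile by annular segmentation.

    Each zone carries the pure-defocus wavefront of its sagittal power,
    evaluated over the *full* aperture and then masked to its annulus.
    ``extra_opd`` (µm, full-grid array) is added inside every zone before
    masking, which implements the per-zone w_(CL+Eye) superposition.
    """
    grid = grid or GridSpec()
    R = float(aperture_radius_mm)
    if R > profile.max_radius_mm + 1e-12:
        raise ValueError(
            f"aperture radius {R} mm exceeds the measured lens radius "
            f"{profile.max_radius_mm} mm; use combine_with_eye, which clamps "
            "to min(pupil radius, lens radius)"
        )
    if n_zones is None:
        n_zones = default_zone_count(profile, R)
    powers = annulus_powers(profile, n_zones, R)
    c20 = np.array([defocus_coeff_from_diopters(p, R) for p in powers])
    z20, mask = _defocus_basis(grid, R)
    zones = zone_index_map(grid, R, n_zones)
    opd = np.full(zones.shape, np.nan)
    opd[mask] = c20[zones[mask]] * z20[mask]
    if extra_opd is not None:
        opd[mask] += extra_opd[mask]
    wavefront = WavefrontMap(opd, R, grid)
    return MultifocalAssembly(wavefront, powers, n_zones, R, None)


def eye_wavefront(
    eye: EyeRecord, grid: GridSpec, aperture_radius_mm: float | None = None
) -> WavefrontMap:
    """W_Eye synthesized over the eye's measured pupil, cropped to R.

    Coefficients keep their meaning over the measurement pupil; the map is
    restricted spatially, never rescaled, so R must not exceed the
    measured pupil radius.
    """
    R = aperture_radius_mm if aperture_radius_mm is not None else eye.pupil_radius_mm
    if R > eye.pupil_radius_mm + 1e-12:
        raise ValueError("aperture exceeds the eye's measured pupil radius")
    r, theta = grid.radial_coords(R)
    mask = r <= R
    rho = np.zeros_like(r)
    rho[mask] = r[mask] / eye.pupil_radius_mm
    opd = np.zeros_like(r)
    from .zernike import osa_to_nm

    for j, c in eye.zernikes.coeffs.items():
        if c == 0.0:
            continue
        n, m = osa_to_nm(j)
        opd[mask] += c * zernike_value(n, m, rho[mask], theta[mask])
    opd[~mask] = np.nan
    return WavefrontMap(opd, R, grid)


def combine_with_eye(
    profile: SagittalProfile,
    eye: EyeRecord,
    grid: GridSpec | None = None,
    n_zones: int | None = None,
) -> MultifocalAssembly:
    """W_T = W_CL + W_Eye over R = min(eye pupil radius, lens radius)."""
    grid = grid or GridSpec()
    R = min(eye.pupil_radius_mm, profile.max_radius_mm)
    eye_map = eye_wavefront(eye, grid, R)
    assembly = build_multifocal_wavefront(
        profile, R, n_zones=n_zones, grid=grid, extra_opd=eye_map.filled(0.0)
    )
    assembly.eye = eye
    return assembly
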