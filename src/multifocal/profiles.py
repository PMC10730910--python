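"""Reading, validation and preprocessing of lens sagittal power profiles
and per-eye aberration tables.

A sagittal (axial) power profile gives the local lens power, in diopters,
as a function of the radial coordinate from the lens center, as produced
by Schlieren-based metrology instruments (nominally 28 samples per
millimeter).  Profiles carry their distance (base) prescription, which is
removed before any wavefront construction so that analysis focuses on the
multifocal structure of the lens rather than its refractive correction.

File dialect: comma-separated values, '.' decimal separator, '#'-prefixed
metadata lines (``# lens=``, ``# base_power_D=``, ``# addition_D=``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .zernike import ZernikeCoefficients, osa_to_nm

__all__ = [
    "SagittalProfile",
    "EyeRecord",
    "read_profile",
    "write_profile",
    "remove_base_power",
    "power_at_annulus",
    "annulus_powers",
    "read_eye_table",
    "write_eye_table",
]

#: nominal radial sampling density of the metrology instrument (points/mm)
NOMINAL_SAMPLING_PER_MM = 28.0


@dataclass
class SagittalProfile:
    """Radial sagittal power samples of a lens (mm, D) with metadata."""

    radii_mm: np.ndarray
    powers_d: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.powers_d = np.asarray(self.powers_d, dtype=float)
        if self.radii_mm.ndim != 1 or self.radii_mm.shape != self.powers_d.shape:
            raise ValueError("radii and powers must be 1-D arrays of equal length")
        if self.radii_mm.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if self.radii_mm[0] < 0:
            raise ValueError("radii must start at or above 0")
        if np.any(np.diff(self.radii_mm) <= 0):
            raise ValueError("radii must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(self.powers_d)):
            raise ValueError("non-finite power values")
        self.meta.setdefault(
            "sampling_per_mm",
            float((self.radii_mm.size - 1) / (self.radii_mm[-1] - self.radii_mm[0])),
        )

    @property
    def max_radius_mm(self) -> float:
        return float(self.radii_mm[-1])

    def samples_within(self, radius_mm: float) -> int:
        return int(np.count_nonzero(self.radii_mm <= radius_mm))


def read_profile(path) -> SagittalProfile:
    """Read a profile CSV (radius_mm, power_D) with optional metadata lines.

    Rows may appear in any order; radii are sorted ascending.  Duplicate
    radii and non-numeric rows are rejected with the offending line named.
    """
    path = Path(path)
    meta: dict = {}
    radii: list[float] = []
    powers: list[float] = []
    header_allowed = True
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                key = key.strip()
                value = value.strip()
                if key in ("base_power_D", "addition_D", "sampling_per_mm"):
                    meta[key] = float(value)
                else:
                    meta[key] = value
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        try:
            r, p = float(parts[0]), float(parts[1])
        except ValueError:
            if header_allowed:
                header_allowed = False
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from None
        header_allowed = False
        radii.append(r)
        powers.append(p)
    if len(radii) < 2:
        raise ValueError(f"{path}: fewer than 2 numeric samples")
    order = np.argsort(radii)
    radii_arr = np.asarray(radii)[order]
    powers_arr = np.asarray(powers)[order]
    if np.any(np.diff(radii_arr) == 0):
        raise ValueError(f"{path}: duplicate radii in profile")
    return SagittalProfile(radii_arr, powers_arr, meta)


def write_profile(path, profile: SagittalProfile) -> None:
    """Write a profile in the canonical CSV dialect (round-trips read_profile)."""
    path = Path(path)
    lines = []
    for key in ("lens", "base_power_D", "addition_D", "sampling_per_mm"):
        if key in profile.meta:
            value = profile.meta[key]
            if isinstance(value, float):
                lines.append(f"# {key}={value:.9g}")
            else:
                lines.append(f"# {key}={value}")
    lines.append("radius_mm,power_D")
    for r, p in zip(profile.radii_mm, profile.powers_d):
        lines.append(f"{r:.9g},{p:.9g}")
    path.write_text("\n".join(lines) + "\n")


def remove_base_power(profile: SagittalProfile, base_d: float) -> SagittalProfile:
    """Subtract the distance (base) prescription from every sample."""
    meta = dict(profile.meta)
    meta["base_removed_D"] = meta.get("base_removed_D", 0.0) + base_d
    return SagittalProfile(profile.radii_mm.copy(), profile.powers_d - base_d, meta)


def _zone_edges(n_zones: int, aperture_radius_mm: float) -> np.ndarray:
    return aperture_radius_mm * np.arange(n_zones + 1) / n_zones


def annulus_powers(
    profile: SagittalProfile, n_zones: int, aperture_radius_mm: float
) -> np.ndarray:
    """Zone powers D_l for all annuli [R l/n, R (l+1)/n), l = 0..n-1.

    Each zone takes the mean of the profile samples whose radius falls in
    its annulus (half-open intervals, last zone closed at R); zones
    containing no sample fall back to linear interpolation of the profile
    at the annulus midpoint.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    R = float(aperture_radius_mm)
    if R <= 0:
        raise ValueError("aperture radius must be positive")
    if R > profile.max_radius_mm + 1e-12:
        raise ValueError(
            f"aperture radius {R} mm exceeds measured lens radius "
            f"{profile.max_radius_mm} mm; clamp with the min(pupil, lens) rule"
        )
    r = profile.radii_mm
    inside = r <= R
    zone = np.minimum((r[inside] * n_zones / R).astype(int), n_zones - 1)
    sums = np.bincount(zone, weights=profile.powers_d[inside], minlength=n_zones)
    counts = np.bincount(zone, minlength=n_zones)
    powers = np.empty(n_zones)
    filled = counts > 0
    powers[filled] = sums[filled] / counts[filled]
    if not np.all(filled):
        edges = _zone_edges(n_zones, R)
        mids = 0.5 * (edges[:-1] + edges[1:])
        powers[~filled] = np.interp(mids[~filled], profile.radii_mm, profile.powers_d)
    return powers


def power_at_annulus(
    profile: SagittalProfile, l: int, n_zones: int, aperture_radius_mm: float
) -> float:
    """Zone power D_l for annulus l of n over aperture radius R (diopters)."""
    if not 0 <= l <= n_zones - 1:
        raise IndexError(f"zone index {l} out of range for n={n_zones}")
    return float(annulus_powers(profile, n_zones, aperture_radius_mm)[l])


@dataclass
class EyeRecord:
    """One eye: its Zernike aberrations and its physiological pupil."""

    zernikes: ZernikeCoefficients
    pupil_diameter_mm: float
    eye_id: str = ""

    def __post_init__(self) -> None:
        if self.pupil_diameter_mm <= 0:
            raise ValueError(f"eye {self.eye_id!r}: pupil diameter must be positive")
        if abs(self.zernikes.pupil_radius_mm - self.pupil_diameter_mm / 2) > 1e-9:
            raise ValueError(
                f"eye {self.eye_id!r}: coefficient pupil does not match pupil_diameter_mm"
            )

    @property
    def pupil_radius_mm(self) -> float:
        return self.pupil_diameter_mm / 2.0


def read_eye_table(path) -> list[EyeRecord]:
    """Read an eye table CSV: eye_id, pupil_diameter_mm, z0...zJ (OSA index).

    Missing higher-order columns are treated as zero coefficients.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"eye_id", "pupil_diameter_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    zcols = []
    for col in df.columns:
        if col.startswith("z") and col[1:].isdigit():
            osa_to_nm(int(col[1:]))  # validates index
            zcols.append(col)
    records = []
    for _, row in df.iterrows():
        pupil = float(row["pupil_diameter_mm"])
        if pupil <= 0:
            raise ValueError(f"{path}: eye {row['eye_id']!r} has non-positive pupil")
        coeffs = {
            int(col[1:]): float(row[col])
            for col in zcols
            if np.isfinite(row[col]) and row[col] != 0.0
        }
        records.append(
            EyeRecord(
                ZernikeCoefficients(coeffs, pupil / 2.0),
                pupil,
                str(row["eye_id"]),
            )
        )
    return records


def write_eye_table(path, eyes: list[EyeRecord], max_osa_index: int = 27) -> None:
    """Write an eye table CSV readable by :func:`read_eye_table`."""
    path = Path(path)
    cols = [f"z{j}" for j in range(max_osa_index + 1)]
    rows = []
    for eye in eyes:
        row = {"eye_id": eye.eye_id, "pupil_diameter_mm": eye.pupil_diameter_mm}
        for j in range(max_osa_index + 1):
            row[f"z{j}"] = eye.zernikes.coeffs.get(j, 0.0)
        rows.append(row)
    pd.DataFrame(rows, columns=["eye_id", "pupil_diameter_mm", *cols]).to_csv(
        path, index=False
    )
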