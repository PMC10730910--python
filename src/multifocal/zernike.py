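"""OSA/ANSI-normalized Zernike polynomials and wavefront synthesis.

Ocular wavefronts are conventionally expanded in the orthonormal Zernike
basis of the OSA/ANSI Z80.28 standard.  Coefficients are expressed in
micrometres of optical path difference (OPD) and are always defined over an
explicit pupil radius; a coefficient without its pupil is meaningless.

The module provides

* scalar/vectorized evaluation of single Zernike modes,
* synthesis of a sampled wavefront map from a coefficient set,
* the paraxial conversion between a sphere power in diopters and the
  defocus coefficient c(2,0), and
* plain-text I/O for coefficient tables.

Sign convention: positive sphere power maps to a *negative* defocus
coefficient (myopic-defocus convention), ``c(2,0) = -P r^2 / (4 sqrt(3))``
with P in diopters and r the pupil radius.  Only relative consistency of
this sign matters for through-focus analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "osa_index",
    "osa_to_nm",
    "zernike_value",
    "ZernikeCoefficients",
    "GridSpec",
    "WavefrontMap",
    "wavefront_from_coeffs",
    "defocus_coeff_from_diopters",
    "diopters_from_defocus_coeff",
    "read_coefficients",
    "write_coefficients",
]

_SQRT3 = math.sqrt(3.0)


def _validate_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise IndexError(f"invalid Zernike index (n={n}, m={m})")


def osa_index(n: int, m: int) -> int:
    """OSA/ANSI single index j for radial order n, azimuthal frequency m."""
    _validate_nm(n, m)
    return (n * (n + 2) + m) // 2


def osa_to_nm(j: int) -> tuple[int, int]:
    """Inverse of :func:`osa_index`."""
    if j < 0:
        raise IndexError(f"invalid OSA index {j}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    _validate_nm(n, m)
    return n, m


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_value(n: int, m: int, rho, theta):
    """Orthonormal (OSA/ANSI) Zernike polynomial Z_n^m(rho, theta).

    ``rho`` is the radius normalized to the pupil (valid on [0, 1]);
    ``theta`` the azimuth in radians.  Scalars or arrays accepted.
    """
    _validate_nm(n, m)
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (m == 0)))
    rad = _radial(n, abs(m), rho)
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(theta)
    val = norm * rad * ang
    if val.ndim == 0:
        return float(val)
    return val


@dataclass(frozen=True)
class GridSpec:
    """Square computation grid for pupil-plane sampling.

    ``pupil_fill`` is the fraction of the grid side spanned by the pupil
    *diameter*; keeping it at or below 0.5 provides the zero padding
    required for alias-free OTF computation.  ``wavelength_nm`` travels
    with the grid because the frequency calibration of the OTF depends on
    both the sampling pitch and the wavelength.
    """

    matrix_size: int = 512
    pupil_fill: float = 0.25
    wavelength_nm: float = 555.0

    def __post_init__(self) -> None:
        if self.matrix_size < 64 or self.matrix_size % 2:
            raise ValueError("matrix_size must be even and >= 64")
        if not 0.0 < self.pupil_fill <= 1.0:
            raise ValueError("pupil_fill must lie in (0, 1]")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")

    def pixel_pitch_mm(self, pupil_radius_mm: float) -> float:
        """Physical pupil-plane pitch, set so the pupil spans pupil_fill of the grid."""
        return 2.0 * pupil_radius_mm / (self.pupil_fill * self.matrix_size)

    def radial_coords(self, pupil_radius_mm: float):
        """(r_mm, theta) at pixel centers, origin at index N//2."""
        n = self.matrix_size
        pitch = self.pixel_pitch_mm(pupil_radius_mm)
        x = (np.arange(n) - n // 2) * pitch
        xx, yy = np.meshgrid(x, x)
        return np.hypot(xx, yy), np.arctan2(yy, xx)

    def pupil_mask(self, pupil_radius_mm: float) -> np.ndarray:
        """Pixel-center membership: inside iff center radius <= pupil radius."""
        r, _ = self.radial_coords(pupil_radius_mm)
        return r <= pupil_radius_mm


@dataclass
class ZernikeCoefficients:
    """OSA-indexed coefficient vector (µm) with its defining pupil radius."""

    coeffs: dict[int, float] = field(default_factory=dict)
    pupil_radius_mm: float = 2.06

    def __post_init__(self) -> None:
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be positive")
        for j in self.coeffs:
            osa_to_nm(int(j))  # validates
        self.coeffs = {int(j): float(c) for j, c in self.coeffs.items()}

    @classmethod
    def from_nm(cls, coeffs: dict[tuple[int, int], float], pupil_radius_mm: float):
        return cls({osa_index(n, m): c for (n, m), c in coeffs.items()}, pupil_radius_mm)

    def get(self, n: int, m: int) -> float:
        return self.coeffs.get(osa_index(n, m), 0.0)

    def set(self, n: int, m: int, value: float) -> None:
        self.coeffs[osa_index(n, m)] = float(value)

    def scaled(self, factor: float) -> "ZernikeCoefficients":
        return ZernikeCoefficients(
            {j: factor * c for j, c in self.coeffs.items()}, self.pupil_radius_mm
        )

    def plus(self, other: "ZernikeCoefficients") -> "ZernikeCoefficients":
        if other.pupil_radius_mm != self.pupil_radius_mm:
            raise ValueError("cannot add coefficient sets over different pupils")
        out = dict(self.coeffs)
        for j, c in other.coeffs.items():
            out[j] = out.get(j, 0.0) + c
        return ZernikeCoefficients(out, self.pupil_radius_mm)


@dataclass
class WavefrontMap:
    """Optical path difference (µm) sampled on a square grid.

    Values are defined inside the pupil disk and NaN outside, so the pupil
    support is always recoverable from the map itself.
    """

    opd: np.ndarray
    pupil_radius_mm: float
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be positive")
        self.opd = np.asarray(self.opd, dtype=float)
        if self.opd.shape != (self.grid.matrix_size, self.grid.matrix_size):
            raise ValueError("opd shape does not match grid")
        if not np.all(np.isfinite(self.opd[self.mask])):
            raise ValueError("non-finite OPD inside pupil")

    @property
    def mask(self) -> np.ndarray:
        return self.grid.pupil_mask(self.pupil_radius_mm)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """OPD with the outside-pupil region replaced by ``fill``."""
        out = np.where(np.isfinite(self.opd), self.opd, fill)
        out[~self.mask] = fill
        return out

    def rms(self) -> float:
        """Root-mean-square OPD over the pupil (µm), piston included."""
        vals = self.opd[self.mask]
        return float(np.sqrt(np.mean(vals**2)))


def wavefront_from_coeffs(z: ZernikeCoefficients, grid: GridSpec) -> WavefrontMap:
    """Synthesize OPD(x, y) = sum_j c_j Z_j over the pupil disk."""
    r, theta = grid.radial_coords(z.pupil_radius_mm)
    mask = r <= z.pupil_radius_mm
    rho = np.zeros_like(r)
    rho[mask] = r[mask] / z.pupil_radius_mm
    opd = np.zeros_like(r)
    for j, c in z.coeffs.items():
        if c == 0.0:
            continue
        n, m = osa_to_nm(j)
        opd[mask] += c * zernike_value(n, m, rho[mask], theta[mask])
    opd[~mask] = np.nan
    return WavefrontMap(opd, z.pupil_radius_mm, grid)


def defocus_coeff_from_diopters(power_d: float, pupil_radius_mm: float) -> float:
    """Paraxial sphere power (D) -> defocus coefficient c(2,0) in µm.

    c(2,0) = -P r^2 / (4 sqrt(3)), with r the pupil radius.  Positive power
    yields a negative coefficient (myopic-defocus sign convention).
    """
    if pupil_radius_mm <= 0:
        raise ValueError("pupil_radius_mm must be positive")
    return -power_d * pupil_radius_mm**2 / (4.0 * _SQRT3)


def diopters_from_defocus_coeff(c20_um: float, pupil_radius_mm: float) -> float:
    """Inverse of :func:`defocus_coeff_from_diopters`."""
    if pupil_radius_mm <= 0:
        raise ValueError("pupil_radius_mm must be positive")
    return -c20_um * 4.0 * _SQRT3 / pupil_radius_mm**2


def write_coefficients(path, z: ZernikeCoefficients) -> None:
    """Write a coefficient table: header, osa_index,coeff_um rows, pupil metadata."""
    path = Path(path)
    lines = [f"# pupil_diameter_mm={2.0 * z.pupil_radius_mm:.6g}", "osa_index,coeff_um"]
    for j in sorted(z.coeffs):
        lines.append(f"{j},{z.coeffs[j]:.9g}")
    path.write_text("\n".join(lines) + "\n")


def read_coefficients(path) -> ZernikeCoefficients:
    """Read a coefficient table written by :func:`write_coefficients`."""
    path = Path(path)
    pupil_diameter = None
    coeffs: dict[int, float] = {}
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("pupil_diameter_mm"):
                pupil_diameter = float(body.split("=", 1)[1])
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["osa_index", "coeff_um"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header 'osa_index,coeff_um'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        try:
            j, c = int(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: unparseable row {line!r}") from exc
        coeffs[j] = c
    if pupil_diameter is None:
        raise ValueError(f"{path}: missing '# pupil_diameter_mm=' metadata line")
    return ZernikeCoefficients(coeffs, pupil_diameter / 2.0)
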