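"""Synthetic lens profiles and eye populations.

The study-scale inputs — sagittal power profiles of commercial multifocal
contact lenses and a 65-eye aberrometry database — are not public, so
this module generates realistic stand-ins covering the same design space:

* profile morphologies: monofocal, center-near, center-distance, aspheric
  (add decaying from center to edge) and concentric bifocal, with
  additions between 0.75 and 3.00 D, sampled at the instrument-native 28
  points/mm over 0-5 mm radius, with optional Gaussian measurement noise;
* eye populations with 2nd-5th order Zernike terms plus 6th-order
  spherical aberration, order-decaying coefficient magnitudes, a positive
  population mean of primary spherical aberration, and physiological
  pupil diameters spanning 2.45-6.27 mm.

All randomness flows from explicit seeds; identical specs and seeds
reproduce identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import NOMINAL_SAMPLING_PER_MM, EyeRecord, SagittalProfile
from .zernike import ZernikeCoefficients, osa_index

__all__ = [
    "LensDesignSpec",
    "EyePopulationSpec",
    "generate_lens_profile",
    "generate_eye_population",
    "with_equivalent_sphere",
    "generate_study_batch",
    "DESIGNS",
    "STUDY_BASE_POWERS_D",
]

DESIGNS = (
    "monofocal",
    "center_near",
    "center_distance",
    "aspheric",
    "concentric_bifocal",
)

#: distance prescriptions measured in the study emulation
STUDY_BASE_POWERS_D = (-6.0, -3.0, 1.0)


@dataclass
class LensDesignSpec:
    """Parametric description of one synthetic lens profile."""

    design: str = "monofocal"
    base_power_d: float = -3.0
    addition_d: float = 0.0
    zone_boundaries_mm: tuple = (1.5,)
    transition_width_mm: float = 0.5
    max_radius_mm: float = 5.0
    sampling_per_mm: float = NOMINAL_SAMPLING_PER_MM
    noise_sd_d: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(
                f"unknown design {self.design!r}; valid designs: {', '.join(DESIGNS)}"
            )
        if self.addition_d < 0:
            raise ValueError("addition must be non-negative")
        if self.sampling_per_mm <= 0:
            raise ValueError("sampling density must be positive")
        for b in self.zone_boundaries_mm:
            if not 0 < b < self.max_radius_mm:
                raise ValueError("zone boundaries must lie inside (0, max_radius)")


def _raised_cosine_step(r: np.ndarray, boundary: float, width: float) -> np.ndarray:
    """Smooth 1 -> 0 step centered on ``boundary`` over ``width`` (hard if 0)."""
    if width <= 0:
        return (r < boundary).astype(float)
    lo, hi = boundary - width / 2.0, boundary + width / 2.0
    out = np.zeros_like(r)
    out[r <= lo] = 1.0
    ramp = (r > lo) & (r < hi)
    out[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - lo) / width))
    return out


def generate_lens_profile(spec: LensDesignSpec) -> SagittalProfile:
    """Deterministic synthetic sagittal profile for a design template."""
    n = int(round(spec.max_radius_mm * spec.sampling_per_mm)) + 1
    radii = np.arange(n) / spec.sampling_per_mm
    base, add = spec.base_power_d, spec.addition_d
    if spec.design == "monofocal":
        powers = np.full(n, base)
    elif spec.design == "center_near":
        powers = base + add * _raised_cosine_step(
            radii, spec.zone_boundaries_mm[0], spec.transition_width_mm
        )
    elif spec.design == "center_distance":
        powers = base + add * (
            1.0
            - _raised_cosine_step(
                radii, spec.zone_boundaries_mm[0], spec.transition_width_mm
            )
        )
    elif spec.design == "aspheric":
        powers = base + add * (1.0 - (radii / spec.max_radius_mm) ** 2)
    else:  # concentric_bifocal: alternating base / base+add rings
        ring = np.zeros(n, dtype=int)
        for b in sorted(spec.zone_boundaries_mm):
            ring += radii >= b
        near_ring = (ring % 2 == 1).astype(float)
        if spec.transition_width_mm > 0:
            smooth = np.zeros(n)
            state = 0.0
            for b in sorted(spec.zone_boundaries_mm):
                step = _raised_cosine_step(radii, b, spec.transition_width_mm)
                smooth = smooth + (1.0 - step) * (1.0 - 2.0 * state)
                state = 1.0 - state
            near_ring = np.clip(smooth, 0.0, 1.0)
        powers = base + add * near_ring
    if spec.noise_sd_d > 0:
        rng = np.random.default_rng(spec.seed)
        powers = powers + rng.normal(0.0, spec.noise_sd_d, size=n)
    meta = {
        "lens": spec.label or spec.design,
        "base_power_D": base,
        "addition_D": add,
        "sampling_per_mm": spec.sampling_per_mm,
        "design": spec.design,
    }
    return SagittalProfile(radii, powers, meta)


#: pupil diameter (mm) at which the population coefficient scales are stated
REFERENCE_PUPIL_MM = 6.0


@dataclass
class EyePopulationSpec:
    """Parametric description of a synthetic aberrometry population.

    Coefficient scales are per radial order, in µm over a 6 mm reference
    pupil, decaying with order as in normal adult populations; each eye's
    coefficients are scaled to its own pupil as (r / 3 mm)^n, the leading
    power-law of Zernike pupil dependence, so small pupils carry
    correspondingly small aberrations.  Primary spherical aberration
    c(4,0) receives a positive population mean.  Defocus is drawn in
    diopters (residual equivalent sphere of a distance-corrected eye) and
    converted to c(2,0) over each eye's pupil.  Included modes: full
    orders 2-5 plus (6,0).
    """

    n_eyes: int = 65
    pupil_range_mm: tuple = (2.45, 6.27)
    order_scales_um: dict = field(
        default_factory=lambda: {2: 0.15, 3: 0.12, 4: 0.05, 5: 0.02, 6: 0.01}
    )
    sa_mean_um: float = 0.12
    equivalent_sphere_sd_d: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        lo, hi = self.pupil_range_mm
        if not (1.0 < lo <= hi < 9.0):
            raise ValueError("pupil_range must lie within (1, 9) mm")


def _included_modes() -> list[tuple[int, int]]:
    modes = []
    for n in (2, 3, 4, 5):
        for m in range(-n, n + 1, 2):
            modes.append((n, m))
    modes.append((6, 0))
    return modes


def generate_eye_population(spec: EyePopulationSpec) -> list[EyeRecord]:
    """Draw a deterministic population of synthetic eyes."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pupil_range_mm
    pupils = rng.uniform(lo, hi, size=spec.n_eyes)
    ref_radius = REFERENCE_PUPIL_MM / 2.0
    eyes = []
    for i in range(spec.n_eyes):
        radius = pupils[i] / 2.0
        coeffs: dict[int, float] = {}
        for n, m in _included_modes():
            if (n, m) == (2, 0):
                # residual equivalent sphere, drawn in diopters
                sphere = rng.normal(0.0, spec.equivalent_sphere_sd_d)
                c = sphere * radius**2 / (4.0 * np.sqrt(3.0))
            else:
                scale = spec.order_scales_um.get(n, 0.0)
                c = rng.normal(0.0, scale) if scale > 0 else 0.0
                if (n, m) == (4, 0):
                    c += spec.sa_mean_um
                c *= (radius / ref_radius) ** n
            if c != 0.0:
                coeffs[osa_index(n, m)] = c
        eyes.append(
            EyeRecord(
                ZernikeCoefficients(coeffs, pupils[i] / 2.0),
                float(pupils[i]),
                eye_id=f"eye{i + 1:03d}",
            )
        )
    return eyes


def with_equivalent_sphere(eye: EyeRecord, sphere_d: float) -> EyeRecord:
    """Inject an equivalent-sphere refractive error of ``sphere_d`` diopters.

    The eye's through-focus VSOTF with a plano monofocal lens then peaks
    at added vergence ``sphere_d``, so the recovered distance-correction
    shift is ``-sphere_d``.
    """
    r = eye.pupil_radius_mm
    c20_extra = sphere_d * r**2 / (4.0 * np.sqrt(3.0))
    z = ZernikeCoefficients(dict(eye.zernikes.coeffs), r)
    z.set(2, 0, z.get(2, 0) + c20_extra)
    return EyeRecord(z, eye.pupil_diameter_mm, eye.eye_id)


#: the 12 synthetic multifocal designs of a study batch: four families,
#: additions spanning 0.75-2.75 D (low / medium / high presbyopic targets)
_BATCH_DESIGNS = (
    ("CN-1.00", "center_near", 1.00),
    ("CN-1.75", "center_near", 1.75),
    ("CN-2.50", "center_near", 2.50),
    ("CD-1.00", "center_distance", 1.00),
    ("CD-1.75", "center_distance", 1.75),
    ("CD-2.50", "center_distance", 2.50),
    ("ASP-0.75", "aspheric", 0.75),
    ("ASP-1.50", "aspheric", 1.50),
    ("ASP-2.25", "aspheric", 2.25),
    ("BIF-1.25", "concentric_bifocal", 1.25),
    ("BIF-2.00", "concentric_bifocal", 2.00),
    ("BIF-2.75", "concentric_bifocal", 2.75),
)


def generate_study_batch(
    seed: int,
    n_eyes: int = 65,
    base_powers_d: tuple = STUDY_BASE_POWERS_D,
    noise_sd_d: float = 0.05,
    sampling_per_mm: float = NOMINAL_SAMPLING_PER_MM,
) -> tuple[list[SagittalProfile], list[EyeRecord]]:
    """Full synthetic study batch: 12 designs x len(base_powers) profiles,
    one monofocal control, and the eye population.

    Profile labels are ``<design>@<base>D``; the monofocal control is
    generated at the middle base power.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    profiles: list[SagittalProfile] = []
    for name, design, addition in _BATCH_DESIGNS:
        for base in base_powers_d:
            spec = LensDesignSpec(
                design=design,
                base_power_d=base,
                addition_d=addition,
                zone_boundaries_mm=(1.0, 1.75, 2.5, 3.25, 4.0)
                if design == "concentric_bifocal"
                else (1.5,),
                transition_width_mm=0.4,
                noise_sd_d=noise_sd_d,
                sampling_per_mm=sampling_per_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
                label=f"{name}@{base:+.2f}D",
            )
            profiles.append(generate_lens_profile(spec))
    mono_base = base_powers_d[len(base_powers_d) // 2]
    mono_spec = LensDesignSpec(
        design="monofocal",
        base_power_d=mono_base,
        noise_sd_d=noise_sd_d,
        sampling_per_mm=sampling_per_mm,
        seed=int(rng.integers(0, 2**31 - 1)),
        label="monofocal",
    )
    profiles.append(generate_lens_profile(mono_spec))
    eyes = generate_eye_population(
        EyePopulationSpec(n_eyes=n_eyes, seed=int(rng.integers(0, 2**31 - 1)))
    )
    return profiles, eyes
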