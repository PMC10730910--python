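"""Run configuration: every study constant surfaced as a named key.

Defaults reproduce the canonical simulation conditions: 512x512 matrix,
pupil filling a quarter of the grid side, 555 nm, the 193-sample
[-1, +5] D vergence grid, a 60 cpd frequency cutoff and the 0.12 VSOTF
acceptable-vision threshold.  A ``--fast`` profile (128x128 matrix, zone
count capped) is provided for batch runs and smoke tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fourier import NeuralCSF
from .zernike import GridSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    matrix_size: int = 512
    pupil_fill: float = 0.25
    wavelength_nm: float = 555.0
    vergence_min_d: float = -1.0
    vergence_max_d: float = 5.0
    vergence_samples: int = 193
    freq_cutoff_cpd: float = 60.0
    threshold: float = 0.12
    csf: dict = field(
        default_factory=lambda: {
            "gain": 2.6,
            "low_freq_floor": 0.0192,
            "freq_scale_cpd": 1.0 / 0.114,
            "exponent": 1.1,
        }
    )
    seed: int = 0
    #: optional cap on the number of annular zones (None = instrument-native)
    zone_cap: int | None = None
    #: "added_defocus" (pupil-plane convention) or "object_vergence" (negated axis)
    axis_orientation: str = "added_defocus"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.axis_orientation not in ("added_defocus", "object_vergence"):
            raise ValueError("axis_orientation must be 'added_defocus' or 'object_vergence'")

    def grid(self) -> GridSpec:
        return GridSpec(self.matrix_size, self.pupil_fill, self.wavelength_nm)

    def neural_csf(self) -> NeuralCSF:
        return NeuralCSF(**self.csf)

    def vergence_grid(self) -> np.ndarray:
        return np.linspace(self.vergence_min_d, self.vergence_max_d, self.vergence_samples)

    def fast(self) -> "RunConfig":
        """Reduced-resolution profile for batch runs: 128 grid, zones capped."""
        cfg = RunConfig(**{**asdict(self), "matrix_size": 128, "zone_cap": 48})
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
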