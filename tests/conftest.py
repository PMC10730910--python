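import numpy as np
import pytest

from multifocal import EyeRecord, GridSpec, ZernikeCoefficients

#: average pupil diameter of the emulated subject database (mm)
AVERAGE_PUPIL_MM = 4.12


@pytest.fixture(scope="session")
def grid64():
    return GridSpec(64, 0.25, 555.0)


@pytest.fixture(scope="session")
def grid128():
    return GridSpec(128, 0.25, 555.0)


@pytest.fixture(scope="session")
def grid512():
    return GridSpec(512, 0.25, 555.0)


@pytest.fixture
def clean_eye():
    """Aberration-free eye at the database-average pupil size."""
    return EyeRecord(
        ZernikeCoefficients({}, AVERAGE_PUPIL_MM / 2), AVERAGE_PUPIL_MM, "clean"
    )


@pytest.fixture
def flat_profile():
    """A plano (0 D everywhere) lens profile sampled at 28 points/mm."""
    from multifocal import LensDesignSpec, generate_lens_profile

    return generate_lens_profile(
        LensDesignSpec(design="monofocal", base_power_d=0.0)
    )


def direct_autocorrelation_otf(pupil: np.ndarray) -> np.ndarray:
    """Independent OTF oracle: direct (non-FFT) pupil autocorrelation.

    Returns the full (2N-1)-sized normalized autocorrelation
    sum_x P(x+s) conj(P(x)); the OTF equals its central crop.
    """
    from scipy.signal import correlate2d

    ac = correlate2d(pupil, pupil, mode="full")
    n = pupil.shape[0]
    return ac / ac[n - 1, n - 1]


def crop_center(full: np.ndarray, n: int) -> np.ndarray:
    """Central n x n crop of a (2n-1) x (2n-1) autocorrelation, zero shift at n//2."""
    c = full.shape[0] // 2
    h = n // 2
    return full[c - h : c + h, c - h : c + h]
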