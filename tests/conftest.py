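import numpy as np
import pytest

from radstab.synth import CohortSpec, LesionParams, generate_lesion
from radstab.types import ImageVolume, LesionSample, ROIMask


@pytest.fixture(scope="session")
def small_lesion() -> LesionSample:
    """A compact textured lesion cheap enough for brute-force oracles."""
    return generate_lesion(
        LesionParams(semiaxes_mm=(4.0, 5.0, 5.0), texture_sd_hu=80.0, noise_sd_hu=5.0),
        spacing=(2.0, 1.0, 1.0),
        shape=(8, 16, 16),
        seed=7,
    )


@pytest.fixture(scope="session")
def fixture_lesions() -> list[LesionSample]:
    """Three small lesions spanning smooth, textured and noisy regimes."""
    cases = [
        LesionParams(semiaxes_mm=(4.0, 5.0, 5.0), texture_sd_hu=0.0, noise_sd_hu=0.0,
                     texture_corr_mm=4.0),
        LesionParams(semiaxes_mm=(4.0, 6.0, 5.0), texture_sd_hu=80.0, noise_sd_hu=5.0,
                     texture_corr_mm=2.0),
        LesionParams(semiaxes_mm=(5.0, 4.0, 6.0), texture_sd_hu=30.0, noise_sd_hu=40.0,
                     texture_corr_mm=6.0),
    ]
    return [
        generate_lesion(p, spacing=(2.0, 1.0, 1.0), shape=(8, 16, 16), seed=100 + i)
        for i, p in enumerate(cases)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_sample(volume: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                **kwargs) -> LesionSample:
    return LesionSample(
        volume=ImageVolume(volume, spacing),
        mask=ROIMask(mask, spacing),
        subject_id=kwargs.pop("subject_id", "s0"),
        **kwargs,
    )
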