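import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteostage.types import CtVolume, LesionRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_ellipsoid_mask(shape, center, radii):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


@pytest.fixture
def ellipsoid_case():
    """A quantized 64x64x20 volume with one centred ellipsoidal lesion."""
    rng = np.random.default_rng(42)
    shape = (64, 64, 20)
    vox = rng.integers(20, 60, size=shape).astype(np.uint8)
    mask = make_ellipsoid_mask(shape, (32, 30, 10), (9, 7, 4))
    vox[mask] = rng.integers(150, 220, size=int(mask.sum())).astype(np.uint8)
    vol = CtVolume(vox, (0.7, 0.7, 1.0), "P000", quantized=True)
    lesion = LesionRecord(
        lesion_id="P000_L001",
        patient_id="P000",
        label="malignant",
        subcategory="osteoblastic",
        mask_label=1,
    )
    return vol, mask, lesion


@pytest.fixture(scope="session")
def toy_cohort():
    from osteostage.synthetic import generate_cohort, separable_config

    return generate_cohort(separable_config(n_patients=5, seed=11))
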