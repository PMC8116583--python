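import numpy as np
import pytest

from fundusiod.roi_geometry import littmann_scale
from fundusiod.synth_cohort import (CohortParams, camera_constant_for,
                                    render_fundus_case, sample_subjects)

TEST_IMAGE_SIZE = 256


def random_level_patch(rng, shape=(8, 8), n_levels=4, p_mask=0.85):
    """Random quantized patch plus mask for texture-oracle comparisons."""
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < p_mask
    if mask.sum() < 4:  # keep matrices non-degenerate
        mask[:2, :2] = True
    return levels, mask


@pytest.fixture(scope="session")
def rendered_case():
    """One rendered synthetic case with annotation and magnification model."""
    subs, trus = sample_subjects(CohortParams(n_subjects=3, seed=21))
    sub, tru = subs[0], trus[0]
    mag = littmann_scale(sub.al, camera_constant_for(TEST_IMAGE_SIZE))
    image, ann = render_fundus_case(sub, tru, image_size_px=TEST_IMAGE_SIZE,
                                    scale_mm_per_px=mag.scale, seed=5)
    return {"subject": sub, "truth": tru, "mag": mag,
            "image": image, "annotation": ann}


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 6-case rendered dataset on disk."""
    from fundusiod.synth_cohort import generate_dataset

    out = tmp_path_factory.mktemp("dataset")
    params = CohortParams(n_subjects=6, seed=7)
    manifest = generate_dataset(params, out, image_size_px=TEST_IMAGE_SIZE)
    return {"dir": out, "params": params, "manifest": manifest}
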