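import numpy as np
import pytest
from hypothesis import settings

from mitomorph import morphology, segment, simulate

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noisy_field():
    """Small noisy field shared by segmentation/functional tests."""
    cfg = simulate.SimConfig(image_size_px=(512, 512), n_mitochondria=6,
                             n_mds=6, seed=1)
    return simulate.generate_field(cfg)


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free field with 30 mitochondria + 20 MDSs and protrusions."""
    cfg = simulate.SimConfig(image_size_px=(1024, 1024), n_mitochondria=30,
                             n_mds=20, poisson_noise=False,
                             gaussian_read_sigma=0.0, n_protrusions=12,
                             seed=7)
    return simulate.generate_field(cfg)


@pytest.fixture(scope="session")
def clean_objects(clean_field):
    """Segmented objects of the clean field, soma excluded."""
    # fixed threshold: the triangle rule needs a noise-broadened
    # histogram, which a noise-free render does not have
    mask = segment.binarize_global(clean_field.structural, 25.0)
    mask = segment.refine_mask(mask, [("fill_holes", None),
                                      ("erode", None), ("erode", None),
                                      ("remove_small", 8)])
    mask = segment.apply_region_exclusion(mask, clean_field.soma_mask)
    objects, intensity = morphology.label_objects(
        mask, clean_field.structural)
    return objects, intensity, mask


def render_isolated_capsule(width_nm, length_um=1.2, angle_deg=20.0,
                            noise_seed=None, peak=150.0, patch_px=80,
                            pixel_size_nm=25.0):
    """One capsule patch (optionally Poisson-noised), plus its SimConfig."""
    cfg = simulate.SimConfig(image_size_px=(patch_px, patch_px),
                             pixel_size_nm=pixel_size_nm,
                             poisson_noise=False, gaussian_read_sigma=0.0,
                             width_range_nm=(60.0, 600.0))
    center = (patch_px * pixel_size_nm * 1e-3 / 2,) * 2
    spec = simulate.ObjectSpec(center, angle_deg, length_um, width_nm)
    img = peak * simulate.render_membrane_object(spec, cfg,
                                                 (patch_px, patch_px))
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        img = rng.poisson(img + 3.0).astype(float)
    return img, spec, cfg
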