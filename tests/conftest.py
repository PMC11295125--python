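import numpy as np
import pytest

import flowim as f


@pytest.fixture(scope="session")
def small_cfg():
    """Optics for a reduced 1024x1024 desk-scale frame with a
    geometrically consistent per-frame volume."""
    return f.scaled_config(1024, 1024)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Optics for a very small 256x256 frame (fast unit tests)."""
    return f.scaled_config(256, 256)


@pytest.fixture(scope="session")
def mono_scene(small_cfg):
    """A medium-density monospecific scene with ground truth."""
    pop = f.sample_population(target_density=f.simulate.DENSITY_MEDIUM,
                              cfg=small_cfg, seed=41)
    return f.render_scene(pop, small_cfg, seed=42)


@pytest.fixture(scope="session")
def blank_scene(small_cfg):
    return f.render_scene([], small_cfg, seed=43)


def render_disk_roi(diameter_um=5.0, crop=48, focus=0.0, noise=0.01, seed=0,
                    aspect=1.0, morphotype="disk_cell"):
    """One centered particle crop, for feature tests."""
    cfg = f.OpticalConfig()
    s = cfg.sample_pixel_size
    p = f.ParticleSpec(
        center=(crop / 2 * s, crop / 2 * s),
        diameter=diameter_um,
        morphotype=morphotype,
        aspect_ratio=aspect,
        focus_offset=focus,
    )
    return f.render_particle_crop(p, cfg, crop_side=crop, noise_sd=noise, seed=seed)
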