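import numpy as np
import pytest

from hempspec import (
    build_scene_design,
    default_class_models,
    default_wavelengths,
    render_scene,
)


@pytest.fixture(scope="session")
def wl120():
    return default_wavelengths(120)


@pytest.fixture(scope="session")
def class_models():
    return default_class_models(("CW", "BX"), ("wk02", "wk04"), ("leaf", "flower"))


@pytest.fixture(scope="session")
def small_scene(wl120, class_models):
    """One rendered default-noise scene: 4 leaves + 4 flowers + panel."""
    labels = [("CW", "wk02", "leaf")] * 4 + [("CW", "wk02", "flower")] * 4
    design = build_scene_design(labels, seed=3)
    cube, gt, meta = render_scene(design, class_models, wl120)
    return design, cube, gt, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
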