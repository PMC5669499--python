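import warnings

import numpy as np
import pytest

from fovod.detector import init_model
from fovod.synthetic import SceneSpec, generate_dataset
from fovod.training import TrainConfig, train_fod
from fovod.visual_field import FieldConfig, build_field

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_field():
    return build_field(FieldConfig())


@pytest.fixture(scope="session")
def field52():
    """Field with the 52-px / 4-degree fovea; small templates fit inside."""
    return build_field(FieldConfig.preset_52px())


def make_handbuilt_model(field, shapes=((4, 4),), seed=0, n_scales=4,
                         scales_per_octave=4, zero=False):
    """A deterministic model with random (or zero) unit templates."""
    rng = None if zero else np.random.default_rng(seed)
    return init_model(field, shapes, rng=rng, n_scales=n_scales,
                      scales_per_octave=scales_per_octave, class_label="toy")


@pytest.fixture(scope="session")
def toy_model(field52):
    return make_handbuilt_model(field52, shapes=((4, 4), (3, 5)), seed=3)


@pytest.fixture(scope="session")
def small_scene_spec():
    """Reduced scenes for unit tests (not the acceptance conditions)."""
    return SceneSpec(size=(192, 192), center_bias=0.2,
                     objects_per_image=(0.3, 0.7))


@pytest.fixture(scope="session")
def small_trained():
    """One class trained at reduced scale; shared across test modules."""
    spec = SceneSpec(size=(256, 256), objects_per_image=(0.3, 0.7))
    train, test = generate_dataset(spec, 40, 8, seed=5)
    positives = [(r.image, b) for r in train
                 for c, b in r.annotations if c == "wedge"]
    backgrounds = [r.image for r in train]
    field = build_field(FieldConfig())
    cfg = TrainConfig(seed=5, n_scales=8, scales_per_octave=4,
                      target_template_px=64)
    model = train_fod(positives, backgrounds, field, cfg, "wedge")
    return {"model": model, "train": train, "test": test, "spec": spec,
            "config": cfg, "positives": positives,
            "backgrounds": backgrounds}
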