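import numpy as np
import pytest

from twpscope import RuleModel, SceneSpec, ParticleRequest, generate_scene
from twpscope.experiments import segment_and_measure


@pytest.fixture(scope="session")
def small_scene():
    """One 620 px tile with 8 haloed particles spanning 15-180 µm."""
    reqs = tuple(
        ParticleRequest(mfd_um=s, aspect=a, shape=sh)
        for s, a, sh in [
            (180.0, 1.2, "ellipse"),
            (140.0, 1.5, "superellipse"),
            (100.0, 1.0, "blob"),
            (70.0, 1.8, "ellipse"),
            (50.0, 1.3, "blob"),
            (35.0, 1.0, "superellipse"),
            (22.0, 1.1, "ellipse"),
            (15.0, 1.0, "ellipse"),
        ]
    )
    spec = SceneSpec(
        width_px=620, height_px=620, halo_width_um=(3.0, 5.0),
        particles=reqs, rng_seed=42,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def small_scene_table(small_scene):
    """Unfiltered particle table from the rule-classifier pipeline."""
    image, _ = small_scene
    return segment_and_measure(image, RuleModel())


def disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
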