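"""Shared fixtures: fast, small-scale scene configurations.

Unit tests run on miniaturized fields (small nuclei, small puncta) so the
whole suite stays fast; the acceptance tests use the full-scale defaults,
which encode the study conditions.
"""

import pytest

from chromoquant.nuclei import SegmentationParams
from chromoquant.puncta import PunctaParams
from chromoquant.scene import SceneConfig


def small_scene_config(seed=0, **overrides):
    base = dict(
        field_shape=(420, 420),
        n_nuclei=4,
        nucleus_radius_range=(50.0, 62.0),
        puncta_count_mean_neg=5.0,
        puncta_count_mean_pos=8.0,
        puncta_area_mean_neg=90.0,
        puncta_area_mean_pos=110.0,
        puncta_area_sd=15.0,
        seed=seed,
    )
    base.update(overrides)
    return SceneConfig(**base)


SMALL_SEG_PARAMS = SegmentationParams(min_area=2000, max_area=40000)
SMALL_PUNCTA_PARAMS = PunctaParams(min_area=20, max_area=600)
SMALL_BG_RADIUS = 85.0


@pytest.fixture(scope="session")
def small_scene():
    """One generated small scene (image, truth) shared across tests."""
    from chromoquant.scene import generate_widefield_scene

    cfg = small_scene_config(seed=42)
    image, truth = generate_widefield_scene(cfg)
    return cfg, image, truth
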