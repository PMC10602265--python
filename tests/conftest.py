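"""Shared fixtures: small synthetic scenes built programmatically."""

import numpy as np
import pytest

from gazesim.scene_data import SceneBundle, SynthObject, SynthSpec, synth_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact two-object scene for fast simulator runs (~20 x 15 dva)."""
    spec = SynthSpec(
        width_px=64,
        height_px=48,
        n_frames=90,
        fps=30.0,
        px_per_dva=3.2,
        objects=[
            SynthObject(shape="ellipse", size_px=(12, 10), position=(18, 14),
                        velocity=(0.4, 0.1), blob_amplitude=0.8, blob_width_px=6),
            SynthObject(shape="rectangle", size_px=(10, 8), position=(45, 34),
                        velocity=(-0.3, 0.0), blob_amplitude=0.6, blob_width_px=5),
        ],
        background_level=0.1,
        noise_sd=0.02,
        seed=7,
        scene_id="small",
    )
    return synth_scene(spec)


@pytest.fixture()
def static_scene():
    """A single static off-center object with a strong feature blob."""
    spec = SynthSpec(
        width_px=64,
        height_px=48,
        n_frames=60,
        fps=30.0,
        px_per_dva=3.2,
        objects=[
            SynthObject(shape="ellipse", size_px=(14, 12), position=(46, 16),
                        velocity=(0.0, 0.0), blob_amplitude=0.85, blob_width_px=7),
        ],
        background_level=0.05,
        noise_sd=0.0,
        seed=3,
        scene_id="static",
    )
    return synth_scene(spec)


def make_symmetric_scene(n_frames: int = 90) -> SceneBundle:
    """Two identical static objects mirror-symmetric about the centre."""
    spec = SynthSpec(
        width_px=65,
        height_px=49,
        n_frames=n_frames,
        fps=30.0,
        px_per_dva=3.2,
        objects=[
            SynthObject(shape="ellipse", size_px=(10, 10), position=(16, 24),
                        velocity=(0.0, 0.0), blob_amplitude=0.8, blob_width_px=5),
            SynthObject(shape="ellipse", size_px=(10, 10), position=(48, 24),
                        velocity=(0.0, 0.0), blob_amplitude=0.8, blob_width_px=5),
        ],
        background_level=0.05,
        noise_sd=0.0,
        seed=11,
        scene_id="sym",
    )
    return synth_scene(spec)
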