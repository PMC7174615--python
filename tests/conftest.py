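import numpy as np
import pytest

from headgrade.synthetic import SceneParams, generate_scene
from headgrade.segnet import ImprovedResNetSegmenter

# The scaled study conditions used across the suite: 96x96 single-head
# scenes, encoder widths 8/16/32/64, 10 training epochs on 48 scenes.
SCENE_KW = dict(height=96, width=96, n_heads=1, head_radius_range=(22, 38),
                leaf_occlusion_fraction=0.1)


def make_scenes(n, seed0, yellow_fraction=0.0, **overrides):
    """Generate n scenes; returns (images, head_masks, samples)."""
    kw = {**SCENE_KW, **overrides}
    samples = [generate_scene(SceneParams(**kw, yellow_fraction=yellow_fraction,
                                          seed=seed0 + i))
               for i in range(n)]
    X = np.stack([s.image for s in samples])
    Y = np.stack([s.head_mask for s in samples])
    return X, Y, samples


@pytest.fixture(scope="session")
def scene_batch():
    return make_scenes


@pytest.fixture(scope="session")
def trained_segmenter():
    """One scaled Improved-ResNet segmenter trained on 48 synthetic scenes,
    shared by the end-to-end and robustness tests."""
    X, Y, _ = make_scenes(48, seed0=100)
    est = ImprovedResNetSegmenter(epochs=10, batch_size=8, seed=0,
                                  dropout_rate=0.1)
    est.fit(X, Y)
    return est
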