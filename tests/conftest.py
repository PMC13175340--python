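import numpy as np
import pytest

import topogaze as tg


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def blob_scene():
    """A small scene with disks, an annulus and known bars (no frame contact)."""
    spec = tg.SceneSpec(
        height=96,
        width=96,
        background=255,
        primitives=(
            tg.Disk(20, 20, 8, 20),
            tg.Disk(70, 25, 7, 60),
            tg.Disk(30, 70, 6, 100),
            tg.Annulus(70, 70, 11, 5, 30, 160),
        ),
    )
    return tg.render(spec)


@pytest.fixture(scope="session")
def blob_pairs(blob_scene):
    img, _ = blob_scene
    return {
        d: tg.persistence(tg.build_filtration(img, d)) for d in ("BW", "WB")
    }


def pairs_multiset(pairs):
    return sorted((p.dim, p.birth, p.death, p.essential) for p in pairs)
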