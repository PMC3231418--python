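import numpy as np
import pytest

import oatfrost as of


@pytest.fixture(scope="session")
def small_scene():
    """A 256x256 synthetic field scene with its ground truth."""
    spec = of.SceneSpec(width=256, height=256, seed=11)
    rgb, truth = of.generate_scene(spec)
    return spec, rgb, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def role_map_from(labels, stats):
    """Map a classified label image onto role indices (GO, DO, HD, SG order)."""
    roles = of.semantic_mapping(stats)
    index = {r: i for i, r in enumerate(of.ROLES)}
    lut = {lbl: index[role] for lbl, role in roles.items()}
    out = np.empty_like(labels)
    for lbl, idx in lut.items():
        out[labels == lbl] = idx
    return out
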