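import numpy as np
import pytest

from yolocf.model import AnchorSet, ModelConfig, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Small-input cf5 model shared by tests that only need a forward pass."""
    return build_model(ModelConfig(num_classes=7, img_size=96), seed=0)


@pytest.fixture(scope="session")
def anchors():
    return AnchorSet()


@pytest.fixture(scope="session")
def easy_dataset_dir(tmp_path_factory):
    """A small written-to-disk easy synthetic dataset (96 px)."""
    from yolocf.synthdata import difficulty_presets, write_dataset

    root = tmp_path_factory.mktemp("easyds")
    spec = difficulty_presets()["easy"]
    spec.image_size = 96
    spec.seed = 11
    write_dataset(root, spec, 16, 8)
    return root
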