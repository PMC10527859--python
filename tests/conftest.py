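import numpy as np
import pytest

from dermoseg.dataset_io import SplitSpec, balance_downsample, split_dataset
from dermoseg.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """10 small images with the default sparse-attribute statistics."""
    outdir = tmp_path_factory.mktemp("tiny_isic")
    config = SynthConfig(n_images=10, side=64, seed=7, hair_probability=0.3)
    manifest, ledger = generate_dataset(config, outdir)
    return {"dir": outdir, "manifest": manifest, "ledger": ledger, "config": config}


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """24 easy-mode globule images for fast training smoke runs."""
    outdir = tmp_path_factory.mktemp("easy_isic")
    config = SynthConfig.easy_mode(n_images=24, side=96, seed=5)
    manifest, ledger = generate_dataset(config, outdir)
    return {"dir": outdir, "manifest": manifest, "ledger": ledger, "config": config}


@pytest.fixture(scope="session")
def easy_split(easy_dataset):
    balanced = balance_downsample(easy_dataset["manifest"], "globules", seed=0)
    train, val, test = split_dataset(balanced, SplitSpec(seed=0))
    return {"train": train, "val": val, "test": test}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
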