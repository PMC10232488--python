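from pathlib import Path

import numpy as np
import pytest

import histotile as ht


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory) -> Path:
    """A small on-disk synthetic dataset (3 classes x 8 tiles of 24x24)."""
    root = tmp_path_factory.mktemp("tiny_tiles")
    spec = ht.SyntheticSpec(n_classes=3, tiles_per_class=8, tile_size=(24, 24),
                            noise_sd=4.0, seed=11)
    ht.generate_dataset(spec, root)
    return root


@pytest.fixture(scope="session")
def bench_artifacts(tmp_path_factory):
    """The desk-scale synthetic benchmark, trained end to end once.

    Conditions: 8 classes, 200 tiles/class, 64x64 tiles, noise sd 8,
    generator seed 1; reduced backbone preset; 50 of 64 features selected.
    """
    data_dir = tmp_path_factory.mktemp("bench_data")
    out_dir = tmp_path_factory.mktemp("bench_run")
    spec = ht.SyntheticSpec(n_classes=8, tiles_per_class=200,
                            tile_size=(64, 64), noise_sd=8.0, seed=1)
    ht.generate_dataset(spec, data_dir)
    config = ht.desk_scale_config(seed=1)
    artifacts = ht.run_training(config, data_dir, out_dir)
    return artifacts
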