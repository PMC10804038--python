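"""Shared fixtures: small synthetic datasets and a fitted model.

Everything is generated programmatically at test time; sizes are kept
small so the full suite runs on one CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from retiqa import (
    DatasetConfig,
    ModelConfig,
    PhantomSpec,
    QualityModel,
    TrainConfig,
    generate_phantom,
    make_dataset,
)
import retiqa.io as rio


@pytest.fixture(scope="session")
def cf_phantom() -> np.ndarray:
    return generate_phantom(PhantomSpec(seed=42, modality="CF", side_px=128))


@pytest.fixture(scope="session")
def fa_phantom() -> np.ndarray:
    return generate_phantom(PhantomSpec(seed=42, modality="FA", side_px=128))


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small CF dataset: 48/12/24 train/val/test images at 64 px."""
    out = tmp_path_factory.mktemp("tiny_cf")
    config = DatasetConfig(
        modality="CF",
        seed=101,
        n_images_per_split=(48, 12, 24),
        images_per_visit=(3, 6),
        side_px=64,
    )
    manifest = make_dataset(config, out)
    return out, manifest, config


@pytest.fixture(scope="session")
def tiny_results(tiny_dataset):
    """A quickly fitted small model on the tiny dataset."""
    out, _, _ = tiny_dataset
    model = QualityModel.from_dataset(
        out, ModelConfig(modality="CF", input_side_px=32, width_scale=0.125, seed=7)
    )
    results = model.fit(TrainConfig(epochs=4, batch_size=16, seed=7))
    return results


@pytest.fixture(scope="session")
def tiny_test_manifest(tiny_dataset):
    out, _, _ = tiny_dataset
    manifest = rio.read_manifest(out / "manifest.csv")
    return manifest[manifest["split"] == "test"].reset_index(drop=True)
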