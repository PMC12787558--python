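"""Shared fixtures.

The expensive fixtures (the 800-tree study-scale dataset, its trained
model, and the ablation table) are session-scoped so the recovery and
ablation checks share one training effort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from treefuse.ablate import run_ablation
from treefuse.backbone import tiny_backbone_config
from treefuse.model import FusionModel, ModelConfig
from treefuse.synthetic import GeneratorConfig, generate_dataset
from treefuse.train import (
    TrainConfig,
    evaluate,
    prepare_datasets,
    split_validation,
    train,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """A 120-tree dataset for cheap end-to-end pipeline tests."""
    out = tmp_path_factory.mktemp("synth_small") / "ds"
    generate_dataset(GeneratorConfig(n_trees=120, seed=11), out)
    return out


@pytest.fixture(scope="session")
def study_dataset_dir(tmp_path_factory):
    """The study-scale synthetic dataset: n = 800, seed 7, 96 px."""
    out = tmp_path_factory.mktemp("synth_study") / "ds"
    generate_dataset(GeneratorConfig(n_trees=800, seed=7), out)
    return out


@pytest.fixture(scope="session")
def study_run(study_dataset_dir):
    """Tiny-profile model trained on the study-scale dataset (<= 30 epochs)
    plus its test-set metrics and the injected gas-noise levels."""
    data = prepare_datasets(study_dataset_dir, seed=7)
    tr, va = split_validation(data.train, 0.10, seed=7)
    model = FusionModel(ModelConfig(backbone=tiny_backbone_config(96),
                                    sensor_dim=data.sensor_dim,
                                    head_hidden=64, seed=0))
    result = train(model, tr, va, TrainConfig(max_epochs=30, patience=12, seed=0),
                   data.img_mean, data.img_sd)
    report = evaluate(model, data.test, data.stats, data.img_mean, data.img_sd)
    truth = pd.read_csv(study_dataset_dir / "truth.csv")
    sensors = pd.read_csv(study_dataset_dir / "sensors.csv")
    noise = {
        "o2_sd": float((sensors.O2_rate - truth.o2_det).std()),
        "co2_sd": float((sensors.CO2_rate - truth.co2_det).std()),
    }
    return {"data": data, "model": model, "result": result,
            "report": report, "noise": noise}


@pytest.fixture(scope="session")
def ablation_table(study_dataset_dir):
    """Full / no-SE / image-only / sensor-only over three seeds."""
    data = prepare_datasets(study_dataset_dir, seed=7)
    return run_ablation(
        data, variants=("full", "no_se", "image_only", "sensor_only"),
        seeds=(0, 1, 2), train_cfg=TrainConfig(max_epochs=15, patience=8))
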