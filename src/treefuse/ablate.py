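"""Ablation harness: isolate the contribution of each design element.

Variants mirror the study design: the full fused model; ``no_se`` (every
squeeze-excitation gate removed, so channel attention is fixed at 1);
``image_only`` (sensor MLP removed); ``sensor_only`` (image backbone
removed); and ``single_task`` (three independent networks, one per task
head).  All variants share the train/validation/test split, augmentation
and training recipe for a given seed, so differences are attributable to
the architecture alone.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .backbone import efficientnet_b0_config, tiny_backbone_config
from .model import FusionModel, LossWeights, ModelConfig
from .train import PreparedData, TrainConfig, evaluate, split_validation, train

__all__ = ["VARIANTS", "build_variant_configs", "run_ablation"]

VARIANTS = ("full", "no_se", "image_only", "sensor_only", "single_task")


def _backbone_for(profile: str):
    if profile == "tiny":
        return tiny_backbone_config(96), 64
    if profile == "full":
        return efficientnet_b0_config(224), 344
    raise ValueError(f"unknown profile {profile!r}")


def build_variant_configs(variant: str, sensor_dim: int, profile: str = "tiny",
                          seed: int = 0) -> list[ModelConfig]:
    """Model configuration(s) for one ablation variant.

    ``single_task`` yields three configs (one head each); every other
    variant yields a single config.
    """
    backbone, hidden = _backbone_for(profile)
    base = ModelConfig(backbone=backbone, sensor_dim=sensor_dim,
                       head_hidden=hidden, seed=seed)
    if variant == "full":
        return [base]
    if variant == "no_se":
        return [replace(base, use_se=False)]
    if variant == "image_only":
        return [replace(base, sensor_dim=None)]
    if variant == "sensor_only":
        return [replace(base, backbone=None)]
    if variant == "single_task":
        return [replace(base, heads=(h,)) for h in ("health", "o2", "co2")]
    raise ValueError(f"unknown variant {variant!r}")


def run_ablation(data: PreparedData, variants=VARIANTS, seeds=(0, 1, 2),
                 profile: str = "tiny", train_cfg: TrainConfig | None = None,
                 verbose: bool = False) -> pd.DataFrame:
    """Train and evaluate every (variant, seed) pair on shared splits.

    Returns one row per pair with classification and regression metrics
    plus the parameter count.  Single-task rows merge the metrics of the
    three independent models.
    """
    base_cfg = train_cfg or TrainConfig(max_epochs=12, patience=6)
    rows = []
    for seed in seeds:
        tr, va = split_validation(data.train, base_cfg.val_fraction, seed=seed)
        cfg = replace(base_cfg, seed=seed)
        for variant in variants:
            model_cfgs = build_variant_configs(
                variant, data.sensor_dim, profile=profile, seed=seed)
            weights = (LossWeights(1.0, 1.0, 1.0) if variant == "single_task"
                       else cfg.loss_weights)
            reports, n_params = [], 0
            for mc in model_cfgs:
                model = FusionModel(mc)
                n_params += model.num_params()
                train(model, tr, va, replace(cfg, loss_weights=weights),
                      data.img_mean, data.img_sd)
                reports.append(evaluate(model, data.test, data.stats,
                                        data.img_mean, data.img_sd))
            merged = reports[0]
            if variant == "single_task":
                merged.o2_mae, merged.o2_rmse = reports[1].o2_mae, reports[1].o2_rmse
                merged.co2_mae, merged.co2_rmse = reports[2].co2_mae, reports[2].co2_rmse
            row = {"variant": variant, "seed": seed, "n_params": n_params,
                   **{k: v for k, v in merged.to_dict().items()
                      if k not in ("n_params", "n_macs", "latency_ms")}}
            rows.append(row)
            if verbose:
                print(f"[ablate] {variant} seed={seed} "
                      f"acc={row['accuracy']:.3f} macroF1={row['macro_f1']:.3f} "
                      f"o2_mae={row['o2_mae']:.3f}")
    return pd.DataFrame(rows)
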