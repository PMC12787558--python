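"""Multimodal multi-task fusion network.

A sensor MLP encodes the standardized tabular features; its embedding is
concatenated with the image embedding from the MBConv backbone.  The fused
vector feeds three architecturally decoupled heads: a 4-class tree-health
classifier (softmax) and two linear-output regressors for daily O2
production and CO2 absorption (on the z-scored target scale).  Training
minimises a static weighted sum

    L_T = 0.4 * L_cls + 0.3 * L_O2 + 0.3 * L_CO2

with cross-entropy for the classifier and mean absolute error for the
regressors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .backbone import Backbone, BackboneConfig, BlockConfig
from .nn import tensor as T
from .nn.layers import Linear, Module
from .nn.tensor import Tensor

__all__ = [
    "LossWeights",
    "ModelConfig",
    "SensorMLP",
    "TaskHead",
    "FusionModel",
    "TaskOutputs",
    "total_loss",
    "fit_head_hidden",
    "save_checkpoint",
    "load_checkpoint",
]

HEAD_NAMES = ("health", "o2", "co2")


@dataclass(frozen=True)
class LossWeights:
    """Static multi-task loss weights (classification, O2, CO2)."""

    cls: float = 0.4
    o2: float = 0.3
    co2: float = 0.3

    def __post_init__(self):
        if self.cls < 0 or self.o2 < 0 or self.co2 < 0:
            raise ValueError("loss weights must be nonnegative")

    @property
    def total(self) -> float:
        return self.cls + self.o2 + self.co2


@dataclass
class ModelConfig:
    backbone: BackboneConfig | None
    sensor_dim: int | None
    mlp_widths: tuple[int, int] = (64, 32)
    head_hidden: int = 344
    n_classes: int = 4
    use_se: bool = True
    heads: tuple[str, ...] = HEAD_NAMES
    seed: int = 0

    def __post_init__(self):
        if self.backbone is None and self.sensor_dim is None:
            raise ValueError("at least one modality must be enabled")
        for h in self.heads:
            if h not in HEAD_NAMES:
                raise ValueError(f"unknown head {h!r}")

    @property
    def fusion_width(self) -> int:
        width = 0
        if self.sensor_dim is not None:
            width += self.mlp_widths[-1]
        if self.backbone is not None:
            width += self.backbone.head_ch
        return width

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.backbone is not None:
            d["backbone"] = {
                "stem_ch": self.backbone.stem_ch,
                "blocks": [asdict(b) for b in self.backbone.blocks],
                "head_ch": self.backbone.head_ch,
                "resolution": self.backbone.resolution,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("backbone") is not None:
            bb = d["backbone"]
            d["backbone"] = BackboneConfig(
                stem_ch=bb["stem_ch"],
                blocks=tuple(BlockConfig(**b) for b in bb["blocks"]),
                head_ch=bb["head_ch"],
                resolution=bb["resolution"],
            )
        d["mlp_widths"] = tuple(d["mlp_widths"])
        d["heads"] = tuple(d["heads"])
        return cls(**d)


class SensorMLP(Module):
    """Two affine layers with SiLU between: d -> 64 -> 32 by default."""

    def __init__(self, in_dim: int, widths=(64, 32),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.fc1 = Linear(in_dim, widths[0], rng=rng)
        self.fc2 = Linear(widths[0], widths[1], rng=rng)
        self.out_dim = widths[1]

    def __call__(self, v) -> Tensor:
        if not isinstance(v, Tensor):
            v = Tensor(np.asarray(v))
        if v.shape[1] != self.in_dim:
            raise ValueError(f"sensor width {v.shape[1]} != fitted width {self.in_dim}")
        return self.fc2(T.silu(self.fc1(v)))


class TaskHead(Module):
    """FC -> ReLU -> FC.  Softmax (classification) applied outside."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(in_dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, out_dim, rng=rng)

    def __call__(self, f: Tensor) -> Tensor:
        return self.fc2(T.relu(self.fc1(f)))


@dataclass
class TaskOutputs:
    """Inference outputs: class probabilities and standardized gas estimates."""

    probs: np.ndarray | None  # (N, 4), rows on the simplex
    o2: np.ndarray | None     # (N,), z-scored scale
    co2: np.ndarray | None    # (N,), z-scored scale


class FusionModel(Module):
    """Backbone + sensor MLP + concatenation fusion + decoupled task heads.

    Ablation variants are expressed through the config: ``backbone=None``
    gives the sensor-only model, ``sensor_dim=None`` the image-only model,
    ``use_se=False`` fixes every SE gate at 1 (and instantiates no SE
    parameters), and a restricted ``heads`` tuple yields single-task models.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.backbone = (Backbone(cfg.backbone, rng=rng, use_se=cfg.use_se)
                         if cfg.backbone is not None else None)
        self.mlp = (SensorMLP(cfg.sensor_dim, cfg.mlp_widths, rng=rng)
                    if cfg.sensor_dim is not None else None)
        width = cfg.fusion_width
        self.heads = {}
        for name in cfg.heads:
            out = cfg.n_classes if name == "health" else 1
            self.heads[name] = TaskHead(width, cfg.head_hidden, out, rng=rng)
        # expose heads as attributes so parameter traversal finds them
        for name, head in self.heads.items():
            setattr(self, f"head_{name}", head)

    # --- spec operations -------------------------------------------------
    def sensor_mlp(self, v) -> Tensor:
        if self.mlp is None:
            raise ValueError("model has no sensor pathway")
        return self.mlp(v)

    def image_embed(self, images) -> Tensor:
        if self.backbone is None:
            raise ValueError("model has no image pathway")
        return self.backbone(images)

    def fuse(self, sensor_emb: Tensor | None, image_emb: Tensor | None) -> Tensor:
        """Exact concatenation, sensor block first; no learned parameters."""
        parts = []
        if self.mlp is not None:
            if sensor_emb is None:
                raise ValueError("sensor embedding required but missing")
            parts.append(sensor_emb)
        if self.backbone is not None:
            if image_emb is None:
                raise ValueError("image embedding required but missing")
            parts.append(image_emb)
        if len(parts) == 1:
            return parts[0]
        return T.concat(parts, axis=1)

    def head_classify(self, f: Tensor) -> Tensor:
        """Health-head logits; apply :func:`treefuse.nn.tensor.softmax` to
        obtain the probability simplex of the published formulation."""
        return self.heads["health"](f)

    def head_regress_o2(self, f: Tensor) -> Tensor:
        return T.reshape(self.heads["o2"](f), (f.shape[0],))

    def head_regress_co2(self, f: Tensor) -> Tensor:
        return T.reshape(self.heads["co2"](f), (f.shape[0],))

    # --- forward ---------------------------------------------------------
    def forward(self, images=None, sensors=None) -> dict[str, Tensor]:
        sensor_emb = self.sensor_mlp(sensors) if self.mlp is not None else None
        image_emb = self.image_embed(images) if self.backbone is not None else None
        f = self.fuse(sensor_emb, image_emb)
        out = {}
        if "health" in self.heads:
            out["logits"] = self.head_classify(f)
        if "o2" in self.heads:
            out["o2"] = self.head_regress_o2(f)
        if "co2" in self.heads:
            out["co2"] = self.head_regress_co2(f)
        return out

    __call__ = forward

    def predict(self, images=None, sensors=None) -> TaskOutputs:
        """Deterministic inference-mode outputs as plain NumPy arrays."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(images=images, sensors=sensors)
        finally:
            self.train(was_training)
        return TaskOutputs(
            probs=T.softmax(out["logits"]) if "logits" in out else None,
            o2=out["o2"].data.copy() if "o2" in out else None,
            co2=out["co2"].data.copy() if "co2" in out else None,
        )


def total_loss(outputs: dict[str, Tensor], labels=None, o2_targets=None,
               co2_targets=None, weights: LossWeights = LossWeights()):
    """Weighted multi-task objective.

    Returns a dict of scalar loss tensors: per-task components plus
    ``total = w_cls * L_cls + w_o2 * L_O2 + w_co2 * L_CO2``.  Regression
    targets must already be on the z-scored scale.
    """
    losses: dict[str, Tensor] = {}
    terms = []
    if "logits" in outputs:
        if labels is None:
            raise ValueError("labels required for the classification head")
        losses["cls"] = T.softmax_cross_entropy(outputs["logits"], labels)
        terms.append(T.scale(losses["cls"], weights.cls))
    if "o2" in outputs:
        if o2_targets is None:
            raise ValueError("O2 targets required")
        losses["o2"] = T.l1_loss(outputs["o2"], o2_targets)
        terms.append(T.scale(losses["o2"], weights.o2))
    if "co2" in outputs:
        if co2_targets is None:
            raise ValueError("CO2 targets required")
        losses["co2"] = T.l1_loss(outputs["co2"], co2_targets)
        terms.append(T.scale(losses["co2"], weights.co2))
    tot = terms[0]
    for t in terms[1:]:
        tot = T.add(tot, t)
    losses["total"] = tot
    return losses


def fit_head_hidden(backbone_params: int, sensor_dim: int,
                    mlp_widths=(64, 32), embed_width: int = 1280,
                    n_classes: int = 4, target_millions: float = 5.4,
                    start: int = 344) -> int:
    """Pick the shared head hidden width so the total parameter count,
    in millions rounded to one decimal, meets the published budget.

    Starts from the reference width and walks outward minimally.
    """
    fusion = mlp_widths[-1] + embed_width
    mlp = sensor_dim * mlp_widths[0] + mlp_widths[0] \
        + mlp_widths[0] * mlp_widths[1] + mlp_widths[1]

    def total(h):
        heads = 3 * (fusion * h + h) + (h * n_classes + n_classes) + 2 * (h + 1)
        return backbone_params + mlp + heads

    for delta in range(0, 2000):
        for h in (start + delta, start - delta):
            if h >= 1 and round(total(h) / 1e6, 1) == target_millions:
                return h
    raise ValueError("no head width meets the parameter budget")


def save_checkpoint(path, model: FusionModel, extra: dict | None = None):
    """Single-file checkpoint: parameters + JSON-encoded configuration.

    ``extra`` typically carries the fitted preprocessing statistics so
    inference is reproducible from the file alone.
    """
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = {"model_config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[FusionModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = FusionModel(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    return model, meta["extra"]
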