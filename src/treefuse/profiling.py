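"""Static parameter and multiply-accumulate (MAC) accounting.

MACs are counted for convolutions and fully connected layers only
(``K_h * K_w * C_in / groups * C_out * H_out * W_out`` per convolution,
``in * out`` per fully connected layer), the convention used by the common
network profilers.  Batch-norm, activations, pooling and the elementwise SE
gating multiply are excluded.  Compact networks are conventionally quoted in
units of 1e9 MACs ("GFLOPs").
"""

from __future__ import annotations

from .backbone import BackboneConfig, _conv_out
from .nn.layers import Module

__all__ = [
    "count_params",
    "backbone_mac_breakdown",
    "count_macs_backbone",
    "fusion_mac_breakdown",
    "count_macs",
]


def count_params(model: Module) -> int:
    """Exact count of trainable scalars in a module tree."""
    return model.num_params()


def backbone_mac_breakdown(cfg: BackboneConfig, use_se: bool = True):
    """Itemised MACs of every conv / FC layer in the backbone."""
    items = []
    h = _conv_out(cfg.resolution, 3, 2)
    items.append(("stem", 3 * 3 * 3 * cfg.stem_ch * h * h))
    for i, b in enumerate(cfg.blocks):
        h_in = h
        h = _conv_out(h, b.kernel, b.stride)
        exp = b.expanded_ch
        if b.expansion != 1:
            items.append((f"block{i}.expand", exp * b.in_ch * h_in * h_in))
        items.append((f"block{i}.dw", b.kernel * b.kernel * exp * h * h))
        if use_se:
            items.append((f"block{i}.se_fc1", exp * b.squeeze_ch))
            items.append((f"block{i}.se_fc2", b.squeeze_ch * exp))
        items.append((f"block{i}.project", exp * b.out_ch * h * h))
    items.append(("head", cfg.blocks[-1].out_ch * cfg.head_ch * h * h))
    return items


def count_macs_backbone(cfg: BackboneConfig, use_se: bool = True) -> int:
    return int(sum(m for _, m in backbone_mac_breakdown(cfg, use_se=use_se)))


def fusion_mac_breakdown(backbone_cfg: BackboneConfig | None, sensor_dim: int | None,
                         mlp_widths=(64, 32), head_hidden: int = 344,
                         n_classes: int = 4, use_se: bool = True,
                         heads=("health", "o2", "co2")):
    """MACs of the full fusion model: backbone + sensor MLP + task heads."""
    items = []
    fusion_width = 0
    if backbone_cfg is not None:
        items.extend(backbone_mac_breakdown(backbone_cfg, use_se=use_se))
        fusion_width += backbone_cfg.head_ch
    if sensor_dim is not None:
        widths = [sensor_dim, *mlp_widths]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            items.append((f"sensor_mlp.fc{i}", a * b))
        fusion_width += mlp_widths[-1]
    for name in heads:
        out = n_classes if name == "health" else 1
        items.append((f"head_{name}.fc1", fusion_width * head_hidden))
        items.append((f"head_{name}.fc2", head_hidden * out))
    return items


def count_macs(backbone_cfg: BackboneConfig | None, sensor_dim: int | None,
               **kwargs) -> int:
    return int(sum(m for _, m in fusion_mac_breakdown(backbone_cfg, sensor_dim,
                                                      **kwargs)))
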