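"""Assemble the 2D/3D IResUnet3+ and its ablation variants.

Three variants share one skeleton:

* ``unet3p``      — plain double-conv encoder, BatchNorm + ReLU everywhere.
* ``frn_unet3p``  — same encoder topology, every norm+act replaced by FRN+TLU.
* ``iresunet3p``  — stage-residual encoder, FRN+TLU everywhere.

The decoder is the full-scale skip design: decoder node ``X_De^l`` fuses all
five scales — encoder maps at scales <= l (max-pooled down), the same-scale
encoder map, and every deeper decoder/bottleneck map (upsampled by linear
interpolation).  Each branch is convolved to ``aggregation_width`` channels,
the five branches concatenate to ``5 * aggregation_width`` and one fusion
conv + norm + act produces the node output.  A final 1x1 conv + sigmoid
yields per-channel probabilities for the three nested regions (WT, TC, ET),
which overlap and therefore must not be softmax-exclusive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import autodiff as ad
from .autodiff import DimensionError, Tensor
from .core_layers import (Conv, ConvNormAct, Module, PlainStage, StageLayout,
                          StageResidual, StageResidualConfig)

Variant = Literal["unet3p", "frn_unet3p", "iresunet3p"]

N_STAGES = 5


class ConfigurationError(ValueError):
    """Invalid model/input configuration."""


@dataclass
class ChannelPlan:
    """Per-stage channel widths plus the skip aggregation width.

    Defaults follow the published configurations: [64,128,256,512,1024] in
    2D and [16,32,64,128,256] in 3D, with aggregation width equal to the
    first-stage width, so the fused decoder width is 5x that (320 in 2D).
    """

    stage_widths: tuple[int, ...] = (64, 128, 256, 512, 1024)
    aggregation_width: int | None = None

    def __post_init__(self):
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        if len(self.stage_widths) != N_STAGES:
            raise ConfigurationError("exactly 5 stage widths required")
        for a, b in zip(self.stage_widths, self.stage_widths[1:]):
            if b != 2 * a:
                raise ConfigurationError(
                    f"stage widths must double: {a} -> {b}")
        if self.aggregation_width is None:
            self.aggregation_width = self.stage_widths[0]

    @property
    def fused_width(self) -> int:
        return N_STAGES * self.aggregation_width

    @classmethod
    def default(cls, rank: int) -> "ChannelPlan":
        if rank == 2:
            return cls((64, 128, 256, 512, 1024))
        return cls((16, 32, 64, 128, 256))


@dataclass
class ModelSpec:
    variant: Variant = "iresunet3p"
    rank: int = 3
    in_channels: int = 4
    out_channels: int = 3
    plan: ChannelPlan | None = None
    n_middle: int = 0
    layout: StageLayout = field(default_factory=StageLayout)

    def __post_init__(self):
        if self.variant not in ("unet3p", "frn_unet3p", "iresunet3p"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.rank not in (2, 3):
            raise ConfigurationError("rank must be 2 or 3")
        if self.plan is None:
            self.plan = ChannelPlan.default(self.rank)

    @property
    def norm_kind(self) -> str:
        return "batch" if self.variant == "unet3p" else "frn"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "rank": self.rank,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "stage_widths": list(self.plan.stage_widths),
            "aggregation_width": self.plan.aggregation_width,
            "n_middle": self.n_middle,
            "layout": {"convs_per_block": self.layout.convs_per_block,
                       "shortcut_kernel": self.layout.shortcut_kernel},
        }


# ---------------------------------------------------------------------------
# encoder / decoder pieces
# ---------------------------------------------------------------------------

class Encoder(Module):
    """Five stages separated by 2x max pooling; returns X_En^1..X_En^5."""

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        widths = spec.plan.stage_widths
        self.stages = []
        cin = spec.in_channels
        for w in widths:
            if spec.variant == "iresunet3p":
                cfg = StageResidualConfig(cin, w, n_middle=spec.n_middle,
                                          rank=spec.rank,
                                          norm_kind=spec.norm_kind,
                                          layout=spec.layout)
                self.stages.append(StageResidual(cfg, rng=rng))
            else:
                self.stages.append(PlainStage(spec.rank, cin, w,
                                              norm_kind=spec.norm_kind,
                                              rng=rng))
            cin = w

    def forward(self, x: Tensor) -> list[Tensor]:
        maps = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = ad.max_pool(x, 2)
            x = stage(x)
            maps.append(x)
        return maps


class DecoderNode(Module):
    """Full-scale fusion node producing X_De^level (level in 1..4)."""

    def __init__(self, level: int, spec: ModelSpec, rng):
        super().__init__()
        if not 1 <= level <= N_STAGES - 1:
            raise ConfigurationError("decoder level must be in 1..4")
        self.level = level
        plan = spec.plan
        agg = plan.aggregation_width
        self.branch_convs = []
        self.scales = []  # (source scale s, factor, mode)
        for s in range(1, N_STAGES + 1):
            if s < level:
                mode, factor = "pool", 2 ** (level - s)
                cin = plan.stage_widths[s - 1]
            elif s == level:
                mode, factor = "same", 1
                cin = plan.stage_widths[s - 1]
            else:
                mode, factor = "up", 2 ** (s - level)
                # deeper sources: bottleneck is the raw stage-5 encoder map,
                # decoder nodes carry the fused width
                cin = plan.stage_widths[-1] if s == N_STAGES else plan.fused_width
            self.scales.append((s, mode, factor))
            self.branch_convs.append(
                ConvNormAct(spec.rank, cin, agg, spec.norm_kind, rng=rng))
        self.fusion = ConvNormAct(spec.rank, plan.fused_width,
                                  plan.fused_width, spec.norm_kind, rng=rng)

    def forward(self, sources: dict[int, Tensor]) -> Tensor:
        branches = []
        for (s, mode, factor), conv in zip(self.scales, self.branch_convs):
            if s not in sources:
                raise ConfigurationError(
                    f"decoder node {self.level}: missing source map at scale {s}")
            h = sources[s]
            if mode == "pool":
                h = ad.max_pool(h, factor)
            elif mode == "up":
                h = ad.upsample_linear(h, factor)
            branches.append(conv(h))
        fused = ad.concat(branches, axis=1)
        return self.fusion(fused)


def build_decoder_node(level: int, encoder_outputs: list[Tensor],
                       deeper_decoder_maps: dict[int, Tensor],
                       node: DecoderNode) -> Tensor:
    """Run one decoder node from encoder maps and deeper decoder maps."""
    sources = {s: encoder_outputs[s - 1] for s in range(1, level + 1)}
    sources.update(deeper_decoder_maps)
    return node(sources)


class IResUnet3Plus(Module):
    """The assembled segmentation network (any of the three variants)."""

    def __init__(self, spec: ModelSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.encoder = Encoder(spec, rng)
        self.decoder_nodes = [DecoderNode(level, spec, rng)
                              for level in range(N_STAGES - 1, 0, -1)]
        self.head = Conv(spec.rank, spec.plan.fused_width, spec.out_channels,
                         kernel=1, bias=True, rng=rng)

    def _check_input(self, x: Tensor):
        if x.ndim != self.spec.rank + 2:
            raise DimensionError(
                f"rank-{self.spec.rank} model expects {self.spec.rank + 2}-D "
                f"input (N, C, *spatial), got shape {x.shape}")
        if x.shape[1] != self.spec.in_channels:
            raise DimensionError(
                f"expected {self.spec.in_channels} input channels "
                f"(modalities), got {x.shape[1]}")
        div = 2 ** (N_STAGES - 1)
        for i, s in enumerate(x.shape[2:]):
            if s % div:
                raise ConfigurationError(
                    f"spatial axis {i} has size {s}, not divisible by {div}")

    def forward(self, x) -> Tensor:
        x = ad.as_tensor(x)
        self._check_input(x)
        enc = self.encoder(x)
        decoder_maps: dict[int, Tensor] = {N_STAGES: enc[-1]}
        for node in self.decoder_nodes:  # levels 4, 3, 2, 1
            out = build_decoder_node(node.level, enc,
                                     {s: m for s, m in decoder_maps.items()
                                      if s > node.level}, node)
            decoder_maps[node.level] = out
        logits = self.head(decoder_maps[1])
        return ad.sigmoid(logits)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0) -> IResUnet3Plus:
    """Construct a model with He-initialized weights from `seed`."""
    return IResUnet3Plus(spec, rng=np.random.default_rng(seed))


def count_parameters(model: Module) -> int:
    """Total number of learnable scalars (convs, norms, thresholds)."""
    return model.count_parameters()


def forward(model: IResUnet3Plus, batch: np.ndarray) -> np.ndarray:
    """Inference forward pass: (N, 4, *spatial) -> (N, 3, *spatial) probs."""
    model.eval()
    with ad.no_grad():
        out = model(np.asarray(batch, dtype=np.float32))
    return out.data


def parameter_ledger(model: Module) -> list[dict]:
    """Per-parameter listing: name, shape, count."""
    return [{"name": k, "shape": list(p.data.shape), "count": int(p.size)}
            for k, p in model.named_parameters()]


def architecture_summary(model: IResUnet3Plus) -> dict:
    return {
        "spec": model.spec.to_dict(),
        "total_parameters": count_parameters(model),
        "parameters": parameter_ledger(model),
    }


def save_checkpoint(model: IResUnet3Plus, path):
    """Write weights (.npz) plus a JSON architecture sidecar."""
    import pathlib

    path = pathlib.Path(path)
    np.savez(path, **model.state_dict())
    side = path.with_suffix(".json")
    side.write_text(json.dumps(model.spec.to_dict(), indent=2))


def load_checkpoint(path) -> IResUnet3Plus:
    import pathlib

    path = pathlib.Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(
        variant=side["variant"], rank=side["rank"],
        in_channels=side["in_channels"], out_channels=side["out_channels"],
        plan=ChannelPlan(tuple(side["stage_widths"]),
                         side["aggregation_width"]),
        n_middle=side["n_middle"],
        layout=StageLayout(**side["layout"]),
    )
    model = build_model(spec)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model
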