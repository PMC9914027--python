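"""Assembly of the full ShuffleNet-Light network and complexity reporting.

Layout: a stride-1 stem (3x3 conv, BN, ReLU, then a 1x1 expansion to the
first stage width) followed by four stages.  Stage i runs ``stage_repeats[i]``
shuffle units at ``stage_widths[i]`` (stride 1 throughout), a
squeeze-and-excitation block, a 2x2 max pool (stride 2, the only source of
downsampling), and — between stages — a 1x1 conv + BN + activation expansion
to the next width.  The head is global average pooling, a fully connected
layer with GELU, and a linear classifier whose softmax yields the 7-class
probabilities.  Input spatial size must be divisible by 2^4.

The published parameter budget for the canonical configuration is 1.9 million;
``calibrate_budget`` documents the deterministic repair rule that pins any
edited configuration back into the [1.85 M, 1.95 M] band.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from ._tensor import Tensor, softmax
from .blocks import SEBlock, ShuffleUnit

__all__ = [
    "BUDGET_RANGE",
    "BudgetError",
    "ComplexityReport",
    "ModelConfig",
    "ShuffleNetLight",
    "build_model",
    "calibrate_budget",
    "count_parameters",
]

BUDGET_RANGE = (1_850_000, 1_950_000)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the canonical configuration."""

    stem_channels: int = 24
    stage_widths: tuple = (64, 128, 256, 512)
    stage_repeats: tuple = (3, 7, 10, 9)
    se_reduction: int = 16
    head_width: int = 128
    n_classes: int = 7
    activation: str = "gelu"
    use_shuffle: bool = True
    input_size: int = 256

    def __post_init__(self):
        if len(self.stage_widths) != 4 or len(self.stage_repeats) != 4:
            raise ValueError("expected exactly 4 stage widths and 4 repeat counts")
        if any(w % 2 for w in self.stage_widths):
            raise ValueError("stage widths must be even")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        d["stage_repeats"] = list(self.stage_repeats)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_widths", "stage_repeats"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ComplexityReport:
    total_params: int
    breakdown: dict = field(default_factory=dict)
    macs: int | None = None

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 1)

    def to_dict(self) -> dict:
        return {
            "total_params": self.total_params,
            "params_millions": self.params_millions,
            "macs": self.macs,
            "breakdown": self.breakdown,
        }


class BudgetError(RuntimeError):
    pass


class _Stage(nn.Module):
    def __init__(self, width, repeats, se_reduction, next_width, cfg, rng):
        super().__init__()
        self.units = [
            ShuffleUnit(width, cfg.use_shuffle, cfg.activation, rng=rng)
            for _ in range(repeats)
        ]
        self.se = SEBlock(width, se_reduction, rng=rng)
        self.pool = nn.MaxPool2x2()
        if next_width is not None:
            self.expand = nn.Sequential(
                nn.Conv2d(width, next_width, 1, rng=rng),
                nn.BatchNorm2d(next_width),
                nn.Activation(cfg.activation),
            )
        else:
            self.expand = None

    def forward(self, x, taps=None, name=""):
        for unit in self.units:
            x = unit(x)
        x = self.se(x)
        if taps is not None:
            taps[f"{name}.se"] = x
        x = self.pool(x)
        if self.expand is not None:
            x = self.expand(x)
        return x


class ShuffleNetLight(nn.Module):
    """The full network.  ``forward`` returns logits; ``predict_proba`` the
    softmax probabilities.  Pass ``taps={}`` to capture the per-stage SE
    outputs (used by GradCAM)."""

    TAP_NAMES = ("stage1.se", "stage2.se", "stage3.se", "stage4.se")

    def __init__(self, cfg: ModelConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or ModelConfig()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        w = cfg.stage_widths
        self.stem_conv = nn.Conv2d(3, cfg.stem_channels, 3, padding=1, rng=rng)
        self.stem_bn = nn.BatchNorm2d(cfg.stem_channels)
        self.stem_relu = nn.Activation("relu")
        self.stem_expand = nn.Sequential(
            nn.Conv2d(cfg.stem_channels, w[0], 1, rng=rng),
            nn.BatchNorm2d(w[0]),
            nn.Activation(cfg.activation),
        )
        self.stages = [
            _Stage(
                w[i],
                cfg.stage_repeats[i],
                cfg.se_reduction,
                w[i + 1] if i < 3 else None,
                cfg,
                rng,
            )
            for i in range(4)
        ]
        self.head_fc = nn.Linear(w[3], cfg.head_width, rng=rng)
        self.head_act = nn.Activation("gelu")
        self.classifier = nn.Linear(cfg.head_width, cfg.n_classes, rng=rng)
        self.gap = nn.GlobalAvgPool()

    def forward(self, x, taps: dict | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, wdt = x.shape[2], x.shape[3]
        if h % 16 or wdt % 16:
            raise ValueError(
                f"input spatial size {h}x{wdt} must be divisible by 2^4 "
                "(four 2x2 pooling stages)"
            )
        x = self.stem_relu(self.stem_bn(self.stem_conv(x)))
        x = self.stem_expand(x)
        for i, stage in enumerate(self.stages):
            x = stage(x, taps=taps, name=f"stage{i + 1}")
        x = self.gap(x)
        x = self.head_act(self.head_fc(x))
        return self.classifier(x)

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.forward(x).data, axis=1)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> ShuffleNetLight:
    """Build a seeded network from a configuration."""
    return ShuffleNetLight(cfg, rng=np.random.default_rng(seed))


def count_parameters(model: ShuffleNetLight, count_macs: bool = False) -> ComplexityReport:
    """Exact trainable-scalar count with a per-module breakdown.

    With ``count_macs`` a forward pass on a single input at the configured
    resolution tallies multiply-accumulate operations (conv + linear).
    """
    breakdown: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        breakdown[top] = breakdown.get(top, 0) + int(p.data.size)
    total = int(sum(breakdown.values()))
    macs = None
    if count_macs:
        from . import _tensor

        size = model.cfg.input_size
        _tensor.MAC_COUNTER = [0]
        try:
            was_training = model.training
            model.eval()
            model.forward(np.zeros((1, 3, size, size), dtype=np.float32))
            macs = int(_tensor.MAC_COUNTER[0])
            model.train(was_training)
        finally:
            _tensor.MAC_COUNTER = None
    return ComplexityReport(total_params=total, breakdown=breakdown, macs=macs)


def _config_param_count(cfg: ModelConfig) -> int:
    return build_model(cfg).parameter_count()


def calibrate_budget(cfg: ModelConfig | None = None) -> ModelConfig:
    """Deterministically repair a configuration into the published budget band.

    Search order: stage 4 repeat offsets 0, -1, +1, -2, +2, ... +-4, each first
    with the configuration's own head width, then head widths 64, 128, 256.
    The first configuration whose exact count lands in ``BUDGET_RANGE`` wins.
    """
    cfg = cfg or ModelConfig()
    lo, hi = BUDGET_RANGE
    head_widths = [cfg.head_width] + [w for w in (64, 128, 256) if w != cfg.head_width]
    offsets = [0]
    for k in range(1, 5):
        offsets += [-k, k]
    closest = None
    for delta in offsets:
        r3 = cfg.stage_repeats[3] + delta
        if r3 < 1:
            continue
        for hw in head_widths:
            candidate = replace(
                cfg,
                stage_repeats=cfg.stage_repeats[:3] + (r3,),
                head_width=hw,
            )
            count = _config_param_count(candidate)
            if lo <= count <= hi:
                return candidate
            gap = min(abs(count - lo), abs(count - hi))
            if closest is None or gap < closest[0]:
                closest = (gap, count)
    raise BudgetError(
        f"no configuration in [{lo}, {hi}] found; closest count was {closest[1]}"
    )
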