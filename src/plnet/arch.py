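"""PL-Net architecture: shared-block encoder-decoder with internal "steps"
and external "stages".

The network is a U-shaped encoder-decoder whose building blocks are shared
between two nested sub-networks ("stages") of different depth.  Stage 1 is the
shallow, coarse-segmentation network; stage 2 reuses every stage-1 block and
adds the deepest level (the global bottleneck).  Within a stage the
encoder-decoder is traversed ``n_steps`` times ("internal progressive
learning"); each traversal owns its own conv units, and traversal ``s`` feeds
traversal ``s+1`` through backward skip connections (BSC): the previous
traversal's same-scale decoder feature is concatenated into the encoder input.
Forward skip connections (FSC) are the classical same-scale encoder-to-decoder
concatenations.

Counting convention (fixed once, used everywhere):

* conv unit  = 3x3 conv (weights + bias) + batch norm (2 trainable per
  channel) + ReLU  ->  ``9*in*out + 3*out`` trainable scalars;
* downsampling = 2x2 max pooling (parameter-free);
* upsampling = channel-preserving 3x3 stride-2 transposed conv + BN + ReLU,
  one per decoder transition, shared across steps and stages;
* the global bottleneck owns one fixed 3x3 "bridge" conv unit in addition to
  its per-step conv units;
* each stage ends in its own 1x1 prediction conv (the pre-activation head);
* batch-norm running statistics are buffers, not trainable parameters.

Under this convention the default model (Ocs=1, two steps, two stages) has
14,908,098 trainable scalars and each extra step adds exactly 4,705,440.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .nn import Tensor

__all__ = [
    "ArchConfig",
    "StageOutputs",
    "scale_channels",
    "build_plnet",
    "PLNet",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_CHANNELS = (32, 64, 128, 256, 512)


def scale_channels(base_channels, ocs):
    """Scale every level width by the output-channel scale ``ocs``.

    Round-half-up, clamped to at least one channel.  Monotone in ``ocs``.
    """
    if not ocs > 0:
        raise ValueError(f"ocs must be positive, got {ocs}")
    if any(c < 1 for c in base_channels):
        raise ValueError("base channels must all be >= 1")
    return [max(1, int(np.floor(c * ocs + 0.5))) for c in base_channels]


@dataclass
class ArchConfig:
    """Architectural hyperparameters.

    ``base_channels`` lists the output width of every encoder level from the
    input resolution down to the global bottleneck; its length is the depth of
    the deepest stage.  ``ocs`` multiplies every width.  Stage ``k`` (of
    ``n_stages``) uses levels ``0 .. depth-1-(n_stages-k)``.
    """

    ocs: float = 1.0
    n_steps: int = 2
    n_stages: int = 2
    base_channels: tuple = DEFAULT_CHANNELS
    in_channels: int = 3
    n_classes: int = 1
    input_size: int = 224

    def __post_init__(self):
        if self.ocs <= 0:
            raise ValueError("ocs must be positive")
        if self.n_steps < 1 or self.n_stages < 1:
            raise ValueError("n_steps and n_stages must be >= 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        depth = len(self.base_channels)
        if depth < 2:
            raise ValueError("need at least two levels")
        if self.n_stages > depth - 1:
            raise ValueError(
                f"{self.n_stages} stages need depth >= {self.n_stages + 1}"
            )
        if self.input_size % (2 ** (depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2**{depth - 1}"
            )

    @property
    def depth(self):
        return len(self.base_channels)

    @property
    def channels(self):
        """Per-level widths after Ocs scaling."""
        return scale_channels(self.base_channels, self.ocs)

    def stage_bottleneck(self, stage):
        """Deepest level index traversed by 1-based ``stage``."""
        if not 1 <= stage <= self.n_stages:
            raise ValueError(f"stage {stage} out of range 1..{self.n_stages}")
        return self.depth - 1 - (self.n_stages - stage)

    def to_dict(self):
        d = asdict(self)
        d["base_channels"] = list(self.base_channels)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "base_channels" in d:
            d["base_channels"] = tuple(d["base_channels"])
        return cls(**d)


@dataclass
class StageOutputs:
    """Per-stage pre-activation prediction maps, shallow stage first."""

    preacts: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.preacts) == 0:
            raise ValueError("need at least one stage output")


class PLNet(nn.Module):
    """The progressive-learning segmentation network."""

    def __init__(self, config: ArchConfig, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        c = config.channels
        depth = config.depth
        self.channels = c

        # encoder conv units: one per step per level; every level except the
        # global bottleneck reserves a backward-feature slot of its own width
        self.enc = [
            [
                nn.ConvUnit(self._enc_in(lvl), c[lvl], rng)
                for _ in range(config.n_steps)
            ]
            for lvl in range(depth)
        ]
        # fixed bridge conv at the global bottleneck
        self.bridge = nn.ConvUnit(c[-1], c[-1], rng)
        # decoder conv units: skip (c_l) concat upsampled (c_{l+1})
        self.dec = [
            [
                nn.ConvUnit(c[lvl] + c[lvl + 1], c[lvl], rng)
                for _ in range(config.n_steps)
            ]
            for lvl in range(depth - 1)
        ]
        # channel-preserving transposed-conv upsamplers, one per transition
        self.ups = [nn.TransposeUp(c[lvl + 1], rng) for lvl in range(depth - 1)]
        # one pre-activation prediction head per stage
        self.heads = [
            nn.Conv2d(c[0], config.n_classes, 1, rng)
            for _ in range(config.n_stages)
        ]

    def _enc_in(self, lvl):
        c = self.config.channels
        base = self.config.in_channels if lvl == 0 else c[lvl - 1]
        if lvl < self.config.depth - 1:
            base += c[lvl]  # backward-feature slot
        return base

    # -- merge rules -------------------------------------------------------

    def bsc_merge(self, x, prev, step, level, train=False, stage=1):
        """Backward skip merge feeding the encoder conv of ``step`` at
        ``level``.

        ``prev`` is the same-scale feature of the previous traversal (its
        decoder output, or the previous stage's final feature).  When no
        backward feature exists yet — the very first traversal of stage 1 —
        the backward slot is filled with zeros so that every traversal sees
        identically shaped inputs; ``prev=None`` is only legal there (or at a
        level no earlier traversal reached).
        """
        if prev is None:
            if step > 0:
                raise ValueError(
                    "a backward feature is required beyond the first traversal"
                )
            n, _, h, w = x.data.shape
            prev = Tensor(np.zeros((n, self.channels[level], h, w)))
        if prev.data.shape[2:] != x.data.shape[2:]:
            raise ValueError(
                f"backward feature {prev.data.shape} does not match {x.data.shape}"
            )
        return self.enc[level][step](nn.concat([x, prev]), train)

    def fsc_merge(self, x, x_hat, step, level, train=False):
        """Forward skip merge: encoder feature ``x`` concat upsampled decoder
        feature ``x_hat``, through the level's step conv."""
        if x.data.shape[2:] != x_hat.data.shape[2:]:
            raise ValueError(
                f"spatial mismatch {x.data.shape} vs {x_hat.data.shape}"
            )
        return self.dec[level][step](nn.concat([x, x_hat]), train)

    # -- forward execution -------------------------------------------------

    def _check_input(self, image):
        h, w = image.data.shape[2:]
        div = 2 ** (self.config.depth - 1)
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by {div}")

    def _run_pass(self, image, step, bottleneck, back, train):
        """One complete encode-decode traversal over levels 0..bottleneck.

        Returns (decoder level-0 output, backward features for the next
        traversal).
        """
        enc_feats = {}
        x = image
        for lvl in range(bottleneck + 1):
            inp = x if lvl == 0 else nn.maxpool2x2(enc_feats[lvl - 1])
            if lvl < self.config.depth - 1:
                enc_feats[lvl] = self.bsc_merge(
                    inp, back.get(lvl), step, lvl, train
                )
            else:  # global bottleneck: no backward slot
                enc_feats[lvl] = self.enc[lvl][step](inp, train)
        top = enc_feats[bottleneck]
        if bottleneck == self.config.depth - 1:
            top = self.bridge(top, train)
        u = top
        dec_feats = {}
        for lvl in range(bottleneck - 1, -1, -1):
            u = self.ups[lvl](u, train)
            u = self.fsc_merge(enc_feats[lvl], u, step, lvl, train)
            dec_feats[lvl] = u
        new_back = dict(dec_feats)
        if bottleneck < self.config.depth - 1:
            new_back[bottleneck] = enc_feats[bottleneck]
        return dec_feats[0], new_back

    def forward_all(self, image, train=False, upto_stage=None):
        """Run stages 1..upto_stage (default all); return StageOutputs."""
        if not isinstance(image, Tensor):
            image = Tensor(image)
        self._check_input(image)
        n_stages = upto_stage or self.config.n_stages
        if not 1 <= n_stages <= self.config.n_stages:
            raise ValueError(f"stage {n_stages} out of range")
        back = {}
        preacts = []
        for k in range(1, n_stages + 1):
            bott = self.config.stage_bottleneck(k)
            out = None
            for step in range(self.config.n_steps):
                out, back = self._run_pass(image, step, bott, back, train)
            preacts.append(self.heads[k - 1](out))
        return StageOutputs(preacts)

    def ipl_forward(self, image, stage, train=False):
        """Pre-activation map of ``stage`` (1-based); earlier stages are run
        to supply its backward features."""
        return self.forward_all(image, train=train, upto_stage=stage).preacts[-1]

    # -- parameter bookkeeping --------------------------------------------

    def stage_modules(self, stage):
        """Modules traversed by stages 1..stage (1-based)."""
        bott = self.config.stage_bottleneck(stage)
        mods = []
        for lvl in range(bott + 1):
            mods.extend(self.enc[lvl])
        for lvl in range(bott):
            mods.append(self.ups[lvl])
            mods.extend(self.dec[lvl])
        if bott == self.config.depth - 1:
            mods.append(self.bridge)
        mods.extend(self.heads[:stage])
        return mods

    def stage_parameters(self, stage):
        params = []
        for m in self.stage_modules(stage):
            params.extend(m.parameters())
        return params

    def level_plan(self):
        """Human-readable per-level summary of the channel/stage plan."""
        cfg = self.config
        rows = []
        size = cfg.input_size
        for lvl, ch in enumerate(cfg.channels):
            stages = [
                k
                for k in range(1, cfg.n_stages + 1)
                if lvl <= cfg.stage_bottleneck(k)
            ]
            rows.append(
                {
                    "depth_index": lvl,
                    "spatial_size": size // (2**lvl),
                    "channels": ch,
                    "stage_membership": stages,
                    "encoder_step_convs": cfg.n_steps,
                    "decoder_step_convs": cfg.n_steps if lvl < cfg.depth - 1 else 0,
                }
            )
        return rows


def build_plnet(config: ArchConfig, seed=0) -> PLNet:
    """Construct a PL-Net with seeded Kaiming initialization."""
    return PLNet(config, rng=np.random.default_rng(seed))


def count_parameters(model: PLNet) -> int:
    """Exact number of trainable scalars (convs, biases, norm scales/shifts,
    transposed-conv upsamplers, bridge, prediction heads)."""
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# checkpoints: npz weights + YAML sidecar echoing the ArchConfig
# ---------------------------------------------------------------------------


def save_checkpoint(model: PLNet, path):
    path = str(path)
    arrays = {name: p.data for name, p in model.named_parameters()}
    for i, (mod, key) in enumerate(model.buffers()):
        arrays[f"__buffer{i}__{key}"] = getattr(mod, key)
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    side = (path[: -len(".npz")] if path.endswith(".npz") else path) + ".yaml"
    with io.open(side, "w") as fh:
        yaml.safe_dump({"arch": model.config.to_dict()}, fh)


def load_checkpoint(path):
    path = str(path)
    npz = path if path.endswith(".npz") else path + ".npz"
    side = (path[: -len(".npz")] if path.endswith(".npz") else path) + ".yaml"
    with io.open(side) as fh:
        cfg = ArchConfig.from_dict(yaml.safe_load(fh)["arch"])
    model = build_plnet(cfg)
    data = np.load(npz)
    for name, p in model.named_parameters():
        p.data = np.array(data[name])
    for i, (mod, key) in enumerate(model.buffers()):
        setattr(mod, key, np.array(data[f"__buffer{i}__{key}"]))
    return model
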