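"""Assembly of the multi-task mobile 3-D U-Net and its classical baseline.

Both variants share one declarative layer plan:

* **encoder** — ``num_levels`` modules.  Module *i* applies two
  feature-extraction units (the first doubles the channel count to
  ``base_channels * 2**i``, the second preserves it) followed by 2x2x2 max
  pooling, so each module doubles the channels while halving every extent.
* **decoder** — the mirror image: each module starts with a 2x2x2 transpose
  convolution that doubles the extents and halves the channels, concatenates
  the matching encoder skip tensor, and applies two feature-recovery units
  (the first halves the concatenated width, the second preserves it).
* a final 1x1x1 convolution maps to ``num_classes_seg`` channels and a
  sigmoid turns them into voxelwise probabilities in [0, 1].

In the ``mm_3dunet`` variant every unit is an inverted-residual-wrapped CEC
unit (1x1x1 expansion by factor ``t``, depthwise 3x3x3, linear 1x1x1
compression; the identity skip is active whenever input and output widths
match).  In the ``baseline_3dunet`` variant every unit is a single standard
3x3x3 convolution followed by LeakyReLU and instance normalisation.

With ``use_act`` an auxiliary classification branch is attached to the
deepest encoder features: the depth axis is collapsed by averaging, a 3x3
2-D convolution extracts planar type features, max pooling and global
average pooling condense them, and a linear layer emits one logit per class
(lesion present / absent).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .blocks import CECSpec, CECUnit, ConvSpec, InvertedResidual, TensorShape

VARIANTS = ("baseline_3dunet", "mm_3dunet")


@dataclass(frozen=True)
class NetworkConfig:
    """Every architectural knob needed to rebuild a network bit-for-bit."""

    variant: str = "mm_3dunet"
    base_channels: int = 16
    num_levels: int = 4
    expansion_factor: int = 6
    input_shape: TensorShape = field(
        default_factory=lambda: TensorShape(1, 32, 256, 256))
    use_act: bool = False
    num_classes_seg: int = 1
    num_classes_cls: int = 2
    negative_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.base_channels < 2 or self.base_channels % 2:
            raise ValueError("base_channels must be a positive even integer")
        if self.num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if self.expansion_factor < 1:
            raise ValueError("expansion factor t must be >= 1")
        if self.input_shape.channels != 1:
            raise ValueError("single-channel volumes only")
        div = 2 ** self.num_levels
        for ext in self.input_shape.spatial:
            if ext % div:
                raise ValueError(
                    f"input extents {self.input_shape.spatial} must be divisible by "
                    f"2**num_levels = {div}")

    @property
    def encoder_widths(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.num_levels)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list((self.input_shape.channels,) + self.input_shape.spatial)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        c, *spatial = d.pop("input_shape")
        return cls(input_shape=TensorShape(c, *spatial), **d)


@dataclass(frozen=True)
class PlanEntry:
    """One ledger row of the architecture: a unit, transpose, or head layer."""

    layer_id: str
    role: str          # unit | transpose | final | act_conv | act_linear
    in_channels: int
    out_channels: int
    level: int         # spatial extents are input extents / 2**level


def layer_plan(config: NetworkConfig) -> list[PlanEntry]:
    """The exact layer sequence of :func:`build_network`, as cost-ledger rows."""
    L = config.num_levels
    widths = config.encoder_widths
    plan: list[PlanEntry] = []
    cin = config.input_shape.channels
    for i, w in enumerate(widths):
        plan.append(PlanEntry(f"enc{i}/unit0", "unit", cin, w, i))
        plan.append(PlanEntry(f"enc{i}/unit1", "unit", w, w, i))
        cin = w
    d = widths[-1]
    for i in range(L - 1, -1, -1):
        up = d // 2
        plan.append(PlanEntry(f"dec{i}/up", "transpose", d, up, i))
        cat = up + widths[i]
        out = d // 2
        plan.append(PlanEntry(f"dec{i}/unit0", "unit", cat, out, i))
        plan.append(PlanEntry(f"dec{i}/unit1", "unit", out, out, i))
        d = out
    plan.append(PlanEntry("seg_head", "final", d, config.num_classes_seg, 0))
    if config.use_act:
        deep = widths[-1]
        plan.append(PlanEntry("act/conv", "act_conv", deep, config.base_channels, L))
        plan.append(PlanEntry("act/linear", "act_linear",
                              config.base_channels, config.num_classes_cls, L))
    return plan


@dataclass
class NetworkOutput:
    """Segmentation probabilities plus optional classifier logits."""

    seg_probs: np.ndarray
    cls_logits: np.ndarray | None = None


def _make_unit(config: NetworkConfig, cin: int, cout: int,
               rng: np.random.Generator) -> nn.Module:
    if config.variant == "mm_3dunet":
        spec = CECSpec(cin, cout, config.expansion_factor,
                       negative_slope=config.negative_slope,
                       use_residual=(cin == cout))
        return InvertedResidual(spec, rng)
    return nn.Sequential(nn.Conv3d(cin, cout, (3, 3, 3), rng),
                         nn.LeakyReLU(config.negative_slope),
                         nn.InstanceNorm(cout))


class MMNet(nn.Module):
    """Runnable network; the layer layout mirrors :func:`layer_plan` exactly."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.num_levels
        widths = config.encoder_widths
        self.enc_units: list[nn.Module] = []
        self.pools: list[nn.MaxPool3d] = []
        cin = config.input_shape.channels
        for w in widths:
            self.enc_units.append(_make_unit(config, cin, w, rng))
            self.enc_units.append(_make_unit(config, w, w, rng))
            self.pools.append(nn.MaxPool3d())
            cin = w
        self.transposes: list[nn.ConvTranspose3d] = []
        self.dec_units: list[nn.Module] = []
        d = widths[-1]
        for i in range(L - 1, -1, -1):
            self.transposes.append(nn.ConvTranspose3d(d, d // 2, rng))
            cat = d // 2 + widths[i]
            self.dec_units.append(_make_unit(config, cat, d // 2, rng))
            self.dec_units.append(_make_unit(config, d // 2, d // 2, rng))
            d = d // 2
        self.seg_head = nn.PointwiseConv3d(d, config.num_classes_seg, rng)
        self.sigmoid = nn.Sigmoid()
        if config.use_act:
            deep = widths[-1]
            self.act_conv = nn.Conv2d(deep, config.base_channels, 3, rng)
            self.act_act = nn.LeakyReLU(config.negative_slope)
            self.act_pool = nn.MaxPool2d()
            self.act_linear = nn.Linear(config.base_channels, config.num_classes_cls, rng)
        self._cache: dict = {}

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> NetworkOutput:
        cfg = self.config
        if x.ndim != 4 or x.shape[0] != cfg.input_shape.channels:
            raise ValueError(f"expected ({cfg.input_shape.channels}, D, H, W) input, "
                             f"got {x.shape}")
        div = 2 ** cfg.num_levels
        if any(ext % div for ext in x.shape[1:]):
            raise ValueError(f"input extents {x.shape[1:]} must be divisible by {div}")
        x = np.asarray(x, dtype=np.float32)
        L = cfg.num_levels
        skips = []
        h = x
        for i in range(L):
            h = self.enc_units[2 * i](h)
            h = self.enc_units[2 * i + 1](h)
            skips.append(h)
            h = self.pools[i](h)
        deep = h
        cls_logits = None
        if cfg.use_act:
            planar = deep.mean(axis=1)                       # collapse depth
            self._cache["act_depth"] = deep.shape[1]
            f = self.act_pool(self.act_act(self.act_conv(planar)))
            self._cache["act_spatial"] = f.shape[1:]
            pooled = f.mean(axis=(1, 2))                     # global average
            cls_logits = self.act_linear(pooled)
        split_at = []
        for j, i in enumerate(range(L - 1, -1, -1)):
            h = self.transposes[j](h)
            split_at.append(h.shape[0])
            h = np.concatenate([h, skips[i]], axis=0)
            h = self.dec_units[2 * j](h)
            h = self.dec_units[2 * j + 1](h)
        self._cache["split_at"] = split_at
        seg = self.sigmoid(self.seg_head(h))
        return NetworkOutput(seg_probs=seg, cls_logits=cls_logits)

    # -- backward --------------------------------------------------------
    def backward(self, seg_grad: np.ndarray,
                 cls_grad: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients given output gradients."""
        cfg = self.config
        L = cfg.num_levels
        g = self.seg_head.backward(self.sigmoid.backward(seg_grad))
        skip_grads: dict[int, np.ndarray] = {}
        split_at = self._cache["split_at"]
        for j in range(L - 1, -1, -1):
            i = L - 1 - j
            g = self.dec_units[2 * j + 1].backward(g)
            g = self.dec_units[2 * j].backward(g)
            s = split_at[j]
            skip_grads[i] = g[s:]
            g = self.transposes[j].backward(np.ascontiguousarray(g[:s]))
        if cfg.use_act and cls_grad is not None:
            gl = self.act_linear.backward(cls_grad)
            hs, ws = self._cache["act_spatial"]
            gf = np.broadcast_to(gl[:, None, None] / (hs * ws),
                                 (gl.shape[0], hs, ws)).astype(np.float32)
            gp = self.act_conv.backward(self.act_act.backward(self.act_pool.backward(gf)))
            depth = self._cache["act_depth"]
            g = g + np.broadcast_to(gp[:, None] / depth,
                                    (gp.shape[0], depth) + gp.shape[1:]).astype(np.float32)
        for i in range(L - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc_units[2 * i + 1].backward(g)
            g = self.enc_units[2 * i].backward(g)


def build_network(config: NetworkConfig) -> MMNet:
    """Instantiate the parameterised network described by ``config``."""
    return MMNet(config)


def save_checkpoint(network: MMNet, path) -> None:
    """Persist weights plus the embedded NetworkConfig (npz + JSON)."""
    import json

    arrays = {k: p.value for k, p in network.parameters().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(network.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> MMNet:
    """Rebuild a network bit-for-bit from a checkpoint file."""
    import json

    with np.load(path) as data:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode()))
        net = MMNet(cfg)
        params = net.parameters()
        for k, p in params.items():
            p.value = data[k].astype(np.float32)
    return net


def predict_mask(output: NetworkOutput, threshold: float = 0.5) -> np.ndarray:
    """Binarise segmentation probabilities; ties (p == threshold) are positive."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    return (output.seg_probs >= threshold).astype(np.uint8)
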