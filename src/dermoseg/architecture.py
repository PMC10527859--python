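"""Dermo-Seg network assembly: residual encoder + UNet decoder.

The encoder follows the canonical deep-residual-network stage table: a 7x7
stride-2 stem, a 3x3 stride-2 max-pool, then four stages of residual blocks
(bottleneck triples for the 50/101/152-layer configurations, basic pairs
for 18/34), halving the spatial size per stage.  The decoder mirrors a UNet
expansive path: each stage is a x2 nearest-neighbour up-sample, a channel
concatenation with the matching-resolution encoder activation (four skips
for the canonical depth-32 encoder), and two CONV_BLOCKs (3x3 conv ->
batch-norm -> ReLU).  A 1x1 convolution plus sigmoid maps the final feature
map to a single foreground-probability channel, so output spatial size
equals input spatial size.

Skip sources are the last ReLU activation of the stem (before max-pooling)
and of every encoder stage except the deepest.  The encoder can be frozen
(its weights excluded from optimisation and its batch-norms run in
inference mode), matching the transfer-learning setup in which only the
decoder and head are trained.

``count_flops`` and ``count_parameters`` provide the analytic accounting:
one FLOP per multiply-add over convolutional and fully-connected layers,
including the 1x1 projection shortcuts instantiated wherever a block
changes shape.  Down-sampling bottlenecks carry their stride on the first
1x1 convolution (the original placement), which the FLOP figures are
sensitive to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    Module,
    Param,
    ReLU,
    Sigmoid,
    UpsampleNearest2d,
)

__all__ = [
    "EncoderSpec",
    "DecoderSpec",
    "ModelSummary",
    "SegmentationModel",
    "build_dermoseg",
    "count_flops",
    "count_parameters",
    "forward",
    "format_flops_as_published",
]


# ---------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class EncoderSpec:
    """Residual-encoder configuration (stage table)."""

    stem_channels: int = 64
    stem_kernel: int = 7
    block: str = "bottleneck"  # "bottleneck" (1x1,3x3,1x1) or "basic" (3x3,3x3)
    repeats: tuple[int, ...] = (3, 4, 6, 3)
    widths: tuple[int, ...] = (64, 128, 256, 512)
    num_classes: int = 1000  # classification head, used only for FLOP accounting

    def __post_init__(self) -> None:
        if self.block not in ("bottleneck", "basic"):
            raise ValueError("block must be 'bottleneck' or 'basic'")
        if len(self.repeats) != len(self.widths):
            raise ValueError("repeats and widths must have equal length")

    @property
    def expansion(self) -> int:
        return 4 if self.block == "bottleneck" else 1

    @property
    def n_stages(self) -> int:
        return len(self.repeats)

    @property
    def downsample_factor(self) -> int:
        # stem stride 2, max-pool stride 2, one stride-2 stage transition each
        return 4 * 2 ** (self.n_stages - 1)

    def stage_output_sizes(self, input_size: int) -> list[int]:
        """Spatial side of each stage output (224 -> [56, 28, 14, 7])."""
        s = input_size // 4
        sizes = [s]
        for _ in range(self.n_stages - 1):
            s //= 2
            sizes.append(s)
        return sizes

    @classmethod
    def resnet18(cls) -> "EncoderSpec":
        return cls(block="basic", repeats=(2, 2, 2, 2))

    @classmethod
    def resnet34(cls) -> "EncoderSpec":
        return cls(block="basic", repeats=(3, 4, 6, 3))

    @classmethod
    def resnet50(cls) -> "EncoderSpec":
        return cls(block="bottleneck", repeats=(3, 4, 6, 3))

    @classmethod
    def resnet101(cls) -> "EncoderSpec":
        return cls(block="bottleneck", repeats=(3, 4, 23, 3))

    @classmethod
    def resnet152(cls) -> "EncoderSpec":
        return cls(block="bottleneck", repeats=(3, 8, 36, 3))

    @classmethod
    def desk(cls) -> "EncoderSpec":
        """Reduced two-stage encoder for CPU-scale runs (downsample x8)."""
        return cls(stem_channels=16, block="bottleneck", repeats=(1, 1), widths=(8, 16))


@dataclass(frozen=True)
class DecoderSpec:
    """UNet expansive-path configuration: one filter width per up-sample."""

    widths: tuple[int, ...] = (256, 128, 64, 32, 16)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("decoder widths must be positive")
        if any(a < b for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError("decoder widths must be non-increasing")

    @classmethod
    def desk(cls) -> "DecoderSpec":
        return cls(widths=(32, 16, 8))


@dataclass(frozen=True)
class ModelSummary:
    total: int
    trainable: int
    non_trainable: int


# ---------------------------------------------------------------------------
# Analytic accounting


def count_flops(spec: EncoderSpec, input_size: int = 224, include_top: bool = True) -> int:
    """Multiply-add count of the encoder (optionally + classifier head).

    One FLOP per multiply-add of every convolution and fully-connected
    layer, including the 1x1 projection shortcut of each shape-changing
    block; identity shortcuts and pooling contribute no multiply-adds.
    """
    s = input_size // 2
    flops = s * s * spec.stem_kernel**2 * 3 * spec.stem_channels
    s //= 2  # max-pool
    cin = spec.stem_channels
    for i, (reps, w) in enumerate(zip(spec.repeats, spec.widths)):
        stride = 1 if i == 0 else 2
        if i > 0:
            s //= 2
        cout = w * spec.expansion
        for b in range(reps):
            if spec.block == "bottleneck":
                flops += s * s * cin * w  # 1x1 reduce (carries the stride in block 0)
                flops += s * s * 9 * w * w  # 3x3
                flops += s * s * w * cout  # 1x1 expand
            else:
                flops += s * s * 9 * cin * w
                flops += s * s * 9 * w * w
            if b == 0 and (cin != cout or stride != 1):
                flops += s * s * cin * cout
            cin = cout
    if include_top:
        flops += cin * spec.num_classes  # global average pool has no multiply-adds
    return int(flops)


def format_flops_as_published(flops: int) -> float:
    """Two-significant-figure figure in the style of the architecture table.

    The published stage table truncates toward zero at two significant
    figures (its 34- and 50-layer entries are below the round-half-up
    values of the exact counts), so this formatter truncates as well.
    """
    if flops <= 0:
        return 0.0
    exp = math.floor(math.log10(flops)) - 1
    return math.floor(flops / 10**exp) * 10.0**exp


# ---------------------------------------------------------------------------
# Network modules


class _ConvBlock(Module):
    """CONV_BLOCK: 3x3 (or given) convolution -> batch-norm -> ReLU."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng, name: str):
        self.conv = Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng, name=name)
        self.bn = BatchNorm2d(cout, name=name)
        self.relu = ReLU()

    def forward(self, x, train=False):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class _Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with post-addition ReLU."""

    def __init__(self, cin: int, width: int, stride: int, rng, name: str):
        cout = width * 4
        self.conv1 = Conv2d(cin, width, 1, stride=stride, padding=0, rng=rng, name=f"{name}.c1")
        self.bn1 = BatchNorm2d(width, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(width, width, 3, rng=rng, name=f"{name}.c2")
        self.bn2 = BatchNorm2d(width, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv3 = Conv2d(width, cout, 1, padding=0, rng=rng, name=f"{name}.c3")
        self.bn3 = BatchNorm2d(cout, name=f"{name}.bn3")
        if cin != cout or stride != 1:
            self.proj = Conv2d(cin, cout, 1, stride=stride, padding=0, rng=rng, name=f"{name}.proj")
            self.proj_bn = BatchNorm2d(cout, name=f"{name}.proj_bn")
        else:
            self.proj = None
            self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        t = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        t = self.relu2.forward(self.bn2.forward(self.conv2.forward(t, train), train), train)
        t = self.bn3.forward(self.conv3.forward(t, train), train)
        if self.proj is not None:
            identity = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            identity = x
        return self.relu_out.forward(t + identity, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv3.backward(self.bn3.backward(d))
        dmain = self.conv2.backward(self.bn2.backward(self.relu2.backward(dmain)))
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(d))
        else:
            dx = dx + d
        return dx


class _BasicBlock(Module):
    """3x3 -> 3x3 residual block (18/34-layer configurations)."""

    def __init__(self, cin: int, width: int, stride: int, rng, name: str):
        self.conv1 = Conv2d(cin, width, 3, stride=stride, rng=rng, name=f"{name}.c1")
        self.bn1 = BatchNorm2d(width, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(width, width, 3, rng=rng, name=f"{name}.c2")
        self.bn2 = BatchNorm2d(width, name=f"{name}.bn2")
        if cin != width or stride != 1:
            self.proj = Conv2d(cin, width, 1, stride=stride, padding=0, rng=rng, name=f"{name}.proj")
            self.proj_bn = BatchNorm2d(width, name=f"{name}.proj_bn")
        else:
            self.proj = None
            self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        t = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        t = self.bn2.forward(self.conv2.forward(t, train), train)
        if self.proj is not None:
            identity = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            identity = x
        return self.relu_out.forward(t + identity, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv2.backward(self.bn2.backward(d))
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(d))
        else:
            dx = dx + d
        return dx


class _DecoderBlock(Module):
    """x2 up-sample, optional skip concatenation, two CONV_BLOCKs."""

    def __init__(self, cin: int, skip_channels: int, width: int, rng, name: str):
        self.cin = cin
        self.skip_channels = skip_channels
        self.up = UpsampleNearest2d(2)
        self.block1 = _ConvBlock(cin + skip_channels, width, 3, 1, rng, f"{name}.b1")
        self.block2 = _ConvBlock(width, width, 3, 1, rng, f"{name}.b2")

    def forward(self, x, skip, train=False):
        u = self.up.forward(x, train)
        if skip is not None:
            u = np.concatenate([u, skip], axis=1)
        return self.block2.forward(self.block1.forward(u, train), train)

    def backward(self, dy):
        dcat = self.block1.backward(self.block2.backward(dy))
        if self.skip_channels:
            dup, dskip = dcat[:, : self.cin], dcat[:, self.cin :]
        else:
            dup, dskip = dcat, None
        return self.up.backward(dup), dskip


class SegmentationModel(Module):
    """The assembled encoder-decoder with a sigmoid foreground head.

    Weight set w is partitioned into the (optionally frozen) encoder and
    the trainable decoder + head; training minimises the hybrid loss over
    the trainable partition.  Input contract: NCHW float images scaled to
    [0, 1], spatial side divisible by the encoder downsample factor (zero
    padding is applied when ``pad_input`` is enabled); output: same spatial
    size, one channel of per-pixel probabilities.
    """

    def __init__(
        self,
        encoder_spec: EncoderSpec,
        decoder_spec: DecoderSpec,
        freeze_encoder: bool = True,
        seed: int = 0,
        pad_input: bool = False,
    ):
        n_up = encoder_spec.n_stages + 1
        if len(decoder_spec.widths) != n_up:
            raise ValueError(
                f"decoder needs {n_up} stages for this encoder, got {len(decoder_spec.widths)}"
            )
        self.encoder_spec = encoder_spec
        self.decoder_spec = decoder_spec
        self.freeze_encoder = freeze_encoder
        self.pad_input = pad_input
        rng = np.random.default_rng(seed)

        es = encoder_spec
        self.stem_conv = Conv2d(3, es.stem_channels, es.stem_kernel, stride=2, rng=rng, name="stem")
        self.stem_bn = BatchNorm2d(es.stem_channels, name="stem")
        self.stem_relu = ReLU()
        self.pool = MaxPool2d(3, 2, 1)

        block_cls = _Bottleneck if es.block == "bottleneck" else _BasicBlock
        self.stages: list[list[Module]] = []
        cin = es.stem_channels
        for i, (reps, w) in enumerate(zip(es.repeats, es.widths)):
            blocks = []
            for b in range(reps):
                stride = 2 if (i > 0 and b == 0) else 1
                blocks.append(block_cls(cin, w, stride, rng, f"stage{i + 1}.{b}"))
                cin = w * es.expansion
            self.stages.append(blocks)

        # skip channel widths, deepest first, then the stem activation
        stage_out = [w * es.expansion for w in es.widths]
        skip_channels = list(reversed(stage_out[:-1])) + [es.stem_channels]
        self.decoder_blocks: list[_DecoderBlock] = []
        dcin = stage_out[-1]
        for i, w in enumerate(decoder_spec.widths):
            sc = skip_channels[i] if i < len(skip_channels) else 0
            self.decoder_blocks.append(_DecoderBlock(dcin, sc, w, rng, f"dec{i + 1}"))
            dcin = w
        self.n_skips = len(skip_channels)
        self.head_conv = Conv2d(dcin, 1, 1, padding=0, bias=True, rng=rng, name="head")
        self.head_sigmoid = Sigmoid()

        if freeze_encoder:
            for p in self.encoder_parameters():
                p.trainable = False

    # -- parameter partitions ------------------------------------------------

    def encoder_parameters(self) -> list[Param]:
        out = self.stem_conv.parameters() + self.stem_bn.parameters()
        for stage in self.stages:
            for block in stage:
                out.extend(block.parameters())
        return out

    def decoder_parameters(self) -> list[Param]:
        out: list[Param] = []
        for dec in self.decoder_blocks:
            out.extend(dec.parameters())
        out.extend(self.head_conv.parameters())
        return out

    def parameters(self) -> list[Param]:
        return self.encoder_parameters() + self.decoder_parameters()

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected an NCHW batch with 3 channels")
        factor = self.encoder_spec.downsample_factor
        h, w = x.shape[2], x.shape[3]
        pad_h = (-h) % factor
        pad_w = (-w) % factor
        if (pad_h or pad_w) and not self.pad_input:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by {factor}; enable pad_input to zero-pad"
            )
        if pad_h or pad_w:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
        # frozen encoders run in inference mode so batch-norm statistics stay fixed
        enc_train = train and not self.freeze_encoder
        t = self.stem_bn.forward(self.stem_conv.forward(x, enc_train), enc_train)
        skip_stem = self.stem_relu.forward(t, enc_train)
        t = self.pool.forward(skip_stem, enc_train)
        stage_outs = []
        for stage in self.stages:
            for block in stage:
                t = block.forward(t, enc_train)
            stage_outs.append(t)
        skips = list(reversed(stage_outs[:-1])) + [skip_stem]
        d = t
        for i, dec in enumerate(self.decoder_blocks):
            skip = skips[i] if i < self.n_skips else None
            d = dec.forward(d, skip, train)
        p = self.head_sigmoid.forward(self.head_conv.forward(d, train), train)
        if pad_h or pad_w:
            p = p[:, :, :h, :w]
        return p

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate gradients given dLoss/dProbability (NCHW, 1 channel)."""
        d = self.head_conv.backward(self.head_sigmoid.backward(dprob))
        dskips: list[np.ndarray | None] = []
        for dec in reversed(self.decoder_blocks):
            d, dskip = dec.backward(d)
            dskips.append(dskip)
        dskips.reverse()  # now aligned with decoder order (deepest skip first)
        if self.freeze_encoder:
            return
        n = len(self.stages)
        for j in range(n - 1, -1, -1):
            for block in reversed(self.stages[j]):
                d = block.backward(d)
            if j > 0:  # skip i feeds stage_outs[n-2-i]; stage j-1 <-> i = n-1-j
                d = d + dskips[n - 1 - j]
        d = self.pool.backward(d)
        d = d + dskips[n - 1]  # stem skip
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(d)))

    # -- weights IO ----------------------------------------------------------

    def _named_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i:04d}_{p.name}"] = p.value
        bns = [m for m in self._walk() if isinstance(m, BatchNorm2d)]
        for i, bn in enumerate(bns):
            state[f"bnstat_{i:04d}_mean"] = bn.running_mean
            state[f"bnstat_{i:04d}_var"] = bn.running_var
        return state

    def _walk(self):
        seen = []

        def rec(obj):
            if isinstance(obj, Module):
                seen.append(obj)
                for attr in vars(obj).values():
                    rec(attr)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    rec(item)

        rec(self)
        return seen

    def save_weights(self, path) -> None:
        np.savez(path, **self._named_state())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            state = dict(data)
        self.set_state(state)

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_state().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            key = f"param_{i:04d}_{p.name}"
            if p.value.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value = state[key].copy()
        bns = [m for m in self._walk() if isinstance(m, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = state[f"bnstat_{i:04d}_mean"].copy()
            bn.running_var = state[f"bnstat_{i:04d}_var"].copy()


def build_dermoseg(
    encoder: EncoderSpec | None = None,
    decoder: DecoderSpec | None = None,
    freeze_encoder: bool = True,
    pretrained: str | None = None,
    seed: int = 0,
    pad_input: bool = False,
) -> SegmentationModel:
    """Assemble the segmentation network.

    ``pretrained`` takes a path to an ``.npz`` weights file (e.g. an encoder
    snapshot exported by :meth:`SegmentationModel.save_weights`); when None
    the network starts from He-initialised random weights.  ``freeze_encoder``
    excludes every encoder parameter from the trainable set.
    """
    model = SegmentationModel(
        encoder or EncoderSpec.resnet50(),
        decoder or DecoderSpec(),
        freeze_encoder=freeze_encoder,
        seed=seed,
        pad_input=pad_input,
    )
    if pretrained is not None:
        model.load_weights(pretrained)
        if freeze_encoder:
            for p in model.encoder_parameters():
                p.trainable = False
    return model


def count_parameters(model: SegmentationModel) -> ModelSummary:
    """Exact layer-wise parameter counts (batch-norm running stats excluded)."""
    trainable = sum(p.size for p in model.parameters() if p.trainable)
    non_trainable = sum(p.size for p in model.parameters() if not p.trainable)
    return ModelSummary(
        total=trainable + non_trainable, trainable=trainable, non_trainable=non_trainable
    )


def forward(model: SegmentationModel, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Inference-mode forward pass in batches; returns (N, H, W) probabilities."""
    images = np.asarray(images, dtype=np.float32)
    outs = []
    for i in range(0, images.shape[0], batch_size):
        outs.append(model.forward(images[i : i + batch_size], train=False)[:, 0])
    return np.concatenate(outs, axis=0)
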