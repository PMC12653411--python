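"""Two-phase gated attention-augmented Double U-Net.

Phase 1 is a VGG-19-style encoder (four blocks; 2+2+4+4 convolutions) whose
first three blocks end in 2×2 max pooling, so the fourth block's output sits
at 1/8 resolution — 28×28 with 512 channels for a 224×224 input. That output
passes through the bottleneck cascade (attention-augmented convolution →
gating → ASPP, each toggleable) and a four-block decoder with conditional
bilinear upsampling: the deepest decoder block fuses the stage-4 skip at 1/8
resolution without upsampling, and each subsequent block doubles the spatial
size and fuses the matching shallower skip, followed by squeeze-and-
excitation. A softmax head emits the Phase-1 probability map.

Phase 2 re-encodes the input image masked by Phase 1's foreground
probability. Its encoder mirrors the conditional structure (first block
without pooling, blocks 2–4 pooled, SE after each block), shares the same
bottleneck cascade design, and its decoder blocks concatenate three inputs:
upsampled features, the Phase-2 encoder skip, and the Phase-1 decoder output
at the same resolution. The two phase probability maps are concatenated and
fused by a 1×1 convolution + softmax into the final three-class map
(background / cytoplasm / nucleus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .blocks import (AACConfig, AAConv2d, ASPP, ConfigurationError,
                     GatingBlock, SEBlock, _ConvBNReLU)
from .tensor import Tensor, concat, maxpool2d, no_grad, upsample_bilinear2d

__all__ = ["ModelConfig", "GaadUNet", "save_checkpoint", "load_checkpoint",
           "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by 8 (three pooling stages precede the
    bottleneck). The attention block's relative-position tables are sized
    from ``input_size / 8`` at construction.
    """

    num_classes: int = 3
    input_size: tuple[int, int] = (224, 224)
    encoder1_widths: tuple[int, ...] = (64, 128, 256, 512)
    encoder2_widths: tuple[int, ...] = (64, 128, 256, 512)
    decoder_widths: tuple[int, ...] = (256, 128, 64, 32)
    encoder1_convs: tuple[int, ...] = (2, 2, 4, 4)  # VGG-19 layout
    encoder2_convs: tuple[int, ...] = (2, 2, 2, 2)
    aspp_out: int = 256
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    se_reduction: int = 8
    use_aac: bool = True
    use_gating: bool = True
    dk_total: int = 32
    dv_total: int = 32
    num_heads: int = 4
    relative: bool = True

    def __post_init__(self):
        h, w = self.input_size
        if h % 8 or w % 8:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by 8")
        if len(self.encoder1_widths) != 4 or len(self.decoder_widths) != 4:
            raise ConfigurationError("expected four encoder/decoder stages")

    @property
    def bottleneck_size(self) -> tuple[int, int]:
        return (self.input_size[0] // 8, self.input_size[1] // 8)

    def aac_config(self, channels: int) -> AACConfig:
        return AACConfig(in_channels=channels, out_channels=channels,
                         dk_total=self.dk_total, dv_total=self.dv_total,
                         num_heads=self.num_heads, relative=self.relative,
                         spatial_shape=self.bottleneck_size)

    def scaled(self, factor: int) -> "ModelConfig":
        """Width-reduced copy (all channel counts divided by ``factor``)."""
        def div(ws):
            return tuple(max(1, w // factor) for w in ws)
        d = asdict(self)
        d["encoder1_widths"] = div(self.encoder1_widths)
        d["encoder2_widths"] = div(self.encoder2_widths)
        d["decoder_widths"] = div(self.decoder_widths)
        d["aspp_out"] = max(1, self.aspp_out // factor)
        for k in ("input_size", "aspp_rates", "encoder1_convs", "encoder2_convs"):
            d[k] = tuple(d[k])
        return ModelConfig(**d)


class _EncoderBlock(nn.Module):
    """Stack of 3×3 Conv-BN-ReLU layers, optional trailing SE."""

    def __init__(self, cin, cout, n_convs, se_reduction=None, rng=None):
        super().__init__()
        layers = []
        for i in range(n_convs):
            layers.append(_ConvBNReLU(cin if i == 0 else cout, cout, 3, rng=rng))
        self.layers = nn.ModuleList(layers)
        self.se = SEBlock(cout, se_reduction, rng=rng) if se_reduction else None

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        if self.se is not None:
            x = self.se(x)
        return x


class _Bottleneck(nn.Module):
    """AAC (optional) → gating (optional) → ASPP cascade."""

    def __init__(self, cfg: ModelConfig, channels: int, rng=None):
        super().__init__()
        self.aac = AAConv2d(cfg.aac_config(channels), rng=rng) if cfg.use_aac else None
        self.gating = GatingBlock(channels, rng=rng) if cfg.use_gating else None
        self.aspp = ASPP(channels, cfg.aspp_out, cfg.aspp_rates, rng=rng)

    def forward(self, x):
        self.last_input_shape = tuple(x.shape)  # introspection for contracts
        if self.aac is not None:
            x = self.aac(x)
        if self.gating is not None:
            x = self.gating(x)
        return self.aspp(x)


class _DecoderBlock(nn.Module):
    """Conditional ×2 bilinear upsampling, skip concatenation, two
    Conv-BN-ReLU layers, then SE."""

    def __init__(self, cin, skip_channels, cout, upsample, se_reduction,
                 name, rng=None):
        super().__init__()
        self.upsample = upsample
        self.name = name
        self.skip_channels = tuple(skip_channels)
        total = cin + sum(skip_channels)
        self.conv1 = _ConvBNReLU(total, cout, 3, rng=rng)
        self.conv2 = _ConvBNReLU(cout, cout, 3, rng=rng)
        self.se = SEBlock(cout, se_reduction, rng=rng)

    def forward(self, x, skips):
        if self.upsample:
            x = upsample_bilinear2d(x, (x.shape[2] * 2, x.shape[3] * 2))
        for s, expect in zip(skips, self.skip_channels):
            if s.shape[2:] != x.shape[2:] or s.shape[1] != expect:
                raise ConfigurationError(
                    f"{self.name}: skip shape {s.shape} incompatible with "
                    f"features {x.shape} (expected {expect} channels)")
        x = concat([x, *skips], axis=1)
        return self.se(self.conv2(self.conv1(x)))


class _Phase1(nn.Module):
    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        w, nc = cfg.encoder1_widths, cfg.encoder1_convs
        self.enc = nn.ModuleList([
            _EncoderBlock(3 if i == 0 else w[i - 1], w[i], nc[i], rng=rng)
            for i in range(4)])
        self.bottleneck = _Bottleneck(cfg, w[3], rng=rng)
        dw = cfg.decoder_widths
        skip_w = (w[3], w[2], w[1], w[0])
        self.dec = nn.ModuleList([
            _DecoderBlock(cfg.aspp_out if i == 0 else dw[i - 1], [skip_w[i]],
                          dw[i], upsample=(i > 0), se_reduction=cfg.se_reduction,
                          name=f"phase1.decoder{i + 1}", rng=rng)
            for i in range(4)])
        self.head = nn.Conv2d(dw[3], cfg.num_classes, 1, rng=rng)

    def forward(self, x):
        skips = []
        for i, block in enumerate(self.enc):
            if i > 0:
                x = maxpool2d(x)
            x = block(x)
            skips.append(x)
        x = self.bottleneck(x)
        dec_outs = []
        for i, block in enumerate(self.dec):
            x = block(x, [skips[3 - i]])
            dec_outs.append(x)
        probs = self.head(x).softmax(axis=1)
        return probs, dec_outs


class _Phase2(nn.Module):
    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        w, nc = cfg.encoder2_widths, cfg.encoder2_convs
        self.enc = nn.ModuleList([
            _EncoderBlock(3 if i == 0 else w[i - 1], w[i], nc[i],
                          se_reduction=cfg.se_reduction, rng=rng)
            for i in range(4)])
        self.bottleneck = _Bottleneck(cfg, w[3], rng=rng)
        dw = cfg.decoder_widths
        skip_w = (w[3], w[2], w[1], w[0])
        self.dec = nn.ModuleList([
            _DecoderBlock(cfg.aspp_out if i == 0 else dw[i - 1],
                          [skip_w[i], dw[i]], dw[i], upsample=(i > 0),
                          se_reduction=cfg.se_reduction,
                          name=f"phase2.decoder{i + 1}", rng=rng)
            for i in range(4)])
        self.head = nn.Conv2d(dw[3], cfg.num_classes, 1, rng=rng)

    def forward(self, x, phase1_dec_outs):
        skips = []
        for i, block in enumerate(self.enc):
            if i > 0:  # conditional pooling: first block keeps full resolution
                x = maxpool2d(x)
            x = block(x)
            skips.append(x)
        x = self.bottleneck(x)
        for i, block in enumerate(self.dec):
            x = block(x, [skips[3 - i], phase1_dec_outs[i]])
        return self.head(x).softmax(axis=1)


def phase2_input(image: Tensor, probs1: Tensor) -> Tensor:
    """Mask the input image by Phase 1's foreground probability.

    Foreground = 1 − background-class probability, broadcast over the three
    color channels. At inference this replaces the ground-truth product the
    refinement stage is built on during supervised training.
    """
    if image.shape[2:] != probs1.shape[2:]:
        raise ConfigurationError(
            f"image {image.shape} and probability map {probs1.shape} "
            "are not spatially aligned")
    fg = 1.0 - probs1.narrow(1, 0, 1)  # (B, 1, H, W)
    return image * fg


class GaadUNet(nn.Module):
    """Full two-phase model; returns (final, phase-1, phase-2) probability maps."""

    def __init__(self, cfg: ModelConfig, seed: int | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.phase1 = _Phase1(cfg, rng=rng)
        self.phase2 = _Phase2(cfg, rng=rng)
        self.fusion = nn.Conv2d(2 * cfg.num_classes, cfg.num_classes, 1, rng=rng)

    def forward(self, image: Tensor, gt_onehot: Tensor | None = None):
        """Run both phases.

        ``gt_onehot`` (B, classes, H, W), if given, gates the Phase-2 input
        by the ground-truth foreground instead of the predicted one
        (teacher forcing during training); inference never uses it.
        """
        if image.shape[1] != 3:
            raise ConfigurationError("expected a 3-channel RGB input")
        h, w = image.shape[2], image.shape[3]
        if h % 8 or w % 8:
            raise ConfigurationError(
                f"spatial size {(h, w)} must be divisible by 8")
        out1, dec_outs = self.phase1(image)
        gate_source = gt_onehot if gt_onehot is not None else out1
        x2 = phase2_input(image, gate_source)
        out2 = self.phase2(x2, dec_outs)
        final = self.fusion(concat([out1, out2], axis=1)).softmax(axis=1)
        return final, out1, out2

    def predict(self, image: Tensor) -> np.ndarray:
        """Argmax class mask of the final map (ties break to the lowest index)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                final, _, _ = self.forward(image)
        finally:
            self.train(was_training)
        return np.argmax(final.data, axis=1).astype(np.uint8)


# ---- checkpoint I/O ------------------------------------------------------


def save_checkpoint(path, model: GaadUNet, extra: dict | None = None):
    """Single-file .npz checkpoint: parameters + config echo + format version."""
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.cfg),
            "extra": extra or {}}
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[GaadUNet, dict]:
    """Load a checkpoint; validates format version and config compatibility."""
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["__meta__"]))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} unsupported "
                f"(expected {CHECKPOINT_VERSION})")
        cd = meta["config"]
        for k in ("input_size", "encoder1_widths", "encoder2_widths",
                  "decoder_widths", "encoder1_convs", "encoder2_convs",
                  "aspp_rates"):
            cd[k] = tuple(cd[k])
        cfg = ModelConfig(**cd)
        model = GaadUNet(cfg, seed=0)
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        model.load_state_dict(state)
    return model, meta.get("extra", {})
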