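"""The AKU-Net segmentation network.

A four-level U-Net whose encoder follows the VGG16 block layout (3x3
convolutions + ReLU, 2x2 max pooling between blocks, channel widths
doubling from ``base_filters``), whose decoder upsamples with kernel-2
stride-2 transposed convolutions and batch-normalises every convolution,
and whose skip connections are fused by a convolutional LSTM: the
encoder map and the upsampled decoder map are channel-concatenated,
split into an n x m grid of patches, scanned patch-by-patch by a
peephole convLSTM from a zero initial state, and the per-step hidden
maps are reassembled into a feature map that feeds the decoder
convolutions.  A flag swaps the fusion back to plain concatenation to
instantiate the baseline U-Net.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import functional as F

__all__ = [
    "ConfigurationError", "ModelConfig", "ConvLSTMParams",
    "split_to_patches", "reassemble_patches", "convlstm_step",
    "convlstm_fuse", "build_encoder", "build_model", "AKUNet",
]


class ConfigurationError(ValueError):
    """Invalid architecture configuration."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    input_side:
        Side length of the (square) network input, in pixels.  Must be
        divisible by 8 (three 2x2 poolings) and by ``n * 2**(level-1)``
        at every skip level so the patch grid tiles each skip map.
    base_filters:
        Channel width of the first encoder block; deeper blocks double it.
    convs_per_block:
        Convolutions per encoder block (VGG16 uses 2,2,3,3).
    convlstm_grid:
        (n, m) patch grid the fused skip map is split into.
    convlstm_hidden:
        Hidden channels K per skip level; ``None`` means half the
        concatenated width (= the encoder width at that level).
    skip_fusion:
        "convlstm" for the full model, "concat" for the baseline U-Net.
    pretrained_encoder:
        Optional path to a local ``.npz`` of VGG16 encoder kernels; when
        unset the encoder is randomly initialised (never downloads).
    """

    input_side: int = 256
    encoder_blocks: int = 4
    base_filters: int = 64
    convs_per_block: tuple = (2, 2, 3, 3)
    convlstm_grid: tuple = (4, 4)
    convlstm_hidden: tuple | None = None
    skip_fusion: str = "convlstm"
    bn_in_decoder: bool = True
    pretrained_encoder: str | None = None
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.convs_per_block = tuple(self.convs_per_block)
        self.convlstm_grid = tuple(self.convlstm_grid)
        if self.convlstm_hidden is not None:
            self.convlstm_hidden = tuple(self.convlstm_hidden)
        if self.encoder_blocks != 4:
            raise ConfigurationError("encoder_blocks must be 4")
        if len(self.convs_per_block) != 4:
            raise ConfigurationError("convs_per_block must list 4 blocks")
        if self.skip_fusion not in ("convlstm", "concat"):
            raise ConfigurationError(
                f"unknown skip_fusion {self.skip_fusion!r}")
        if self.input_side % 8:
            raise ConfigurationError(
                f"input_side {self.input_side} is not divisible by 8 "
                "(three 2x2 poolings)")
        n, m = self.convlstm_grid
        for level in range(1, 4):  # skip levels carry fusion units
            side = self.input_side >> (level - 1)
            if side % n or side % m:
                raise ConfigurationError(
                    f"convlstm grid {self.convlstm_grid} does not divide the "
                    f"{side}x{side} skip map at level {level}")

    def channels(self, level: int) -> int:
        """Encoder channel width at 1-based level."""
        return min(self.base_filters << (level - 1), 512)

    def hidden(self, level: int) -> int:
        if self.convlstm_hidden is not None:
            return self.convlstm_hidden[level - 1]
        return self.channels(level)

    def skip_shapes(self):
        return [
            (self.input_side >> l, self.input_side >> l, self.channels(l + 1))
            for l in range(4)
        ]

    def to_dict(self):
        d = dict(vars(self))
        d["convs_per_block"] = list(self.convs_per_block)
        d["convlstm_grid"] = list(self.convlstm_grid)
        if self.convlstm_hidden is not None:
            d["convlstm_hidden"] = list(self.convlstm_hidden)
        return d


# ---------------------------------------------------------------------------
# patch grid

def _grid_slices(h, w, grid):
    n, m = grid
    if h % n or w % m:
        raise ValueError(f"grid {grid} does not divide a {h}x{w} map")
    hp, wp = h // n, w // m
    return [(i * hp, (i + 1) * hp, j * wp, (j + 1) * wp)
            for i in range(n) for j in range(m)], (hp, wp)


def split_to_patches(x, grid, order="row-major"):
    """Split a feature map into an n x m grid of patches, scan order
    row-major.  Accepts (h, w, c) arrays or batched (b, h, w, c) tensors;
    the tiling is lossless (see :func:`reassemble_patches`)."""
    if order != "row-major":
        raise ValueError(f"unsupported scan order {order!r}")
    if isinstance(x, nn.Tensor):
        h, w = x.data.shape[1:3]
        slices, _ = _grid_slices(h, w, grid)
        return [F.crop2d(x, r0, r1, c0, c1) for r0, r1, c0, c1 in slices]
    x = np.asarray(x)
    h, w = x.shape[:2]
    slices, _ = _grid_slices(h, w, grid)
    return [x[r0:r1, c0:c1] for r0, r1, c0, c1 in slices]


def reassemble_patches(patches, grid, order="row-major"):
    """Inverse of :func:`split_to_patches` (exact elementwise round-trip)."""
    if order != "row-major":
        raise ValueError(f"unsupported scan order {order!r}")
    n, m = grid
    if len(patches) != n * m:
        raise ValueError(f"expected {n * m} patches, got {len(patches)}")
    arrays = [p.data if isinstance(p, nn.Tensor) else np.asarray(p)
              for p in patches]
    rows = [np.concatenate(arrays[i * m:(i + 1) * m], axis=-2)
            for i in range(n)]
    return np.concatenate(rows, axis=-3)


# ---------------------------------------------------------------------------
# convLSTM public surface

@dataclass
class ConvLSTMParams:
    """Per-gate convLSTM parameters.

    Input kernels map F_l -> K, hidden kernels K -> K (both (k, k, cin,
    cout)); peephole weights have the full spatial shape of the state and
    act elementwise; biases are per-channel.
    """

    w_xi: np.ndarray
    w_xf: np.ndarray
    w_xc: np.ndarray
    w_xo: np.ndarray
    w_hi: np.ndarray
    w_hf: np.ndarray
    w_hc: np.ndarray
    w_ho: np.ndarray
    w_ci: np.ndarray
    w_cf: np.ndarray
    w_co: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden(self):
        return self.w_xi.shape[-1]

    @classmethod
    def from_cell(cls, cell: nn.ConvLSTMCell) -> "ConvLSTMParams":
        k = cell.hidden
        wx, wh, b = cell.wx.data, cell.wh.data, cell.b.data
        return cls(
            w_xi=wx[..., 0:k], w_xf=wx[..., k:2 * k],
            w_xc=wx[..., 2 * k:3 * k], w_xo=wx[..., 3 * k:4 * k],
            w_hi=wh[..., 0:k], w_hf=wh[..., k:2 * k],
            w_hc=wh[..., 2 * k:3 * k], w_ho=wh[..., 3 * k:4 * k],
            w_ci=cell.wci.data, w_cf=cell.wcf.data, w_co=cell.wco.data,
            b_i=b[0:k], b_f=b[k:2 * k], b_c=b[2 * k:3 * k], b_o=b[3 * k:4 * k],
        )

    def to_cell(self) -> nn.ConvLSTMCell:
        hp, wp, k = self.w_ci.shape
        cin = self.w_xi.shape[2]
        ksz = self.w_xi.shape[0]
        cell = nn.ConvLSTMCell(cin, k, (hp, wp), k=ksz,
                               rng=np.random.default_rng(0))
        cell.wx.data = np.concatenate(
            [self.w_xi, self.w_xf, self.w_xc, self.w_xo], axis=-1
        ).astype(np.float32)
        cell.wh.data = np.concatenate(
            [self.w_hi, self.w_hf, self.w_hc, self.w_ho], axis=-1
        ).astype(np.float32)
        cell.wci.data = np.asarray(self.w_ci, dtype=np.float32)
        cell.wcf.data = np.asarray(self.w_cf, dtype=np.float32)
        cell.wco.data = np.asarray(self.w_co, dtype=np.float32)
        cell.b.data = np.concatenate(
            [self.b_i, self.b_f, self.b_c, self.b_o]).astype(np.float32)
        return cell

    @classmethod
    def zeros(cls, cin, hidden, spatial, k=3):
        hp, wp = spatial
        z = lambda *s: np.zeros(s, dtype=np.float32)
        return cls(
            w_xi=z(k, k, cin, hidden), w_xf=z(k, k, cin, hidden),
            w_xc=z(k, k, cin, hidden), w_xo=z(k, k, cin, hidden),
            w_hi=z(k, k, hidden, hidden), w_hf=z(k, k, hidden, hidden),
            w_hc=z(k, k, hidden, hidden), w_ho=z(k, k, hidden, hidden),
            w_ci=z(hp, wp, hidden), w_cf=z(hp, wp, hidden),
            w_co=z(hp, wp, hidden),
            b_i=z(hidden), b_f=z(hidden), b_c=z(hidden), b_o=z(hidden),
        )


def convlstm_step(p, state, params: ConvLSTMParams):
    """One convLSTM update on a single (h, w, c) patch.

    ``state`` is a (hidden, cell) pair of (h, w, K) arrays (pass ``None``
    for the zero initial state); returns the new (hidden, cell) pair.
    """
    p = np.asarray(p, dtype=np.float32)
    cell = params.to_cell()
    if state is None:
        h_prev, c_prev = cell.init_state(1)
    else:
        h, c = state
        if h.shape != c.shape:
            raise ValueError("hidden and cell state shapes differ")
        if h.shape[:2] != p.shape[:2]:
            raise ValueError(
                f"state spatial shape {h.shape[:2]} does not match patch "
                f"{p.shape[:2]}")
        h_prev = nn.Tensor(np.asarray(h, dtype=np.float32)[None])
        c_prev = nn.Tensor(np.asarray(c, dtype=np.float32)[None])
    h_t, c_t = cell.step(nn.Tensor(p[None]), (h_prev, c_prev))
    return h_t.data[0], c_t.data[0]


def convlstm_fuse(x_enc, x_dec_up, grid, params: ConvLSTMParams,
                  order="row-major"):
    """Fuse an encoder map with the upsampled decoder map.

    Channel-concatenates the two maps, splits into ``grid`` patches,
    iterates the convLSTM over the patch sequence from a zero initial
    state, and reassembles each step's hidden output at its grid
    position.  Output has the input spatial shape and K channels.
    """
    x_enc = np.asarray(x_enc, dtype=np.float32)
    x_dec_up = np.asarray(x_dec_up, dtype=np.float32)
    if x_enc.shape[:2] != x_dec_up.shape[:2]:
        raise ValueError("encoder and decoder maps differ in spatial shape")
    fused = np.concatenate([x_enc, x_dec_up], axis=-1)
    patches = split_to_patches(fused, grid, order)
    state = None
    hidden = []
    for p in patches:
        state = convlstm_step(p, state, params)
        hidden.append(state[0])
    return reassemble_patches(hidden, grid, order)


# ---------------------------------------------------------------------------
# network modules

class _EncoderBlock(nn.Module):
    def __init__(self, cin, cout, n_convs, rng):
        self.convs = [nn.Conv2D(cin if i == 0 else cout, cout, rng=rng)
                      for i in range(n_convs)]

    def __call__(self, x):
        for conv in self.convs:
            x = F.relu(conv(x))
        return x


class Encoder(nn.Module):
    """VGG-style four-block encoder; exposes the four skip maps."""

    def __init__(self, config: ModelConfig, rng):
        self.config = config
        self.blocks = []
        cin = 3
        for level in range(1, 5):
            cout = config.channels(level)
            self.blocks.append(
                _EncoderBlock(cin, cout, config.convs_per_block[level - 1], rng))
            cin = cout
        if config.pretrained_encoder:
            self._load_pretrained(config.pretrained_encoder)

    def _load_pretrained(self, path):
        state = np.load(path)
        idx = 0
        for block in self.blocks:
            for conv in block.convs:
                conv.w.data = state[f"w{idx}"].astype(np.float32)
                conv.b.data = state[f"b{idx}"].astype(np.float32)
                idx += 1

    def skip_shapes(self):
        return self.config.skip_shapes()

    def __call__(self, x):
        skips = []
        for i, block in enumerate(self.blocks):
            if i:
                x = F.maxpool2x2(x)
            x = block(x)
            skips.append(x)
        return skips


class _FusionUnit(nn.Module):
    """convLSTM skip fusion at one level (batched, differentiable)."""

    def __init__(self, cin, hidden, map_side, grid, rng):
        n, m = grid
        self.grid = grid
        self.cell = nn.ConvLSTMCell(cin, hidden, (map_side // n, map_side // m),
                                    rng=rng)

    def __call__(self, x_enc, x_dec_up):
        fused = F.concat([x_enc, x_dec_up], axis=-1)
        patches = split_to_patches(fused, self.grid)
        batch = fused.data.shape[0]
        state = self.cell.init_state(batch)
        hidden = []
        for p in patches:
            state = self.cell.step(p, state)
            hidden.append(state[0])
        n, m = self.grid
        rows = [F.concat(hidden[i * m:(i + 1) * m], axis=2) for i in range(n)]
        return F.concat(rows, axis=1)


class _DecoderStage(nn.Module):
    def __init__(self, cin_deep, skip_ch, fuse_ch, cout, map_side, config, rng):
        self.up = nn.ConvTranspose2D(cin_deep, skip_ch, rng=rng)
        self.fusion = None
        if config.skip_fusion == "convlstm":
            hidden = fuse_ch
            self.fusion = _FusionUnit(2 * skip_ch, hidden, map_side,
                                      config.convlstm_grid, rng)
            cin = hidden
        else:
            cin = 2 * skip_ch
        self.conv1 = nn.Conv2D(cin, cout, rng=rng)
        self.conv2 = nn.Conv2D(cout, cout, rng=rng)
        self.use_bn = config.bn_in_decoder
        if self.use_bn:
            self.bn1 = nn.BatchNorm2D(cout)
            self.bn2 = nn.BatchNorm2D(cout)

    def __call__(self, x_deep, x_skip, training):
        up = self.up(x_deep)
        if self.fusion is not None:
            x = self.fusion(x_skip, up)
        else:
            x = F.concat([x_skip, up], axis=-1)
        x = self.conv1(x)
        if self.use_bn:
            x = self.bn1(x, training)
        x = F.relu(x)
        x = self.conv2(x)
        if self.use_bn:
            x = self.bn2(x, training)
        return F.relu(x)


class AKUNet(nn.Module):
    """U-Net with convLSTM-fused skip connections and a sigmoid head."""

    def __init__(self, config: ModelConfig, rng=None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.decoder_stages = []
        for level in (3, 2, 1):  # decode from the 1/8-res bridge upward
            skip_ch = config.channels(level)
            deep_ch = config.channels(level + 1)
            map_side = config.input_side >> (level - 1)
            self.decoder_stages.append(
                _DecoderStage(deep_ch, skip_ch, config.hidden(level), skip_ch,
                              map_side, config, rng))
        self.head = nn.Conv2D(config.channels(1), 1, k=1, rng=rng)

    # -- forward -----------------------------------------------------------
    def forward(self, x, training=False):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 4 or x.data.shape[3] != 3:
            raise ValueError(f"expected (batch, h, w, 3) input, got {x.data.shape}")
        skips = self.encoder(x)
        y = skips[3]
        for stage, level in zip(self.decoder_stages, (3, 2, 1)):
            y = stage(y, skips[level - 1], training)
        return F.sigmoid(self.head(y))

    __call__ = forward

    def predict(self, images, batch_size=8):
        """Probability maps for a (n, h, w, 3) stack (inference mode)."""
        images = np.asarray(images, dtype=np.float32)
        single = images.ndim == 3
        if single:
            images = images[None]
        out = np.empty(images.shape[:3] + (1,), dtype=np.float32)
        for i in range(0, len(images), batch_size):
            out[i:i + batch_size] = self.forward(images[i:i + batch_size]).data
        return out[0] if single else out

    @property
    def is_recurrent(self):
        return self.config.skip_fusion == "convlstm"

    # -- persistence -------------------------------------------------------
    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.state_dict())
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump({"model": self.config.to_dict()}, fh)

    @classmethod
    def load(cls, path):
        path = Path(path)
        with open(path.with_suffix(".yaml")) as fh:
            cfg = ModelConfig(**yaml.safe_load(fh)["model"])
        model = cls(cfg)
        wpath = path if path.exists() else path.with_suffix(".npz")
        with np.load(wpath) as state:
            model.load_state_dict(dict(state))
        return model


def build_encoder(config: ModelConfig, rng=None) -> Encoder:
    """The four-block encoder producing skip maps at full, 1/2, 1/4 and
    1/8 resolution."""
    return Encoder(config, rng or np.random.default_rng(config.seed))


def build_model(config: ModelConfig, rng=None) -> AKUNet:
    return AKUNet(config, rng)


def baseline_config(config: ModelConfig) -> ModelConfig:
    """Same architecture with plain-concatenation skips (baseline U-Net)."""
    return replace(config, skip_fusion="concat")
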