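"""The two 3D segmentation architectures and the measurement head.

``UNet3D``: an encoder of ``n_stages`` stages (two 3x3x3 convolutions + ReLU
+ 2x2x2 max pooling each, channels doubling per stage), a bottleneck, and a
mirrored decoder (2x upsampling + two convolutions) with stage-wise skip
concatenation; a final 1x1x1 convolution emits per-voxel class scores.

``FCN3D``: a VGG-style downsampling path of seven blocks — blocks 1-2 with
two convolutions + pool, blocks 3-5 with three convolutions + pool, blocks
6-7 with a single convolution (+ optional channel dropout) — followed by
1x1x1 score layers and two transposed convolutions that fuse the stride-32
prediction with the stride-16 skip and recover full resolution (FCN-16
style).

Both networks internally zero-pad each input to the nearest
pooling-compatible size and crop the output back, so any input of at least
``2^n_stages`` (U-Net) or 32 (FCN) voxels per axis works.  A regression head
(global average pooling + two dense layers) can be attached in parallel with
the final part of the decoder to output (thickness, height, width) in mm
directly; its parameters form a group separate from the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``base_channels`` 64 corresponds to the reference 3D U-Net design;
    8-16 gives a desk-scale model adequate for phantoms.  ``dropout_rate``
    applies to the U-Net bottleneck when ``unet_dropout`` and to FCN blocks
    6-7 when ``fcn_dropout`` (both placements are plausible readings of the
    protocol; each sits behind its own flag).
    """

    in_channels: int = 1
    n_classes: int = 5
    base_channels: int = 16
    n_stages: int = 4
    dropout_rate: float = 0.1
    unet_dropout: bool = True
    fcn_dropout: bool = False
    upsample: str = "transposed"  # or "nearest"
    head_outputs: int = 3
    head_hidden: int = 32

    def __post_init__(self) -> None:
        if self.n_stages < 1 or self.base_channels < 1:
            raise ValueError("n_stages and base_channels must be >= 1")
        if self.head_outputs != 3:
            raise ValueError("head_outputs must be 3 (thickness, height, width)")
        if self.upsample not in ("transposed", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")


def _pad_to_multiple(x: np.ndarray, mult: int):
    pads = []
    for ax in (2, 3, 4):
        gap = (-x.shape[ax]) % mult
        pads.append((gap // 2, gap - gap // 2))
    if any(a or b for a, b in pads):
        x = np.pad(x, ((0, 0), (0, 0), *pads))
    return x, pads


def _crop(x: np.ndarray, pads) -> np.ndarray:
    (f0, b0), (f1, b1), (f2, b2) = pads
    return x[:, :, f0:x.shape[2] - b0, f1:x.shape[3] - b1, f2:x.shape[4] - b2]


def _uncrop(g: np.ndarray, pads) -> np.ndarray:
    return np.pad(g, ((0, 0), (0, 0), *pads))


class Head:
    """Global average pooling + two dense layers -> 3 measurements (mm)."""

    def __init__(self, cin: int, hidden: int, outputs: int, rng):
        self.gap = nn.GlobalAvgPool()
        self.fc1 = nn.Linear(cin, hidden, rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(hidden, outputs, rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, feature_map, train=True):
        return self.forward_pooled(self.gap.forward(feature_map, train), train)

    def forward_pooled(self, pooled, train=True):
        return self.fc2.forward(self.relu.forward(self.fc1.forward(pooled, train), train), train)

    def backward_pooled(self, g):
        return self.fc1.backward(self.relu.backward(self.fc2.backward(g)))


class _BaseNet:
    """Shared plumbing: parameter groups, head attachment, checkpointing."""

    config: NetConfig
    head: Head | None

    def backbone_params(self) -> list[nn.Param]:
        raise NotImplementedError

    def params(self) -> list[nn.Param]:
        ps = self.backbone_params()
        if self.head is not None:
            ps = ps + self.head.params()
        return ps

    @property
    def head_channels(self) -> int:
        raise NotImplementedError

    def attach_head(self, rng: np.random.Generator | None = None):
        """Attach the measurement regression head (once)."""
        if self.head is not None:
            raise ValueError("head already attached")
        rng = rng or np.random.default_rng(0)
        self.head = Head(self.head_channels, self.config.head_hidden,
                         self.config.head_outputs, rng)
        return self

    def head_params(self) -> list[nn.Param]:
        if self.head is None:
            raise ValueError("no head attached")
        return self.head.params()

    def forward(self, x, train=True):
        raise NotImplementedError

    def forward_with_head(self, x, train=True):
        """Forward pass returning (class scores, 3-vector of measurements)."""
        if self.head is None:
            raise ValueError("no head attached")
        scores = self.forward(x, train)
        measures = self.head.forward(self._head_feature, train)
        return scores, measures

    def pooled_head_feature(self, x) -> np.ndarray:
        """Backbone forward (eval mode), returning the globally averaged
        decoder feature the head consumes — used to train the head with the
        backbone frozen."""
        self.forward(x, train=False)
        return self._head_feature.mean(axis=(2, 3, 4))

    def predict(self, x) -> np.ndarray:
        """Argmax class codes for a (D, H, W) or (N, 1, D, H, W) input."""
        if x.ndim == 3:
            x = x[None, None]
        scores = self.forward(np.asarray(x, dtype=nn.FLOAT), train=False)
        out = scores.argmax(axis=1).astype(np.uint8)
        return out[0] if out.shape[0] == 1 else out

    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, __config__=np.array([repr(asdict(self.config))]),
                 __arch__=np.array([type(self).__name__]),
                 __has_head__=np.array([self.head is not None]), **arrays)

    @classmethod
    def load(cls, path):
        import ast
        data = np.load(path, allow_pickle=False)
        config = NetConfig(**ast.literal_eval(str(data["__config__"][0])))
        arch = str(data["__arch__"][0])
        model = build_unet3d(config) if arch == "UNet3D" else build_fcn3d(config)
        if bool(data["__has_head__"][0]):
            model.attach_head()
        nn.set_state(model.params(), [data[f"p{i}"] for i in range(len(model.params()))])
        return model


class _ConvBlock:
    def __init__(self, cin, cout, n_convs, rng):
        self.layers = []
        c = cin
        for _ in range(n_convs):
            self.layers += [nn.Conv3d(c, cout, 3, rng), nn.ReLU()]
            c = cout

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class UNet3D(_BaseNet):
    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        self.head = None
        rng = np.random.default_rng(seed)
        b, ns = config.base_channels, config.n_stages
        self.enc = []
        cin = config.in_channels
        for s in range(ns):
            self.enc.append(_ConvBlock(cin, b * 2**s, 2, rng))
            cin = b * 2**s
        self.pools = [nn.MaxPool3d(2) for _ in range(ns)]
        self.bottleneck = _ConvBlock(b * 2**(ns - 1), b * 2**ns, 2, rng)
        self.drop = nn.Dropout3d(config.dropout_rate if config.unet_dropout else 0.0,
                                 np.random.default_rng(seed + 1))
        self.ups, self.dec = [], []
        for s in reversed(range(ns)):
            cup = b * 2**(s + 1)
            if config.upsample == "transposed":
                self.ups.append(nn.ConvTranspose3d(cup, b * 2**s, 2, rng))
                cat = b * 2**s * 2
            else:
                self.ups.append(nn.NearestUp(2))
                cat = cup + b * 2**s
            self.dec.append(_ConvBlock(cat, b * 2**s, 2, rng))
        self.final = nn.Conv3d(b, config.n_classes, 1, rng)
        self._head_feature = None

    def backbone_params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for up in self.ups:
            ps += up.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.final.params()
        return ps

    @property
    def head_channels(self):
        return self.config.base_channels

    def forward(self, x, train=True):
        ns = self.config.n_stages
        mult = 2**ns
        for ax, size in zip("DHW", x.shape[2:]):
            if size < mult:
                raise ValueError(f"input {ax} dimension {size} smaller than 2^n_stages={mult}")
        x, self._pads = _pad_to_multiple(np.asarray(x, dtype=nn.FLOAT), mult)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        x = self.drop.forward(x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        self._head_feature = _crop(x, self._pads)
        scores = self.final.forward(x, train)
        return _crop(scores, self._pads)

    def backward(self, g_scores, g_head_feature=None):
        g = self.final.backward(_uncrop(np.asarray(g_scores, dtype=nn.FLOAT), self._pads))
        if g_head_feature is not None:
            g = g + _uncrop(np.asarray(g_head_feature, dtype=nn.FLOAT), self._pads)
        gskips = []
        for blk, up, cs in zip(reversed(self.dec), reversed(self.ups),
                               reversed(self._skip_channels)):
            gcat = blk.backward(g)
            gskips.append(gcat[:, :cs])
            g = up.backward(np.ascontiguousarray(gcat[:, cs:]))
        g = self.drop.backward(g)
        g = self.bottleneck.backward(g)
        # gskips were collected shallowest-first; the encoder unwinds deepest-first
        for blk, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(gskips)):
            g = pool.backward(g)
            g = blk.backward(g + gskip)
        return _crop(g, self._pads)


class FCN3D(_BaseNet):
    N_POOLS = 5

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        self.head = None
        rng = np.random.default_rng(seed)
        b, k = config.base_channels, config.n_classes
        chans = [b, 2 * b, 4 * b, 8 * b, 8 * b]
        convs_per_block = [2, 2, 3, 3, 3]
        self.blocks, self.pools = [], []
        cin = config.in_channels
        for ch, nc in zip(chans, convs_per_block):
            self.blocks.append(_ConvBlock(cin, ch, nc, rng))
            self.pools.append(nn.MaxPool3d(2))
            cin = ch
        rate = config.dropout_rate if config.fcn_dropout else 0.0
        self.block6 = _ConvBlock(cin, 8 * b, 1, rng)
        self.drop6 = nn.Dropout3d(rate, np.random.default_rng(seed + 6))
        self.block7 = _ConvBlock(8 * b, 8 * b, 1, rng)
        self.drop7 = nn.Dropout3d(rate, np.random.default_rng(seed + 7))
        self.score7 = nn.Conv3d(8 * b, k, 1, rng)
        self.score4 = nn.Conv3d(chans[3], k, 1, rng)
        self.up2 = nn.ConvTranspose3d(k, k, 2, rng)
        self.up16 = nn.ConvTranspose3d(k, k, 16, rng)
        self._head_feature = None

    def backbone_params(self):
        ps = []
        for blk in self.blocks:
            ps += blk.params()
        ps += self.block6.params() + self.block7.params()
        ps += self.score7.params() + self.score4.params()
        ps += self.up2.params() + self.up16.params()
        return ps

    @property
    def head_channels(self):
        return self.config.n_classes

    def forward(self, x, train=True):
        mult = 2**self.N_POOLS
        # internal padding brings every axis to a multiple of 2^N_POOLS, so
        # only clearly degenerate inputs are rejected
        for ax, size in zip("DHW", x.shape[2:]):
            if size < 8:
                raise ValueError(f"input {ax} dimension {size} too small for the FCN")
        x, self._pads = _pad_to_multiple(np.asarray(x, dtype=nn.FLOAT), mult)
        feats = []
        for blk, pool in zip(self.blocks, self.pools):
            x = blk.forward(x, train)
            x = pool.forward(x, train)
            feats.append(x)
        x = self.drop6.forward(self.block6.forward(x, train), train)
        x = self.drop7.forward(self.block7.forward(x, train), train)
        s7 = self.score7.forward(x, train)          # stride 32
        s4 = self.score4.forward(feats[3], train)   # stride 16 skip
        fused = self.up2.forward(s7, train) + s4    # stride 16
        # the head reads the fused stride-16 map: the final decoder feature
        # before resolution recovery
        self._fused_shape = fused.shape
        self._head_feature = fused
        out = self.up16.forward(fused, train)
        return _crop(out, self._pads)

    def backward(self, g_scores, g_head_feature=None):
        g = self.up16.backward(_uncrop(np.asarray(g_scores, dtype=nn.FLOAT), self._pads))
        if g_head_feature is not None:
            g = g + g_head_feature
        gs4 = g
        gs7 = self.up2.backward(g)
        g = self.score7.backward(gs7)
        g = self.block6.backward(self.drop6.backward(
            self.block7.backward(self.drop7.backward(g))))
        gskip4 = self.score4.backward(gs4)
        for i, (blk, pool) in enumerate(zip(reversed(self.blocks), reversed(self.pools))):
            if i == 1:  # gradient entering pool4 also carries the skip branch
                g = g + gskip4
            g = pool.backward(g)
            g = blk.backward(g)
        return _crop(g, self._pads)


def build_unet3d(config: NetConfig | None = None, seed: int = 0) -> UNet3D:
    return UNet3D(config or NetConfig(), seed)


def build_fcn3d(config: NetConfig | None = None, seed: int = 0) -> FCN3D:
    return FCN3D(config or NetConfig(), seed)


def attach_head(model: _BaseNet, head_outputs: int = 3,
                rng: np.random.Generator | None = None) -> _BaseNet:
    """Attach the parallel measurement head to a model built by this module."""
    if head_outputs != model.config.head_outputs:
        raise ValueError("head_outputs must match the model config")
    return model.attach_head(rng)
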