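"""3D U-Net with concurrent spatial & channel squeeze-excitation attention.

The network is a standard four-level 3D U-Net (two 3x3x3 conv+ReLU per
level, 2x max-pool down, stride-2 transposed-conv up) whose decoder
applies one scSE attention block to each concatenated skip+upsampled
feature map — four blocks in total. The channel gate ("cSE+") pools the
spatial extent with BOTH a global max pool and a global average pool,
passes each pooled vector through its own small channel-mixing
bottleneck, adds the two branch outputs and squashes with a sigmoid;
the spatial gate ("sSE") is a 1x1x1 convolution to one channel followed
by a sigmoid. The two gated maps are fused by elementwise addition
(default) or maximum.

Everything runs in float32 NumPy on CPU; training is Adam on voxel-wise
categorical cross-entropy, fully reproducible from the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigValueError, InvalidInputShapeError, ShapeMismatchError
from .types import LabeledPair, ProbabilityMap, Volume

AXIS_NAMES = ("H", "W", "S")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` is fixed at 4 (four down- and four up-sampling levels);
    ``base_channels`` doubles at every downsampling. ``se_reduction``
    is the bottleneck ratio r of the channel gate, ``se_fusion`` the
    rule combining the channel- and spatial-gated maps.
    """

    in_channels: int = 1
    num_classes: int = 2
    base_channels: int = 32
    depth: int = 4
    se_reduction: int = 2
    se_fusion: str = "add"
    normalize_input: str = "zscore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth != 4:
            raise ConfigValueError("depth: must be 4 (four down/up-sampling levels)")
        if self.in_channels < 1:
            raise ConfigValueError("in_channels: must be >= 1")
        if self.num_classes < 2:
            raise ConfigValueError("num_classes: must be >= 2")
        if self.base_channels < 1:
            raise ConfigValueError("base_channels: must be >= 1")
        if self.se_reduction < 1:
            raise ConfigValueError("se_reduction: must be >= 1")
        if self.se_fusion not in ("add", "max"):
            raise ConfigValueError("se_fusion: must be 'add' or 'max'")
        if self.normalize_input not in ("zscore", "minmax", "none"):
            raise ConfigValueError("normalize_input: must be 'zscore', 'minmax' or 'none'")


@dataclass
class TrainConfig:
    """Supervised-training hyperparameters (Adam on cross-entropy)."""

    learning_rate: float = 0.0001
    epochs: int = 150
    batch_size: int = 1
    optimizer: str = "Adam"
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigValueError("learning_rate: must be > 0")
        if self.epochs < 0:
            raise ConfigValueError("epochs: must be >= 0")
        if self.batch_size < 1:
            raise ConfigValueError("batch_size: must be >= 1")
        if self.optimizer != "Adam":
            raise ConfigValueError("optimizer: only 'Adam' is supported")
        if self.loss != "cross_entropy":
            raise ConfigValueError("loss: only 'cross_entropy' is supported")


class ConvBlock:
    """Two 3x3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = nn.Conv3d(cin, cout, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(cout, cout, rng)
        self.relu2 = nn.ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(dy))))


class SCSEBlock:
    """scSE attention with a dual max/average-pooled channel gate.

    The channel gate reduces each channel over the whole spatial extent
    with a global max pool and a global average pool in parallel; each
    pooled C-vector goes through its own C -> C/r -> C bottleneck (ReLU
    between and after), the branch outputs are added and a sigmoid maps
    the sum into (0,1)^C. The spatial gate is a 1x1x1 convolution to a
    single channel followed by a sigmoid.
    """

    def __init__(self, channels: int, reduction: int, fusion: str, rng: np.random.Generator):
        self.channels = channels
        hidden = max(1, channels // reduction)
        self.fusion = fusion
        # independent bottlenecks for the max-pool and average-pool branches
        self.max_fc1 = nn.Linear(channels, hidden, rng)
        self.max_fc2 = nn.Linear(hidden, channels, rng)
        self.avg_fc1 = nn.Linear(channels, hidden, rng)
        self.avg_fc2 = nn.Linear(hidden, channels, rng)
        self.sse_conv = nn.Conv3d(channels, 1, rng, kernel=1)
        self._cache = None

    def params(self):
        return (self.max_fc1.params() + self.max_fc2.params()
                + self.avg_fc1.params() + self.avg_fc2.params()
                + self.sse_conv.params())

    # -- gates ---------------------------------------------------------

    def channel_gate(self, x: np.ndarray, _keep_cache: bool = False):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        amax = flat.argmax(axis=1)
        mp = np.take_along_axis(flat, amax[:, None], axis=1)[:, 0]
        ap = flat.mean(axis=1)
        hm = np.maximum(self.max_fc1.forward(mp), 0.0)
        bm = np.maximum(self.max_fc2.forward(hm), 0.0)
        ha = np.maximum(self.avg_fc1.forward(ap), 0.0)
        ba = np.maximum(self.avg_fc2.forward(ha), 0.0)
        gate = nn.sigmoid(bm + ba)
        cache = (x.shape, amax, hm, bm, ha, ba, gate)
        return (gate, cache) if _keep_cache else gate

    def spatial_gate(self, x: np.ndarray, _keep_cache: bool = False):
        pre = self.sse_conv.forward(x)[0]
        gate = nn.sigmoid(pre)
        return (gate, gate) if _keep_cache else gate

    # -- apply ---------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        g, gcache = self.channel_gate(x, _keep_cache=True)
        s, scache = self.spatial_gate(x, _keep_cache=True)
        cset = x * g[:, None, None, None].astype(x.dtype)
        sset = x * s[None].astype(x.dtype)
        if self.fusion == "add":
            y = cset + sset
            mask = None
        else:
            mask = cset >= sset
            y = np.where(mask, cset, sset)
        self._cache = (x, g, s, gcache, scache, mask)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, g, s, gcache, scache, mask = self._cache
        if self.fusion == "add":
            dc, ds_map = dy, dy
        else:
            dc = np.where(mask, dy, 0.0)
            ds_map = np.where(mask, 0.0, dy)
        dx = dc * g[:, None, None, None] + ds_map * s[None]
        dgate = (dc * x).sum(axis=(1, 2, 3))
        dsg = (ds_map * x).sum(axis=0)
        # channel-gate backward
        shape, amax, hm, bm, ha, ba, gate = gcache
        dz = dgate * gate * (1.0 - gate)
        dbm = np.where(bm > 0, dz, 0.0)
        dhm = np.where(hm > 0, self.max_fc2.backward(dbm), 0.0)
        dmp = self.max_fc1.backward(dhm)
        dba = np.where(ba > 0, dz, 0.0)
        dha = np.where(ha > 0, self.avg_fc2.backward(dba), 0.0)
        dap = self.avg_fc1.backward(dha)
        c = shape[0]
        nvox = int(np.prod(shape[1:]))
        dxf = dx.reshape(c, -1)
        np.add.at(dxf, (np.arange(c), amax), dmp.astype(dx.dtype))
        dxf += (dap / nvox)[:, None]
        # spatial-gate backward
        sg = scache
        dpre = (dsg * sg * (1.0 - sg))[None]
        dx += self.sse_conv.backward(dpre.astype(dx.dtype))
        return dx


def cse_plus_gate(fm: np.ndarray, block: SCSEBlock) -> np.ndarray:
    """Channel gate of the scSE block for a (C, H, W, S) feature map."""
    return block.channel_gate(np.asarray(fm, dtype=nn.DTYPE))


def sse_gate(fm: np.ndarray, block: SCSEBlock) -> np.ndarray:
    """Spatial gate of the scSE block for a (C, H, W, S) feature map."""
    return block.spatial_gate(np.asarray(fm, dtype=nn.DTYPE))


def scse_apply(fm: np.ndarray, block: SCSEBlock) -> np.ndarray:
    """Apply the full scSE block (both gates + fusion) to a feature map."""
    return block.forward(np.asarray(fm, dtype=nn.DTYPE))


class SegmentationNetwork:
    """The four-level scSE-UNet; see the module docstring."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2 ** l for l in range(cfg.depth + 1)]
        self.encoders = []
        self.pools = []
        cin = cfg.in_channels
        for l in range(cfg.depth):
            self.encoders.append(ConvBlock(cin, ch[l], rng))
            self.pools.append(nn.MaxPool2())
            cin = ch[l]
        self.bottleneck = ConvBlock(ch[cfg.depth - 1], ch[cfg.depth], rng)
        self.ups = []
        self.scse_blocks = []
        self.decoders = []
        for l in range(cfg.depth - 1, -1, -1):
            self.ups.append(nn.ConvTranspose2(ch[l + 1], ch[l], rng))
            self.scse_blocks.append(
                SCSEBlock(2 * ch[l], cfg.se_reduction, cfg.se_fusion, rng)
            )
            self.decoders.append(ConvBlock(2 * ch[l], ch[l], rng))
        self.final = nn.Conv3d(ch[0], cfg.num_classes, rng, kernel=1)
        self._skip_channels = [ch[l] for l in range(cfg.depth - 1, -1, -1)]

    # -- parameters ----------------------------------------------------

    def parameters(self):
        out = []
        for enc in self.encoders:
            out += enc.params()
        out += self.bottleneck.params()
        for up, blk, dec in zip(self.ups, self.scse_blocks, self.decoders):
            out += up.params() + blk.params() + dec.params()
        out += self.final.params()
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------

    def _forward_logits(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for enc, pool in zip(self.encoders, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, blk, dec, skip in zip(self.ups, self.scse_blocks, self.decoders,
                                      reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=0)
            h = blk.forward(h)
            h = dec.forward(h)
        return self.final.forward(h)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips = []
        # walk decoder stages in reverse build order
        for i in range(len(self.decoders) - 1, -1, -1):
            d = self.decoders[i].backward(d)
            d = self.scse_blocks[i].backward(d)
            c_skip = self._skip_channels[i]
            dskips.append(d[:c_skip])
            d = self.ups[i].backward(d[c_skip:])
        d = self.bottleneck.backward(d)
        dskips.reverse()  # now ordered deepest-first == encoder order reversed
        for i in range(len(self.encoders) - 1, -1, -1):
            d = self.pools[i].backward(d)
            d = d + dskips[len(self.encoders) - 1 - i]
            d = self.encoders[i].backward(d)

    def prepare_input(self, vol: Volume) -> np.ndarray:
        """Validate divisibility and normalize intensities per volume.

        Default normalization is a per-volume z-score (zero mean, unit
        variance), which keeps optimization well-conditioned without
        normalization layers; min-max to [0, 1] and raw pass-through
        are available via ``NetworkConfig.normalize_input``.
        """
        for axis, size in zip(AXIS_NAMES, vol.shape):
            if size % 16 != 0:
                raise InvalidInputShapeError(
                    f"axis {axis} has size {size}, not divisible by 16"
                )
        x = np.asarray(vol.voxels, dtype=np.float64)
        mode = self.cfg.normalize_input
        if mode == "zscore":
            sd = float(x.std())
            x = (x - float(x.mean())) / sd if sd > 0 else np.zeros_like(x)
        elif mode == "minmax":
            lo, hi = float(x.min()), float(x.max())
            x = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
        return x.astype(nn.DTYPE)[None]

    def predict(self, vol: Volume) -> ProbabilityMap:
        logits = self._forward_logits(self.prepare_input(vol))
        return ProbabilityMap(nn.softmax_channels(logits.astype(np.float64)))

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez(path, config=json.dumps(asdict(self.cfg)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationNetwork":
        with np.load(path, allow_pickle=False) as data:
            cfg = NetworkConfig(**json.loads(str(data["config"])))
            net = cls(cfg)
            for i, p in enumerate(net.parameters()):
                p.value[...] = data[f"param_{i}"]
        return net


def build_network(cfg: NetworkConfig) -> SegmentationNetwork:
    """Construct a seeded scSE-UNet from its configuration."""
    return SegmentationNetwork(cfg)


def forward(net: SegmentationNetwork, vol: Volume) -> ProbabilityMap:
    """Run inference; returns per-voxel class probabilities summing to 1."""
    return net.predict(vol)


def count_parameters(net: SegmentationNetwork) -> int:
    return net.num_parameters()


def train_supervised(
    net: SegmentationNetwork,
    pairs: list[LabeledPair],
    tcfg: TrainConfig,
) -> tuple[SegmentationNetwork, list[float]]:
    """Adam training on voxel-wise cross-entropy.

    Pairs are shuffled each epoch with a generator seeded from
    ``tcfg.seed``; the returned history holds one mean loss per epoch.
    ``epochs == 0`` is a no-op returning the untouched network.
    """
    if not pairs:
        raise ValueError("training set is empty")
    for pair in pairs:
        if pair.labels.num_classes > net.cfg.num_classes:
            raise ShapeMismatchError(
                f"pair {pair.volume.id!r} has {pair.labels.num_classes} classes, "
                f"network outputs {net.cfg.num_classes}"
            )
    if tcfg.epochs == 0:
        return net, []
    opt = nn.Adam(net.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    history: list[float] = []
    ncls = net.cfg.num_classes
    for _epoch in range(tcfg.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = order[start:start + tcfg.batch_size]
            opt.zero_grad()
            for idx in batch:
                pair = pairs[idx]
                x = net.prepare_input(pair.volume)
                logits = net._forward_logits(x)
                probs = nn.softmax_channels(logits)
                y = pair.labels.labels
                nvox = y.size
                onehot_p = np.take_along_axis(probs, y[None], axis=0)[0]
                loss = float(-np.log(np.maximum(onehot_p, 1e-12)).mean())
                losses.append(loss)
                dlogits = probs.copy()
                flat = dlogits.reshape(ncls, -1)
                flat[y.reshape(-1), np.arange(nvox)] -= 1.0
                dlogits /= nvox * len(batch)
                net._backward(dlogits.astype(nn.DTYPE))
            opt.step()
        history.append(float(np.mean(losses)))
    return net, history
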