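"""Stage 1: brain localisation and fixed-size cropping.

A regression CNN predicts the tight bounding box of the brain from a
downsampled (factor 0.5) conformed volume as a 6-vector
``[i0, j0, k0, d_i, d_j, d_k]`` (box vertex and edge lengths, in downsampled
voxel units).  Only the predicted box *center* is used downstream: a
fixed-size box (15.2 cm lateral and superior-inferior, 18.4 cm
anterior-posterior at full scale) is placed around it, shifted — never
shrunk — to lie inside the volume, so every cropped volume has the same
shape.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .core_io import LabelMask, Volume
from .geometry import FULL_SCALE, Geometry


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box with half-open extents [start, start+lengths)."""

    start: tuple[int, int, int]
    lengths: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise ValueError("box lengths must be positive")
        if any(s < 0 for s in self.start):
            raise ValueError("box start must be nonnegative")

    @property
    def end(self) -> tuple[int, int, int]:
        return tuple(s + l for s, l in zip(self.start, self.lengths))

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple(s + l / 2.0 for s, l in zip(self.start, self.lengths))

    def as_vector(self) -> np.ndarray:
        return np.array(self.start + self.lengths, dtype=np.float64)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, e) for s, e in zip(self.start, self.end))


@dataclass(frozen=True)
class CropConfig:
    """Fixed crop-box lengths (voxels at 1 mm iso) and the downsampling
    factor applied before the localisation network."""

    fixed_lengths: tuple[int, int, int] = (152, 152, 184)
    downsample_factor: float = 0.5

    @classmethod
    def from_geometry(cls, geometry: Geometry) -> "CropConfig":
        return cls(
            fixed_lengths=tuple(geometry.crop_lengths),
            downsample_factor=geometry.downsample_factor,
        )


@dataclass
class CropTrainConfig:
    """Training hyperparameters for the localisation network.

    ``lr0`` follows the printed schedule constant "10e-4" read literally as
    1e-3 (set ``lr0=1e-4`` for the alternative reading); ``r`` and ``s``
    parameterise the exponential decay lr0 * r**(epoch/s).
    """

    lr0: float = 1e-3
    r: float = 0.92
    s: float = 10.0
    l1: float = 0.01
    l2: float = 0.01
    batch_size: int = 8
    patience: int = 20
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError("r must be in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class CropNetArch:
    """Structural description of the localisation network: 16 convolutional
    layers (spatial reduction only via stride-2 convolutions), two hidden
    dense layers with Swish activations, a linear 6-unit output, no pooling.
    Filter counts and stride placement are configurable."""

    channels: tuple[int, ...]
    strides: tuple[int, ...]
    dense_units: tuple[int, int] = (64, 32)
    use_pooling: bool = False

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")


def default_arch(input_size: int) -> CropNetArch:
    """Default 16-conv architecture for a cubic input of ``input_size``."""
    n_conv = 16
    n_s2 = max(1, int(np.log2(max(input_size, 4) // 2)))
    n_s2 = min(n_s2, n_conv)
    stride_idx = set(
        int(round(x)) for x in np.linspace(0, n_conv - 4, n_s2)
    )
    strides, channels = [], []
    c = 8
    for i in range(n_conv):
        if i in stride_idx:
            strides.append(2)
            if i > 0:
                c = min(c * 2, 32)
        else:
            strides.append(1)
        channels.append(c)
    return CropNetArch(channels=tuple(channels), strides=tuple(strides))


def swish(x):
    """Swish activation: x * sigmoid(x)."""
    x = np.asarray(x, dtype=np.float64)
    out = x / (1.0 + np.exp(-x))
    return out if out.ndim else float(out)


def lr_schedule(epoch: float, cfg: CropTrainConfig) -> float:
    """Exponentially decaying learning rate lr0 * r**(epoch/s)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * cfg.r ** (epoch / cfg.s)


class CropNet:
    """Localisation network: conv stack -> flatten -> dense -> 6-vector."""

    def __init__(
        self,
        arch: CropNetArch,
        input_size: int,
        l1: float = 0.01,
        l2: float = 0.01,
        seed: int = 0,
    ) -> None:
        if arch.use_pooling:
            raise ValueError(
                "pooling layers are not supported: spatial reduction must "
                "use strided convolutions"
            )
        self.arch = arch
        self.input_size = int(input_size)
        self.l1, self.l2 = l1, l2
        rng = np.random.default_rng(seed)
        self.layers: list[nn.Layer] = []
        cin, size = 1, self.input_size
        for c, s in zip(arch.channels, arch.strides):
            self.layers.append(
                nn.Conv3D(cin, c, kernel_size=3, stride=s, l1=l1, l2=l2, rng=rng)
            )
            self.layers.append(nn.Swish())
            cin = c
            size = -(-size // s)
        self.layers.append(nn.Flatten())
        feat = cin * size ** 3
        for u in arch.dense_units:
            self.layers.append(nn.Dense(feat, u, rng=rng))
            self.layers.append(nn.Swish())
            feat = u
        self.layers.append(nn.Dense(feat, 6, rng=rng))

    # -- structural census ------------------------------------------------
    def layer_census(self) -> dict[str, int]:
        counts = {"conv": 0, "dense": 0, "pool": 0}
        for layer in self.layers:
            if isinstance(layer, nn.Conv3D):
                counts["conv"] += 1
            elif isinstance(layer, nn.Dense):
                counts["dense"] += 1
        return counts

    # -- numerics ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def regularization_loss(self) -> float:
        return sum(layer.regularization_loss() for layer in self.layers)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state(self) -> list[list[np.ndarray]]:
        return [layer.state() for layer in self.layers]

    def load_state(self, state) -> None:
        for layer, s in zip(self.layers, state):
            layer.load_state(s)

    def set_weights_zero(self) -> None:
        for p in self.parameters():
            p[...] = 0.0

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, arr in enumerate(layer.state()):
                arrays[f"l{i}_{j}"] = arr
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "arch": dataclasses.asdict(self.arch),
            "input_size": self.input_size,
            "l1": self.l1,
            "l2": self.l2,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CropNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arch_d = meta["arch"]
        arch = CropNetArch(
            channels=tuple(arch_d["channels"]),
            strides=tuple(arch_d["strides"]),
            dense_units=tuple(arch_d["dense_units"]),
            use_pooling=arch_d.get("use_pooling", False),
        )
        model = cls(arch, meta["input_size"], l1=meta["l1"], l2=meta["l2"])
        data = np.load(str(path.with_suffix(".npz")))
        for i, layer in enumerate(model.layers):
            state = []
            j = 0
            while f"l{i}_{j}" in data:
                state.append(data[f"l{i}_{j}"])
                j += 1
            layer.load_state(state)
        return model


def build_cropnet(
    geometry: Geometry = FULL_SCALE,
    arch: CropNetArch | None = None,
    train_cfg: CropTrainConfig | None = None,
    seed: int = 0,
) -> CropNet:
    """Construct the localisation network for a geometry."""
    train_cfg = train_cfg or CropTrainConfig()
    input_size = int(round(geometry.conform_shape[0] * geometry.downsample_factor))
    arch = arch or default_arch(input_size)
    return CropNet(arch, input_size, l1=train_cfg.l1, l2=train_cfg.l2, seed=seed)


def bbox_target(mask: LabelMask) -> BoundingBox:
    """Tightest axis-aligned box containing all non-Unknown voxels."""
    fg = mask.labels != mask.scheme.unknown_id
    if not fg.any():
        raise ValueError("mask contains no non-Unknown voxels")
    idx = np.nonzero(fg)
    start = tuple(int(ax.min()) for ax in idx)
    lengths = tuple(int(ax.max()) - int(ax.min()) + 1 for ax in idx)
    return BoundingBox(start=start, lengths=lengths)


def downsample_volume(v: Volume, factor: float) -> np.ndarray:
    """Spline-resample a conformed volume by ``factor`` (0.5 -> half size)."""
    if factor == 1.0:
        return np.asarray(v.data, dtype=np.float64)
    return ndimage.zoom(np.asarray(v.data, dtype=np.float64), factor, order=3)


def finalize_bbox(
    predicted: np.ndarray, cfg: CropConfig, vol_shape: tuple[int, int, int]
) -> BoundingBox:
    """Place the fixed-size box around the predicted center.

    The 6-vector is in downsampled coordinates; its implied center is
    rescaled by 1/downsample_factor before the fixed box is placed.  The box
    is shifted (never truncated) to lie inside ``vol_shape``.
    """
    predicted = np.asarray(predicted, dtype=np.float64).reshape(6)
    if not np.all(np.isfinite(predicted)):
        raise ValueError("non-finite box prediction")
    L = np.asarray(cfg.fixed_lengths, dtype=np.int64)
    shape = np.asarray(vol_shape, dtype=np.int64)
    if np.any(L > shape):
        raise ValueError("fixed box larger than the volume")
    center = (predicted[:3] + predicted[3:] / 2.0) / cfg.downsample_factor
    start = np.rint(center - L / 2.0).astype(np.int64)
    start = np.clip(start, 0, shape - L)
    return BoundingBox(start=tuple(int(s) for s in start), lengths=tuple(int(l) for l in L))


def crop(obj: Volume | LabelMask, box: BoundingBox):
    """Extract the subarray under ``box`` (no interpolation)."""
    shape = obj.shape
    if any(e > n for e, n in zip(box.end, shape)):
        raise ValueError("box extends beyond the volume")
    if isinstance(obj, LabelMask):
        return LabelMask(labels=obj.labels[box.slices()].copy(), scheme=obj.scheme)
    return Volume(data=obj.data[box.slices()].copy(), spacing=obj.spacing, axcodes=obj.axcodes)


def train_cropnet(
    train_pairs: list[tuple[Volume, BoundingBox]],
    val_pairs: list[tuple[Volume, BoundingBox]],
    cfg: CropTrainConfig | None = None,
    geometry: Geometry = FULL_SCALE,
    arch: CropNetArch | None = None,
    log: list | None = None,
) -> CropNet:
    """Train the localisation network on (conformed volume, box) pairs.

    Optimizes the mean squared error between the predicted and target
    6-vectors (in downsampled coordinates) with Adam under the exponential
    learning-rate decay schedule; early-stops when the validation MSE fails
    to improve for ``patience`` epochs and restores the best weights.
    """
    cfg = cfg or CropTrainConfig()
    if len(train_pairs) < 2 or len(val_pairs) < 1:
        raise ValueError("need >= 2 training and >= 1 validation pairs")
    f = geometry.downsample_factor
    model = build_cropnet(geometry, arch=arch, train_cfg=cfg, seed=cfg.seed)

    def prep(pairs):
        xs = np.stack(
            [downsample_volume(v, f)[None] for v, _ in pairs]
        )  # (N, 1, D, H, W)
        ts = np.stack([b.as_vector() * f for _, b in pairs])
        return xs, ts

    Xtr, Ttr = prep(train_pairs)
    Xva, Tva = prep(val_pairs)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.lr0)

    def val_mse() -> float:
        pred = model.forward(Xva, training=False)
        return float(np.mean((pred - Tva) ** 2))

    best = np.inf
    best_state = model.state()
    stall = 0
    n = len(train_pairs)
    for epoch in range(cfg.max_epochs):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        ep_loss = 0.0
        n_batches = 0
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            xb, tb = Xtr[idx], Ttr[idx]
            model.zero_grad()
            pred = model.forward(xb, training=True)
            diff = pred - tb
            mse = float(np.mean(diff ** 2))
            model.backward(2.0 * diff / diff.size)
            reg = model.regularization_loss()
            opt.step(model.gradients())
            ep_loss += mse + reg
            n_batches += 1
        vl = val_mse()
        if log is not None:
            log.append(
                {"epoch": epoch, "lr": opt.lr, "train_loss": ep_loss / n_batches,
                 "val_mse": vl}
            )
        if vl < best - 1e-12:
            best = vl
            best_state = model.state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.load_state(best_state)
    return model


def predict_box(
    model: CropNet, v: Volume, crop_cfg: CropConfig
) -> BoundingBox:
    """Run the localisation network and finalize the fixed-size box."""
    x = downsample_volume(v, crop_cfg.downsample_factor)[None, None]
    pred = model.forward(x, training=False)[0]
    return finalize_bbox(pred, crop_cfg, v.shape)
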