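"""Stage 2: overlapping-subvolume segmentation.

The cropped volume is split into overlapping subvolumes (half the cropped
extent, sampled at quarter-extent steps: a 3x3x3 = 27 grid at the default
geometry) which are scored one-by-one by an encoder-decoder CNN with
concatenating skip connections, batch normalization, SAME padding and only
strided convolutions for downsampling.  The training objective is a weighted
sum of Focal loss (alpha=4, gamma=2) and the Generalised Dice Loss; at
inference the per-subvolume scores are merged by summing into a full-extent
accumulator and dividing by the per-voxel coverage count, the merged scores
are argmaxed (ties to the lowest class id), and the result is embedded into
the full volume padded with the Unknown label.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .core_io import LabelMask, LabelScheme, Volume
from .cropnet import CropConfig, CropNet, crop, predict_box
from .geometry import FULL_SCALE, Geometry


# ---------------------------------------------------------------------------
# Subvolume grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubvolumeGrid:
    """Start offsets of overlapping subvolumes covering a cropped extent."""

    extent: tuple[int, int, int]
    sub_shape: tuple[int, int, int]
    step: tuple[int, int, int]
    axis_starts: tuple[tuple[int, ...], ...]

    @property
    def starts(self) -> list[tuple[int, int, int]]:
        return [tuple(s) for s in itertools.product(*self.axis_starts)]

    def __len__(self) -> int:
        return int(np.prod([len(a) for a in self.axis_starts]))


def build_grid(
    extent: tuple[int, int, int],
    sub_shape: tuple[int, int, int],
    step: tuple[int, int, int],
) -> SubvolumeGrid:
    """Regular grid of starts 0, step, 2*step, ... with the last start per
    axis forced to ``extent - sub_shape`` so every voxel is covered."""
    axis_starts = []
    for n, sub, st in zip(extent, sub_shape, step):
        if sub > n:
            raise ValueError(f"sub_shape {sub} exceeds extent {n}")
        if st > sub or st < 1:
            raise ValueError("step must be in [1, sub_shape] (overlap or exact tiling)")
        starts = list(range(0, n - sub + 1, st))
        if starts[-1] != n - sub:
            starts.append(n - sub)
        axis_starts.append(tuple(starts))
    return SubvolumeGrid(
        extent=tuple(extent), sub_shape=tuple(sub_shape), step=tuple(step),
        axis_starts=tuple(axis_starts),
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Online augmentation: with probability ``rotate_prob`` rotate volume and
    mask identically by small per-axis angles about an offset center."""

    rotate_prob: float = 0.3
    offset_range_voxels: tuple[int, int] = (-2, 2)
    angle_range_deg: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if not (0 <= self.rotate_prob <= 1):
            raise ValueError("rotate_prob must be in [0, 1]")


def rotation_matrix(angles_deg) -> np.ndarray:
    """Compose per-axis rotations (applied about axes 0, 1, 2 in order)."""
    rot = np.eye(3)
    for axis, a in enumerate(np.deg2rad(np.asarray(angles_deg, dtype=np.float64))):
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        idx = [i for i in range(3) if i != axis]
        m[idx[0], idx[0]], m[idx[0], idx[1]] = c, -s
        m[idx[1], idx[0]], m[idx[1], idx[1]] = s, c
        rot = m @ rot
    return rot


def _rigid_resample(data, rot, center, order, cval):
    inv = rot.T
    offset = center - inv @ center
    return ndimage.affine_transform(
        data, inv, offset=offset, order=order, mode="constant", cval=cval
    )


def augment(
    pair: tuple[Volume, LabelMask],
    cfg: AugmentConfig,
    rng: np.random.Generator | int,
) -> tuple[Volume, LabelMask]:
    """Rotate volume and mask together (intensity trilinear, labels nearest)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vol, mask = pair
    if rng.random() >= cfg.rotate_prob:
        return vol, mask
    lo, hi = cfg.offset_range_voxels
    offsets = rng.integers(lo, hi + 1, 3)
    angles = rng.uniform(*cfg.angle_range_deg, 3)
    rot = rotation_matrix(angles)
    center = (np.asarray(vol.shape) - 1) / 2.0 + offsets
    vdata = _rigid_resample(np.asarray(vol.data, dtype=np.float64), rot, center, 1, 0.0)
    mdata = _rigid_resample(mask.labels, rot, center, 0, mask.scheme.unknown_id)
    return (
        Volume(data=vdata.astype(vol.data.dtype), spacing=vol.spacing, axcodes=vol.axcodes),
        LabelMask(labels=mdata.astype(mask.labels.dtype), scheme=mask.scheme),
    )


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

@dataclass
class SegLossConfig:
    """Focal + Generalised Dice mixture (weights default 1:1)."""

    alpha: float = 4.0
    gamma: float = 2.0
    focal_weight: float = 1.0
    gdl_weight: float = 1.0
    gdl_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.focal_weight < 0 or self.gdl_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.focal_weight == 0 and self.gdl_weight == 0:
            raise ValueError("at least one loss weight must be positive")


def _truth_array(truth) -> np.ndarray:
    if isinstance(truth, LabelMask):
        return truth.labels
    return np.asarray(truth)


def focal_loss(probs: np.ndarray, truth, cfg: SegLossConfig | None = None) -> float:
    """Mean over voxels of -alpha * (1 - p_t)**gamma * log(p_t)."""
    cfg = cfg or SegLossConfig()
    y = _truth_array(truth)
    if probs.shape[1:] != y.shape:
        raise ValueError(f"probs spatial shape {probs.shape[1:]} != truth {y.shape}")
    p_t = np.take_along_axis(probs, y[None].astype(np.int64), axis=0)[0]
    p_t = np.clip(p_t, 1e-12, 1.0)
    return float(np.mean(cfg.alpha * (1.0 - p_t) ** cfg.gamma * (-np.log(p_t))))


def _one_hot(y: np.ndarray, n_classes: int, dtype=np.float64) -> np.ndarray:
    eye = np.eye(n_classes, dtype=dtype)
    return np.moveaxis(eye[y], -1, 0)


def gdl(probs: np.ndarray, truth, eps: float = 1.0) -> float:
    """Generalised Dice Loss with class weights w_l = 1 / (n_l + eps)**2,
    where n_l is the ground-truth voxel count of label l."""
    y = _truth_array(truth)
    if probs.shape[1:] != y.shape:
        raise ValueError(f"probs spatial shape {probs.shape[1:]} != truth {y.shape}")
    C = probs.shape[0]
    onehot = _one_hot(y, C)
    n_l = onehot.reshape(C, -1).sum(axis=1)
    w = 1.0 / (n_l + eps) ** 2
    p = probs.reshape(C, -1)
    t = onehot.reshape(C, -1)
    num = float(np.sum(w * (p * t).sum(axis=1)))
    den = float(np.sum(w * (p + t).sum(axis=1)))
    if den == 0:
        return 0.0
    return 1.0 - 2.0 * num / den


def seg_loss(probs: np.ndarray, truth, cfg: SegLossConfig | None = None) -> float:
    """Weighted sum of Focal loss and Generalised Dice Loss."""
    cfg = cfg or SegLossConfig()
    return cfg.focal_weight * focal_loss(probs, truth, cfg) + cfg.gdl_weight * gdl(
        probs, truth, cfg.gdl_eps
    )


def _softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _seg_loss_and_grad(
    logits: np.ndarray, truth: np.ndarray, cfg: SegLossConfig
) -> tuple[float, np.ndarray]:
    """Batched loss and d(loss)/d(logits); logits (N, C, D, H, W).

    Computation runs in the dtype of ``logits`` (float32 from the packaged
    networks; float64 inputs keep full precision, e.g. for gradient checks).
    """
    N, C = logits.shape[:2]
    probs = _softmax(logits, axis=1)
    onehot = np.stack([_one_hot(truth[i], C, dtype=probs.dtype) for i in range(N)])
    dL_dp = np.zeros_like(probs)
    total = 0.0
    V = int(np.prod(truth.shape[1:]))

    if cfg.focal_weight > 0:
        p_t = (probs * onehot).sum(axis=1)
        p_t = np.clip(p_t, 1e-12, 1.0)
        one_m = 1.0 - p_t
        total += cfg.focal_weight * float(
            np.mean(cfg.alpha * one_m ** cfg.gamma * (-np.log(p_t)))
        )
        # d/dp [-a(1-p)^g ln p] = a*g*(1-p)^(g-1)*ln p - a*(1-p)^g / p
        if cfg.gamma == 0:
            dfocal = -cfg.alpha / p_t
        else:
            dfocal = cfg.alpha * (
                cfg.gamma * one_m ** (cfg.gamma - 1) * np.log(p_t) - one_m ** cfg.gamma / p_t
            )
        dL_dp += cfg.focal_weight * onehot * (dfocal / (N * V))[:, None]

    if cfg.gdl_weight > 0:
        for i in range(N):
            p = probs[i].reshape(C, -1)
            t = onehot[i].reshape(C, -1)
            n_l = t.sum(axis=1)
            w = 1.0 / (n_l + cfg.gdl_eps) ** 2
            A = float(np.sum(w * (p * t).sum(axis=1)))
            B = float(np.sum(w * (p + t).sum(axis=1)))
            if B == 0:
                continue
            total += cfg.gdl_weight * (1.0 - 2.0 * A / B) / N
            # dL/dp_lv = -2 (w_l y_lv B - A w_l) / B^2
            gp = (-2.0 * (w[:, None] * t * B - A * w[:, None]) / B ** 2)
            dL_dp[i] += cfg.gdl_weight * gp.reshape(probs[i].shape) / N

    # Chain through softmax: dz = p * (g - sum_c p_c g_c)
    inner = (dL_dp * probs).sum(axis=1, keepdims=True)
    dlogits = probs * (dL_dp - inner)
    return total, dlogits


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegNetArch:
    """Encoder-decoder with two stride-2 reductions, concatenating skip
    connections, batch norm after every hidden convolution, no pooling."""

    n_classes: int
    base_channels: int = 8
    use_pooling: bool = False


class SegNet:
    """U-Net-style subvolume segmentation network."""

    def __init__(self, arch: SegNetArch, seed: int = 0) -> None:
        if arch.use_pooling:
            raise ValueError(
                "pooling layers are not supported: spatial reduction must "
                "use strided convolutions"
            )
        self.arch = arch
        rng = np.random.default_rng(seed)
        b = arch.base_channels

        def block(cin, cout, stride=1):
            return (
                nn.Conv3D(cin, cout, 3, stride=stride, rng=rng),
                nn.BatchNorm(cout),
                nn.ReLU(),
            )

        self.enc1a = block(1, b)
        self.enc1b = block(b, b)
        self.down1 = block(b, 2 * b, stride=2)
        self.enc2 = block(2 * b, 2 * b)
        self.down2 = block(2 * b, 4 * b, stride=2)
        self.bottom = block(4 * b, 4 * b)
        self.up1 = nn.Upsample3D()
        self.upc1 = block(4 * b, 2 * b)
        self.dec1 = block(4 * b, 2 * b)  # after concat with enc2 output
        self.up2 = nn.Upsample3D()
        self.upc2 = block(2 * b, b)
        self.dec2 = block(2 * b, b)  # after concat with enc1b output
        self.out_conv = nn.Conv3D(b, arch.n_classes, kernel_size=1, rng=rng)

        self._blocks = [
            self.enc1a, self.enc1b, self.down1, self.enc2, self.down2,
            self.bottom, self.upc1, self.dec1, self.upc2, self.dec2,
        ]
        self._all_layers: list[nn.Layer] = [
            layer for blk in self._blocks for layer in blk
        ] + [self.up1, self.up2, self.out_conv]

    # -- structural census -------------------------------------------------
    def layer_census(self) -> dict[str, int]:
        conv = sum(isinstance(l, nn.Conv3D) for l in self._all_layers)
        bn = sum(isinstance(l, nn.BatchNorm) for l in self._all_layers)
        return {"conv": conv, "batchnorm": bn, "pool": 0, "skip_connections": 2}

    @staticmethod
    def _fwd(blk, x, training):
        for layer in blk:
            x = layer.forward(x, training=training)
        return x

    @staticmethod
    def _bwd(blk, d):
        for layer in reversed(blk):
            d = layer.backward(d)
        return d

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        t = training
        s1 = self._fwd(self.enc1b, self._fwd(self.enc1a, x, t), t)
        s2 = self._fwd(self.enc2, self._fwd(self.down1, s1, t), t)
        z = self._fwd(self.bottom, self._fwd(self.down2, s2, t), t)
        self.up1.target_shape = s2.shape[2:]
        u1 = self._fwd(self.upc1, self.up1.forward(z, t), t)
        d1 = self._fwd(self.dec1, np.concatenate([u1, s2], axis=1), t)
        self.up2.target_shape = s1.shape[2:]
        u2 = self._fwd(self.upc2, self.up2.forward(d1, t), t)
        d2 = self._fwd(self.dec2, np.concatenate([u2, s1], axis=1), t)
        self._split1 = u1.shape[1]
        self._split2 = u2.shape[1]
        return self.out_conv.forward(d2, training=t)

    def backprop(self, dout: np.ndarray) -> None:
        """Backward pass; skip-connection gradients are added where the
        encoder activations branch (after enc2 and enc1b)."""
        d = self.out_conv.backward(dout)
        d = self._bwd(self.dec2, d)
        du2, dskip1 = d[:, : self._split2], d[:, self._split2 :]
        d = self.up2.backward(self._bwd(self.upc2, du2))
        d = self._bwd(self.dec1, d)
        du1, dskip2 = d[:, : self._split1], d[:, self._split1 :]
        d = self.up1.backward(self._bwd(self.upc1, du1))
        d = self._bwd(self.down2, self._bwd(self.bottom, d))
        d = d + dskip2
        d = self._bwd(self.down1, self._bwd(self.enc2, d))
        d = d + dskip1
        d = self._bwd(self.enc1a, self._bwd(self.enc1b, d))

    def zero_grad(self) -> None:
        for layer in self._all_layers:
            layer.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers for g in layer.grads]

    def state(self):
        return [layer.state() for layer in self._all_layers]

    def load_state(self, state) -> None:
        for layer, s in zip(self._all_layers, state):
            layer.load_state(s)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self._all_layers):
            for j, arr in enumerate(layer.state()):
                arrays[f"l{i}_{j}"] = arr
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(
            json.dumps(dataclasses.asdict(self.arch), indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SegNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(SegNetArch(**meta))
        data = np.load(str(path.with_suffix(".npz")))
        for i, layer in enumerate(model._all_layers):
            state, j = [], 0
            while f"l{i}_{j}" in data:
                state.append(data[f"l{i}_{j}"])
                j += 1
            if state:
                layer.load_state(state)
        return model


def build_segnet(
    n_classes: int, base_channels: int = 8, seed: int = 0, use_pooling: bool = False
) -> SegNet:
    return SegNet(
        SegNetArch(n_classes=n_classes, base_channels=base_channels, use_pooling=use_pooling),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    """Training hyperparameters for the segmentation network.  The RMSprop
    learning rate is an implementation choice (the mini-batch size of 2 and
    the patience of 25 epochs are the documented defaults)."""

    lr: float = 1e-3
    batch_size: int = 2
    patience: int = 25
    max_epochs: int = 100
    base_channels: int = 8
    seed: int = 0
    loss: SegLossConfig = field(default_factory=SegLossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)


def _grid_subvolumes(vol: np.ndarray, labels: np.ndarray, grid: SubvolumeGrid):
    subs = []
    ss = grid.sub_shape
    for st in grid.starts:
        sl = tuple(slice(a, a + b) for a, b in zip(st, ss))
        subs.append((vol[sl], labels[sl]))
    return subs


def train_segnet(
    train_pairs: list[tuple[Volume, LabelMask]],
    val_pairs: list[tuple[Volume, LabelMask]],
    cfg: SegTrainConfig | None = None,
    geometry: Geometry = FULL_SCALE,
    n_classes: int | None = None,
    log: list | None = None,
) -> SegNet:
    """Train the subvolume segmentation network on cropped pairs.

    Each epoch iterates over the grid subvolumes of the (online-augmented)
    cropped pairs in mini-batches, optimizing the Focal+GDL objective with
    RMSprop; early-stops on the validation loss with the configured patience
    and restores the best weights.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SegTrainConfig()
    if len(train_pairs) < 2 or len(val_pairs) < 1:
        raise ValueError("need >= 2 training and >= 1 validation cropped pairs")
    if n_classes is None:
        n_classes = train_pairs[0][1].scheme.n_classes
    grid = build_grid(train_pairs[0][0].shape, geometry.sub_shape, geometry.step)
    model = build_segnet(n_classes, base_channels=cfg.base_channels, seed=cfg.seed)
    opt = nn.RMSprop(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)

    val_subs = []
    for vol, mask in val_pairs:
        val_subs.extend(
            _grid_subvolumes(np.asarray(vol.data, np.float64), mask.labels, grid)
        )

    def val_loss() -> float:
        losses = []
        for i0 in range(0, len(val_subs), 4):
            chunk = val_subs[i0 : i0 + 4]
            xb = np.stack([c[0] for c in chunk])[:, None]
            yb = np.stack([c[1] for c in chunk])
            logits = model.forward(xb, training=False)
            loss, _ = _seg_loss_and_grad(logits, yb, cfg.loss)
            losses.append(loss * len(chunk))
        return float(np.sum(losses) / len(val_subs))

    best = np.inf
    best_state = model.state()
    stall = 0
    for epoch in range(cfg.max_epochs):
        subs = []
        for vol, mask in train_pairs:
            av, am = augment((vol, mask), cfg.augment, rng)
            subs.extend(
                _grid_subvolumes(np.asarray(av.data, np.float64), am.labels, grid)
            )
        order = rng.permutation(len(subs))
        ep_loss, n_batches = 0.0, 0
        for i0 in range(0, len(order), cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            xb = np.stack([subs[i][0] for i in idx])[:, None]
            yb = np.stack([subs[i][1] for i in idx])
            model.zero_grad()
            logits = model.forward(xb, training=True)
            loss, dlogits = _seg_loss_and_grad(logits, yb, cfg.loss)
            model.backprop(dlogits)
            opt.step(model.gradients())
            ep_loss += loss
            n_batches += 1
        vl = val_loss()
        if log is not None:
            log.append(
                {"epoch": epoch, "train_loss": ep_loss / n_batches, "val_loss": vl}
            )
        if vl < best - 1e-12:
            best, best_state, stall = vl, model.state(), 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.load_state(best_state)
    return model


# ---------------------------------------------------------------------------
# Merging and inference
# ---------------------------------------------------------------------------

@dataclass
class ScoreVolume:
    """Per-voxel class scores over the cropped extent plus the number of
    subvolumes that contributed to each voxel."""

    scores: np.ndarray  # (C, D, H, W)
    coverage: np.ndarray  # (D, H, W), int

    def argmax_labels(self) -> np.ndarray:
        """Merged labels; argmax ties break to the lowest class id."""
        return np.argmax(self.scores, axis=0).astype(np.int32)


def merge_predictions(
    sub_scores: list[tuple[tuple[int, int, int], np.ndarray]],
    grid: SubvolumeGrid,
    extent: tuple[int, int, int] | None = None,
) -> ScoreVolume:
    """Sum per-subvolume scores into a full-extent accumulator and normalize
    by the per-voxel coverage count."""
    extent = tuple(extent or grid.extent)
    expected = set(grid.starts)
    got = set(tuple(s) for s, _ in sub_scores)
    if got != expected:
        missing = sorted(expected - got)
        raise ValueError(f"missing score arrays for subvolume starts {missing}")
    C = sub_scores[0][1].shape[0]
    ss = grid.sub_shape
    acc = np.zeros((C,) + extent, dtype=np.float64)
    cov = np.zeros(extent, dtype=np.int32)
    for start, arr in sub_scores:
        if arr.shape != (C,) + tuple(ss):
            raise ValueError(f"score array at {start} has shape {arr.shape}")
        sl = tuple(slice(a, a + b) for a, b in zip(start, ss))
        acc[(slice(None),) + sl] += arr
        cov[sl] += 1
    if not (cov >= 1).all():
        raise ValueError("coverage hole: some voxels belong to no subvolume")
    return ScoreVolume(scores=acc / cov, coverage=cov)


def score_subvolumes(
    seg_model: SegNet, cropped: np.ndarray, grid: SubvolumeGrid, batch: int = 4
) -> list[tuple[tuple[int, int, int], np.ndarray]]:
    """Run the segmentation network over all grid subvolumes (eval mode)."""
    starts = grid.starts
    ss = grid.sub_shape
    out = []
    for i0 in range(0, len(starts), batch):
        chunk = starts[i0 : i0 + batch]
        xb = np.stack(
            [cropped[tuple(slice(a, a + b) for a, b in zip(st, ss))] for st in chunk]
        )[:, None]
        logits = seg_model.forward(xb, training=False)
        for st, sc in zip(chunk, logits):
            out.append((tuple(st), sc))
    return out


def predict(
    v: Volume,
    crop_model: CropNet,
    seg_model: SegNet,
    geometry: Geometry = FULL_SCALE,
    scheme: LabelScheme | None = None,
    pre_conformed: bool = False,
) -> LabelMask:
    """Full inference: conform, normalize, crop via the predicted fixed-size
    box, score overlapping subvolumes, merge, argmax, and pad the cropped
    prediction back into the full extent with the Unknown label."""
    from .core_io import conform, default_scheme, normalize_intensity

    scheme = scheme or default_scheme()
    if not pre_conformed:
        v = conform(v, geometry)
    v = normalize_intensity(v)
    crop_cfg = CropConfig.from_geometry(geometry)
    box = predict_box(crop_model, v, crop_cfg)
    cropped = crop(v, box)
    grid = build_grid(cropped.shape, geometry.sub_shape, geometry.step)
    sub_scores = score_subvolumes(seg_model, np.asarray(cropped.data, np.float64), grid)
    merged = merge_predictions(sub_scores, grid)
    labels = np.full(v.shape, scheme.unknown_id, dtype=np.int32)
    labels[box.slices()] = merged.argmax_labels()
    return LabelMask(labels=labels, scheme=scheme)
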