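"""3D fully-convolutional dense-block UNET for per-voxel binding prediction.

The network follows the UNET encoder/decoder layout: the encoder halves the
spatial resolution between levels with average pooling, the decoder doubles
it back with nearest-neighbour upsampling, and skip connections concatenate
encoder features into the decoder at matching resolution, so the output heat
map has exactly the input's spatial shape.  Every block is DenseNet-style:
four convolution+MISH layers where layer k sees the block input concatenated
with all previous layer outputs, followed by a 1x1 transition convolution
that bounds the channel growth.  The head is a single-channel sigmoid.

Training minimises mean per-voxel binary cross-entropy; a constant
equal-probability predictor scores ln 2 = 0.69315 regardless of class
balance, which is the natural "knows nothing" baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import autograd as ag
from .autograd import Tensor
from .featurize import BindingMask, VoxelGrid, enumerate_rotations, rotate_grid

__all__ = [
    "ModelConfig", "TrainConfig", "DenseUNet3D", "mish", "bce_loss",
    "split_dataset", "train", "predict", "predict_rotation_average",
    "save_checkpoint", "load_checkpoint",
]

#: Clamp keeping probabilities away from {0, 1} inside the log.
BCE_EPS = 1e-7


def mish(x):
    """MISH activation, ``x * tanh(softplus(x))``, elementwise on numbers or arrays."""
    x = np.asarray(x, dtype=float)
    out = x * np.tanh(np.logaddexp(0.0, x))
    return out if out.ndim else float(out)


def bce_loss(pred, mask) -> float:
    """Mean binary cross-entropy between probabilities and {0,1} labels.

    Probabilities are clamped to ``[BCE_EPS, 1 - BCE_EPS]``.  Accepts plain
    arrays or the HeatMap/BindingMask wrapper types.
    """
    p = np.asarray(getattr(pred, "values", pred), dtype=float)
    y = np.asarray(getattr(mask, "values", mask), dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"bce_loss: prediction {p.shape} vs mask {y.shape}")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class ModelConfig:
    n_levels: int = 3
    layers_per_block: int = 4   # fixed by the architecture
    growth_channels: int = 16
    block_channels: int = 32    # transition (1x1) output width
    pool_factor: int = 2
    in_channels: int = 17
    out_channels: int = 1
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers_per_block != 4:
            raise ValueError("dense blocks have exactly 4 layers")
        if self.n_levels < 1:
            raise ValueError("need at least one level")


@dataclass
class TrainConfig:
    split_ratio: float = 0.9
    optimizer: str = "adam"      # "adam", "adamw" or "ranger" (adamw + lookahead)
    learning_rate: float = 3e-3
    weight_decay: float = 0.0
    steps: int = 200
    batch_size: int = 2
    log_interval: int = 10
    lookahead_k: int = 6
    lookahead_alpha: float = 0.5
    max_grid_voxels: int | None = None
    restore_best: bool = True
    seed: int = 0


class DenseUNet3D:
    """Dense-block UNET over 17-channel one-hot voxel grids."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(self.config.seed)
        self._build()

    # -- construction -------------------------------------------------

    def _add_conv(self, name: str, cin: int, cout: int, k: int) -> None:
        std = np.sqrt(2.0 / (cin * k**3))
        w = self._rng.normal(0.0, std, size=(cout, cin, k, k, k))
        self.params[f"{name}.w"] = Tensor(w.astype(np.float32))
        self.params[f"{name}.b"] = Tensor(np.zeros(cout, dtype=np.float32))
        for suffix in ("w", "b"):
            self.params[f"{name}.{suffix}"].requires_grad = True

    def _add_block(self, name: str, cin: int) -> int:
        c = self.config
        ch = cin
        for k in range(c.layers_per_block):
            self._add_conv(f"{name}.l{k}", ch, c.growth_channels, c.kernel_size)
            ch += c.growth_channels
        self._add_conv(f"{name}.t", ch, c.block_channels, 1)
        return c.block_channels

    def _build(self) -> None:
        c = self.config
        ch = self._add_block("enc0", c.in_channels)
        for lvl in range(1, c.n_levels):
            ch = self._add_block(f"enc{lvl}", ch)
        ch = self._add_block("dec_bottom", ch)
        for lvl in range(c.n_levels - 2, -1, -1):
            ch = self._add_block(f"dec{lvl}", ch + c.block_channels)
        self._add_conv("head", ch, c.out_channels, 1)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    # -- forward -------------------------------------------------------

    def _conv(self, name: str, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _block(self, name: str, x: Tensor) -> Tensor:
        feats = [x]
        for k in range(self.config.layers_per_block):
            y = ag.mish(self._conv(f"{name}.l{k}", feats[0] if len(feats) == 1 else ag.concat(feats)))
            feats.append(y)
        return ag.mish(self._conv(f"{name}.t", ag.concat(feats)))

    def forward(self, x: np.ndarray) -> Tensor:
        """Channel-first ``(C, X, Y, Z)`` input -> logits Tensor ``(1, X, Y, Z)``."""
        c = self.config
        if x.ndim != 4 or x.shape[0] != c.in_channels:
            raise ValueError(
                f"expected ({c.in_channels}, X, Y, Z) input, got shape {x.shape}"
            )
        spatial = x.shape[1:]
        mult = c.pool_factor ** (c.n_levels - 1)
        padded = tuple(int(np.ceil(s / mult) * mult) for s in spatial)
        t = Tensor(x.astype(np.float32))
        if padded != spatial:
            t = ag.pad_spatial(t, padded)
        skips = []
        h = self._block("enc0", t)
        skips.append(h)
        for lvl in range(1, c.n_levels):
            h = self._block(f"enc{lvl}", ag.avg_pool3d(h, c.pool_factor))
            skips.append(h)
        h = self._block("dec_bottom", h)
        for lvl in range(c.n_levels - 2, -1, -1):
            h = ag.upsample_nearest3d(h, c.pool_factor)
            h = self._block(f"dec{lvl}", ag.concat([h, skips[lvl]]))
        logits = self._conv("head", h)
        if padded != spatial:
            logits = ag.crop_spatial(logits, spatial)
        return logits

    # -- state ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint is missing parameter {k!r}")
            if state[k].shape != p.data.shape:
                raise ValueError(f"parameter {k!r}: shape mismatch")
            p.data = state[k].astype(np.float32).copy()


class _AdamFamily:
    """Adam / AdamW with optional lookahead slow weights ("ranger" mode)."""

    def __init__(self, params: list[Tensor], tc: TrainConfig):
        self.params = params
        self.lr = tc.learning_rate
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.weight_decay = tc.weight_decay
        if tc.optimizer == "ranger" and tc.weight_decay == 0.0:
            self.weight_decay = 1e-4
        self.decoupled = tc.optimizer in ("adamw", "ranger")
        self.lookahead = tc.optimizer == "ranger"
        self.k, self.alpha = tc.lookahead_k, tc.lookahead_alpha
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.slow = [p.data.copy() for p in params] if self.lookahead else None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.weight_decay and self.decoupled:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update
        if self.lookahead and self.t % self.k == 0:
            for i, p in enumerate(self.params):
                self.slow[i] += self.alpha * (p.data - self.slow[i])
                p.data = self.slow[i].copy()


def split_dataset(
    complex_ids: list[str],
    ratio: float = 0.9,
    max_grid_voxels: int | None = None,
    seed: int = 0,
    grid_voxels: dict[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Deterministic 9:1 train/validation split by complex.

    All rotations of a complex stay on one side by construction (the split
    operates on complex ids).  Complexes whose grids exceed
    ``max_grid_voxels`` are forced into validation regardless of the draw.
    """
    ids = list(complex_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 complexes to split")
    oversized = []
    if max_grid_voxels is not None and grid_voxels is not None:
        oversized = [i for i in ids if grid_voxels.get(i, 0) > max_grid_voxels]
    rest = [i for i in ids if i not in oversized]
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(rest)))
    rest = [rest[i] for i in order]
    n_val = max(1, int(round(len(ids) * (1.0 - ratio))))
    n_val_rest = max(0, n_val - len(oversized))
    val = sorted(oversized + rest[:n_val_rest])
    train_ids = sorted(rest[n_val_rest:])
    if not train_ids:
        raise ValueError("split left no training complexes")
    return train_ids, val


def _to_chw(grid) -> np.ndarray:
    """VoxelGrid or (X, Y, Z, C) array -> channel-first float32."""
    arr = np.asarray(getattr(grid, "values", grid), dtype=np.float32)
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D one-hot grid, got shape {arr.shape}")
    return np.ascontiguousarray(arr.transpose(3, 0, 1, 2))


def _to_mask(mask) -> np.ndarray:
    return np.asarray(getattr(mask, "values", mask), dtype=np.float32)[None]


def _dataset_loss(model: DenseUNet3D, samples) -> float:
    total = 0.0
    for g, m in samples:
        logits = model.forward(_to_chw(g))
        total += float(ag.bce_with_logits(logits, _to_mask(m)).data)
    return total / len(samples)


def train(
    model: DenseUNet3D,
    train_set,
    val_set=None,
    tc: TrainConfig | None = None,
):
    """Seeded SGD loop over (grid, mask) pairs.

    Returns ``(model, history)`` where history is a list of dicts with keys
    ``step``, ``train_bce`` and ``val_bce``.  The best-validation weights are
    checkpointed and (by default) restored on return.
    """
    tc = tc or TrainConfig()
    train_set = list(train_set)
    if not train_set:
        raise ValueError("empty training set")
    val_set = list(val_set) if val_set else []
    prepared = [(_to_chw(g), _to_mask(m)) for g, m in train_set]
    params = list(model.params.values())
    opt = _AdamFamily(params, tc)
    rng = np.random.default_rng(tc.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    running = []
    for step in range(1, tc.steps + 1):
        idx = rng.choice(len(prepared), size=min(tc.batch_size, len(prepared)), replace=False)
        for p in params:
            p.zero_grad()
        batch_loss = 0.0
        for i in idx:
            x, y = prepared[i]
            loss = ag.bce_with_logits(model.forward(x), y)
            loss.backward()
            batch_loss += float(loss.data)
        nb = len(idx)
        for p in params:
            if p.grad is not None:
                p.grad /= nb
        opt.step()
        running.append(batch_loss / nb)
        if step % tc.log_interval == 0 or step == tc.steps:
            val = _dataset_loss(model, val_set) if val_set else float("nan")
            history.append(
                {"step": step, "train_bce": float(np.mean(running)), "val_bce": val}
            )
            running = []
            if val_set and val < best_val:
                best_val = val
                best_state = model.state_dict()
    if tc.restore_best and best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def predict(model: DenseUNet3D, grid) -> np.ndarray:
    """Heat map of per-voxel binding probabilities, same spatial shape as input."""
    logits = model.forward(_to_chw(grid))
    return expit(logits.data[0]).astype(np.float64)


def predict_rotation_average(model: DenseUNet3D, grid: VoxelGrid) -> np.ndarray:
    """Average the heat map over the 24 cubic orientations.

    Each orientation is predicted in its rotated frame and de-rotated with
    the inverse (transpose) matrix before averaging.
    """
    acc = np.zeros(grid.spec.shape)
    rots = enumerate_rotations()
    for r in rots:
        gr = rotate_grid(grid, r)
        h = predict(model, gr)
        hm = BindingMask(spec=gr.spec, values=h.astype(np.float32))
        back = rotate_grid(hm, r.T)
        acc += back.values
    return acc / len(rots)


def save_checkpoint(model: DenseUNet3D, history, path: str | Path) -> Path:
    path = Path(path)
    meta = json.dumps({"config": asdict(model.config)})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **model.state_dict())
    if history is not None:
        import csv

        with path.with_suffix(".log.csv").open("w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["step", "train_bce", "val_bce"])
            wr.writeheader()
            wr.writerows(history)
    return path


def load_checkpoint(path: str | Path) -> DenseUNet3D:
    path = Path(path)
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    model = DenseUNet3D(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model
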