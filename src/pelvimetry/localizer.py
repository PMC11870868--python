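"""3D U-Net heatmap regression: training, early stopping, inference.

The localizer maps a preprocessed sagittal volume to five heatmaps and
decodes their peaks into physical landmark coordinates. Training
minimizes the MSE between predicted and Gaussian target heatmaps on
randomly sampled patches (landmark-biased so the rare foreground signal
appears in most batches), with best-validation-epoch model selection
and early stopping.

Defaults mirror the clinical-scale regime (lr 1e-4, batch 32, patch
128 x 128 x 16, 500 epochs, patience 50); :meth:`LocalizerConfig.tiny`
is a CPU-scale preset for phantom experiments and tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DataError, InvalidMetadataError
from .geometry import LANDMARK_LABELS, LandmarkSet
from .heatmap import HeatmapConfig, HeatmapStack, decode_heatmaps, make_heatmap_targets
from .nn import Adam, UNet3D, mse_loss
from .preprocess import PreprocessConfig, VolumeGrid, preprocess_volume


@dataclass(frozen=True)
class LocalizerConfig:
    """Hyperparameters of the heatmap-regression network and its training."""

    learning_rate: float = 1e-4
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    batch_size: int = 32
    patch_size: Tuple[int, int, int] = (128, 128, 16)
    max_epochs: int = 500
    early_stop_patience: int = 50
    base_channels: int = 8
    depth: int = 3
    steps_per_epoch: int = 100
    centered_fraction: float = 0.7
    min_slice_pool: int = 8
    random_seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience >= self.max_epochs:
            raise ConfigError("early-stop patience must be < max_epochs")
        if min(self.patch_size) < 2 or self.batch_size < 1:
            raise ConfigError("invalid patch or batch size")
        if not (0.0 <= self.centered_fraction <= 1.0):
            raise ConfigError("centered_fraction must be in [0, 1]")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "LocalizerConfig":
        """CPU-scale preset used for phantom studies and tests."""
        kwargs = dict(
            learning_rate=3e-3,
            lr_decay=0.87,
            batch_size=4,
            patch_size=(16, 16, 8),
            max_epochs=12,
            early_stop_patience=4,
            base_channels=8,
            depth=1,
            steps_per_epoch=400,
            centered_fraction=0.8,
            random_seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TrainingHistory:
    """Per-epoch losses and the selected (best-validation) epoch, 1-based."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    selected_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


class EarlyStopper:
    """Stop when validation loss has not improved for ``patience`` epochs.

    Epochs are 1-based. ``update`` returns True when training should
    stop *after* the given epoch.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0

    def update(self, epoch: int, loss: float) -> bool:
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            return False
        return (epoch - self.best_epoch) >= self.patience


def run_early_stopping(losses: Sequence[float], patience: int) -> Tuple[int, int]:
    """Apply the early-stopping rule to a validation-loss sequence.

    Returns ``(stopped_epoch, selected_epoch)``, both 1-based; useful
    for reasoning about the rule independently of an actual training run.
    """
    stopper = EarlyStopper(patience)
    for epoch, loss in enumerate(losses, start=1):
        if stopper.update(epoch, loss):
            return epoch, stopper.best_epoch
    return len(losses), stopper.best_epoch


def build_localizer(config: LocalizerConfig) -> UNet3D:
    """Instantiate the U-Net for a config, deterministically seeded."""
    return UNet3D(
        in_channels=1,
        out_channels=len(LANDMARK_LABELS),
        base_channels=config.base_channels,
        depth=config.depth,
        nominal_patch=config.patch_size,
        min_slice_pool=config.min_slice_pool,
        seed=config.random_seed,
    )


def _extract_patch(arr: np.ndarray, start: np.ndarray, size: Sequence[int]) -> np.ndarray:
    """Zero-padded crop of the trailing 3 axes; works for 3D and 4D arrays."""
    size = np.asarray(size, dtype=int)
    lead = arr.shape[:-3]
    out = np.zeros(lead + tuple(size), dtype=arr.dtype)
    shape = np.asarray(arr.shape[-3:])
    src_lo = np.clip(start, 0, shape)
    src_hi = np.clip(start + size, 0, shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        return out
    src = tuple(slice(int(a), int(b)) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(int(a), int(b)) for a, b in zip(dst_lo, dst_hi))
    out[(Ellipsis,) + dst] = arr[(Ellipsis,) + src]
    return out


def sample_training_patch(
    volume: VolumeGrid,
    targets: HeatmapStack,
    config: LocalizerConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, object]]:
    """Draw one training patch pair (input, target, info).

    With probability ``centered_fraction`` the patch is centered near a
    randomly chosen landmark (jittered by up to a quarter patch); else
    its position is uniform. Patches beyond the border are zero-padded,
    so volumes smaller than the patch are fully contained.
    """
    size = np.asarray(config.patch_size, dtype=int)
    shape = np.asarray(volume.shape, dtype=int)
    present = [
        ci for ci in range(targets.data.shape[0]) if targets.data[ci].max() > 0
    ]
    mode = "uniform"
    if present and rng.random() < config.centered_fraction:
        mode = "centered"
        ci = int(rng.choice(present))
        center = np.asarray(
            np.unravel_index(int(np.argmax(targets.data[ci])), tuple(shape))
        )
        offset = rng.integers(-(size // 4), size // 4 + 1)
        start = center - size // 2 + offset
    else:
        lo = np.minimum(0, shape - size)
        hi = np.maximum(0, shape - size)
        start = rng.integers(lo, hi + 1)
    x = _extract_patch(volume.data, start, size)[np.newaxis]
    y = _extract_patch(targets.data, start, size)
    return x, y, {"mode": mode, "start": start}


def _validation_patches(
    pairs: Sequence[Tuple[VolumeGrid, HeatmapStack]], config: LocalizerConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic landmark-centered patches for validation loss."""
    size = np.asarray(config.patch_size, dtype=int)
    xs, ys = [], []
    for vol, targets in pairs:
        shape = np.asarray(vol.shape)
        for ci in range(targets.data.shape[0]):
            if targets.data[ci].max() <= 0:
                continue
            center = np.asarray(
                np.unravel_index(int(np.argmax(targets.data[ci])), tuple(shape))
            )
            start = center - size // 2
            xs.append(_extract_patch(vol.data, start, size)[np.newaxis])
            ys.append(_extract_patch(targets.data, start, size))
    if not xs:
        raise DataError("validation set contains no usable landmarks")
    return np.stack(xs), np.stack(ys)


def train(
    train_set: Sequence[Tuple[VolumeGrid, LandmarkSet]],
    validation_set: Sequence[Tuple[VolumeGrid, LandmarkSet]],
    config: LocalizerConfig,
    preprocess_config: Optional[PreprocessConfig] = None,
    heatmap_config: Optional[HeatmapConfig] = None,
    initial_model: Optional[UNet3D] = None,
) -> Tuple[UNet3D, TrainingHistory]:
    """Train the heatmap regressor with early stopping.

    Volumes are resampled/normalized and Gaussian targets built once up
    front. The returned model carries the parameters of the epoch with
    the lowest validation loss. Fully reproducible under a fixed
    ``config.random_seed``.
    """
    if not train_set or not validation_set:
        raise DataError("training and validation sets must be non-empty")
    pre = preprocess_config or PreprocessConfig()
    hm = heatmap_config or HeatmapConfig()

    def prep(pairs):
        out = []
        for vol, lm in pairs:
            v = preprocess_volume(vol, pre)
            out.append((v, make_heatmap_targets(lm, v, hm)))
        return out

    train_pairs = prep(train_set)
    val_pairs = prep(validation_set)
    val_x, val_y = _validation_patches(val_pairs, config)

    model = initial_model if initial_model is not None else build_localizer(config)
    optim = Adam(model.conv_layers(), lr=config.learning_rate)
    rng = np.random.default_rng(config.random_seed)
    stopper = EarlyStopper(config.early_stop_patience)
    history = TrainingHistory()
    best_state = model.state_dict()

    for epoch in range(1, config.max_epochs + 1):
        losses = []
        for _ in range(config.steps_per_epoch):
            xs, ys = [], []
            for _ in range(config.batch_size):
                vi = int(rng.integers(len(train_pairs)))
                x, y, _info = sample_training_patch(
                    train_pairs[vi][0], train_pairs[vi][1], config, rng
                )
                xs.append(x)
                ys.append(y)
            xb, yb = np.stack(xs), np.stack(ys)
            pred = model.forward(xb)
            loss, dpred = mse_loss(pred, yb)
            model.backward(dpred.astype(pred.dtype))
            optim.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))

        sq_sum, n_elem = 0.0, 0
        for i in range(0, len(val_x), config.batch_size):
            pred = model.forward(val_x[i : i + config.batch_size])
            diff = pred.astype(np.float64) - val_y[i : i + config.batch_size]
            sq_sum += float(np.sum(diff**2))
            n_elem += diff.size
        vloss = sq_sum / n_elem
        history.val_loss.append(vloss)
        improved = vloss < stopper.best
        stop = stopper.update(epoch, vloss)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
        optim.lr *= config.lr_decay

    model.load_state_dict(best_state)
    history.selected_epoch = stopper.best_epoch
    return model, history


class StubHeatmapModel:
    """Debug/test model that emits precomputed heatmaps instead of running a network.

    ``stack_fn`` maps a preprocessed VolumeGrid to a HeatmapStack on
    that grid; useful for exercising the inference pipeline end to end
    without training.
    """

    def __init__(self, stack_fn):
        self.stack_fn = stack_fn

    def predict_stack(self, volume: VolumeGrid) -> HeatmapStack:
        return self.stack_fn(volume)


def _sliding_window_stack(
    model: UNet3D,
    volume: VolumeGrid,
    patch_size: Optional[Sequence[int]],
    overlap: float,
) -> HeatmapStack:
    shape = np.asarray(volume.shape, dtype=int)
    mult = np.asarray(model.required_multiple(), dtype=int)
    if patch_size is None:
        # single whole-volume window, padded up to divisibility
        window = (np.ceil(shape / mult) * mult).astype(int)
    else:
        window = np.asarray(patch_size, dtype=int)
        if np.any(window % mult):
            raise ConfigError(f"inference window {tuple(window)} not divisible by {tuple(mult)}")
    padded_shape = np.maximum(shape, window)
    data = _extract_patch(volume.data, np.zeros(3, dtype=int), padded_shape)

    step = np.maximum(1, np.round(window * (1.0 - overlap)).astype(int))
    starts_per_axis = []
    for ax in range(3):
        last = padded_shape[ax] - window[ax]
        s = list(range(0, int(last) + 1, int(step[ax])))
        if s[-1] != last:
            s.append(int(last))
        starts_per_axis.append(sorted(set(s)))

    acc = np.zeros((model.out_channels,) + tuple(padded_shape), dtype=np.float64)
    cnt = np.zeros(tuple(padded_shape), dtype=np.float64)
    for sx in starts_per_axis[0]:
        for sy in starts_per_axis[1]:
            for sz in starts_per_axis[2]:
                sl = (
                    slice(sx, sx + window[0]),
                    slice(sy, sy + window[1]),
                    slice(sz, sz + window[2]),
                )
                patch = data[sl][np.newaxis, np.newaxis]
                out = model.forward(patch.astype(np.float32))[0]
                acc[(slice(None),) + sl] += out
                cnt[sl] += 1.0
    blended = acc / cnt[np.newaxis]
    crop = (slice(None),) + tuple(slice(0, int(s)) for s in shape)
    return HeatmapStack(data=blended[crop].astype(np.float32))


def predict_landmarks(
    model,
    volume: VolumeGrid,
    preprocess_config: Optional[PreprocessConfig] = None,
    heatmap_config: Optional[HeatmapConfig] = None,
    patch_size: Optional[Sequence[int]] = None,
    overlap: float = 0.5,
    floor: float = 0.0,
) -> Tuple[LandmarkSet, Dict[str, float], Dict[str, bool]]:
    """Whole-volume inference: preprocess, tile, blend, decode.

    The volume is resampled to the reference grid and normalized, the
    model is applied in sliding windows with mean blending (a single
    padded window by default), and heatmap peaks are decoded back to
    physical mm in the original volume's frame (the resampling chain
    never moves physical coordinates).

    Returns ``(landmarks, peak_confidences, low_confidence_flags)``.
    """
    if not isinstance(volume, VolumeGrid):
        raise InvalidMetadataError("predict_landmarks requires a VolumeGrid with spacing metadata")
    pre = preprocess_config or PreprocessConfig()
    vol_p = preprocess_volume(volume, pre)
    if hasattr(model, "predict_stack"):
        stack = model.predict_stack(vol_p)
    else:
        stack = _sliding_window_stack(model, vol_p, patch_size, overlap)
    return decode_heatmaps(stack, vol_p, floor=floor)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(
    path,
    model: UNet3D,
    config: LocalizerConfig,
    history: TrainingHistory,
) -> None:
    """Save weights + config + history to a single ``.npz`` file."""
    meta = {
        "config": asdict(config),
        "history": {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "selected_epoch": history.selected_epoch,
        },
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_dict())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Tuple[UNet3D, LocalizerConfig, TrainingHistory]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        n = len([k for k in z.files if k.startswith("p")])
        arrays = [z[f"p{i}"] for i in range(n)]
    cfg_dict = meta["config"]
    cfg_dict["patch_size"] = tuple(cfg_dict["patch_size"])
    config = LocalizerConfig(**cfg_dict)
    model = build_localizer(config)
    model.load_state_dict(arrays)
    h = meta["history"]
    history = TrainingHistory(
        train_loss=h["train_loss"], val_loss=h["val_loss"], selected_epoch=h["selected_epoch"]
    )
    return model, config, history
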