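"""Orbital fat-pad segmentation: training, inference and overlap metrics.

The segmentation network is the NumPy U-net of :mod:`nutriface.unet`.  The
default training recipe is batch size 1, 50 epochs, binary cross-entropy,
RMSProp (learning rate 1e-5, weight decay 1e-8, momentum 0.9) on an 80/20
random split.  Masks are stored as {0,255} rasters and converted to {0,1}
targets for the loss.  Scaled-down configurations (smaller images, fewer
base channels, fewer epochs, larger learning rate) are plain config choices
and exercise the identical code path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import validate_mask
from .unet import RMSProp, UNet, bce_loss

__all__ = [
    "SegTrainConfig",
    "SegModel",
    "split_dataset",
    "train_seg",
    "predict_mask",
    "dice",
    "iou",
    "miou",
]


@dataclass(frozen=True)
class SegTrainConfig:
    batch_size: int = 1
    epochs: int = 50
    learning_rate: float = 1e-5
    weight_decay: float = 1e-8
    momentum: float = 0.9
    rms_alpha: float = 0.99
    split_fraction: float = 0.8
    seed: int = 0
    image_size: int = 300
    base_channels: int = 64
    levels: int = 4
    threshold: float = 0.5
    out_bias: float = -4.0  # prior log-odds init for the sparse foreground

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SegModel:
    """Trained U-net plus the config it was trained with."""

    net: UNet
    config: SegTrainConfig

    def save(self, path: str | Path) -> None:
        state = self.net.state()
        cfg = json.dumps(asdict(self.config), sort_keys=True)
        header = json.dumps(state["arch"], sort_keys=True)
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __arch__=np.frombuffer(header.encode(), dtype=np.uint8),
                __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                **state["params"],
            )

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with np.load(path) as data:
            arch = json.loads(bytes(data["__arch__"]).decode())
            cfg = json.loads(bytes(data["__config__"]).decode())
            params = {
                k: data[k] for k in data.files if not k.startswith("__")
            }
        return cls(net=UNet.from_state(arch, params), config=SegTrainConfig(**cfg))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self.config), sort_keys=True).encode()
        ).hexdigest()[:16]


def split_dataset(records, fraction: float = 0.8, seed: int = 0,
                  counts: "tuple[int, int] | None" = None):
    """Random disjoint, exhaustive train/test partition.

    With ``fraction``, the training set holds ``round(fraction * n)`` items;
    ``counts=(n_train, n_test)`` pins explicit sizes instead (they must sum
    to ``len(records)``).  Deterministic given the seed; unstratified.
    """
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if counts is not None:
        n_train, n_test = counts
        if n_train + n_test != n:
            raise ValueError(f"counts {counts} do not sum to {n}")
    else:
        n_train = int(round(fraction * n))
        n_test = n - n_train
    if n_train == 0 or n_test == 0:
        raise ValueError("empty train or test set under this split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
    order = rng.permutation(n)
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def _check_pair(face: np.ndarray, mask: np.ndarray):
    face = np.asarray(face, dtype=np.float64)
    if face.ndim == 3:  # luma-reduce RGB
        face = face @ np.array([0.299, 0.587, 0.114])
    if face.shape != mask.shape:
        raise ValueError(f"face {face.shape} and mask {np.shape(mask)} differ")
    validate_mask(np.asarray(mask))
    target = (np.asarray(mask) == 255).astype(np.float32)
    return face.astype(np.float32), target


def train_seg(pairs, config: SegTrainConfig = SegTrainConfig(),
              val_pairs=None, verbose: bool = False):
    """Train the U-net on (face, mask) pairs.

    Returns ``(SegModel, history)`` where ``history`` is a list of per-epoch
    dicts with the mean training loss (and validation Dice when ``val_pairs``
    is given).  Deterministic given the config seed.
    """
    if not pairs:
        raise ValueError("empty training list")
    data = [_check_pair(f, m) for f, m in pairs]
    size = data[0][0].shape
    if any(f.shape != size for f, _ in data):
        raise ValueError("all training images must share one shape")

    net = UNet(
        base_channels=config.base_channels,
        levels=config.levels,
        in_channels=1,
        seed=config.seed,
        out_bias=config.out_bias,
    )
    opt = RMSProp(
        net.params,
        lr=config.learning_rate,
        alpha=config.rms_alpha,
        weight_decay=config.weight_decay,
        momentum=config.momentum,
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    history = []
    model = SegModel(net=net, config=config)
    for epoch in range(config.epochs):
        losses = []
        for i in rng.permutation(len(data)):
            face, target = data[i]
            prob, cache = net.forward(face, want_cache=True)
            losses.append(bce_loss(prob, target))
            grads = net.backward(prob, target, cache)
            opt.step(net.params, grads)
        row = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        if val_pairs:
            dices = []
            for vf, vm in val_pairs:
                pred = predict_mask(model, vf, config.threshold)
                dices.append(dice(pred, np.asarray(vm, dtype=np.uint8)))
            row["val_dice"] = float(np.mean(dices))
        history.append(row)
        if verbose:
            print(f"epoch {row['epoch']}: " + ", ".join(
                f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
    return model, history


def predict_mask(model: SegModel, face: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Segment one face: probability map thresholded into a {0,255} mask."""
    face = np.asarray(face, dtype=np.float64)
    if face.ndim == 3:
        face = face @ np.array([0.299, 0.587, 0.114])
    prob = model.net.forward(face.astype(np.float32))
    return np.where(prob >= threshold, 255, 0).astype(np.uint8)


def _binary_sets(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    validate_mask(a)
    validate_mask(b)
    return a == 255, b == 255


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A^B| / (|A|+|B|) on the 255-pixel sets; 1.0 when both empty."""
    fa, fb = _binary_sets(a, b)
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((fa & fb).sum()) / denom


def iou(a: np.ndarray, b: np.ndarray, cls: str = "foreground") -> float:
    """Intersection-over-union on the chosen class; 1.0 when both empty."""
    fa, fb = _binary_sets(a, b)
    if cls == "background":
        fa, fb = ~fa, ~fb
    elif cls != "foreground":
        raise ValueError("cls must be 'foreground' or 'background'")
    union = int((fa | fb).sum())
    if union == 0:
        return 1.0
    return int((fa & fb).sum()) / union


def miou(a: np.ndarray, b: np.ndarray) -> float:
    """Unweighted mean of foreground and background IoU."""
    return 0.5 * (iou(a, b, "foreground") + iou(a, b, "background"))
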