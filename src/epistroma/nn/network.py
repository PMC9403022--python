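"""Dilated-convolution encoder–decoder for 3-class tissue segmentation.

Architecture: a strided convolutional stem (output stride r), a stack of
dilated residual blocks (each block runs four ResUnits whose dilation rates
cycle through a multi-scale schedule), and a decoder of four parallel
dilated convolutions that each emit ``r^2 * n_classes`` channels, are
pixel-shuffled back to full resolution, and summed pixel by pixel.

Two presets are provided: ``full`` (deep, wide, output stride 8 — the
production architecture) and ``tiny`` (shallow, narrow, output stride 4 —
trainable on a single CPU in minutes, used throughout the test suite).

Everything runs in NumPy with explicit backpropagation; training minimises
mean per-pixel cross-entropy with SGD + momentum, with random-crop and
mirror augmentation.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, replace

import numpy as np

from .layers import Conv2D, PixelShuffle, ReLU, ResUnit, Sequential

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainResult",
    "load_train_config",
    "CrossValidationResult",
    "SegmentationModel",
    "tiny_config",
    "full_config",
    "build_model",
    "train_model",
    "predict_patch",
    "cross_validate",
    "save_model",
    "load_model",
]

CLASS_NAMES = ("background", "epithelium", "stroma")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``stem_channels`` has one entry per stride-2 stem stage, so the encoder
    output stride is ``2 ** len(stem_channels)`` and must equal
    ``upsample_rate`` (one pixel-shuffle stage restores full resolution).
    """

    preset: str = "tiny"
    n_classes: int = 3
    stem_channels: tuple[int, ...] = (12, 16)
    stem_kernel: int = 3
    block_channels: int = 16
    dilated_blocks: tuple[tuple[int, ...], ...] = ((1, 2, 4, 8),)
    decoder_rates: tuple[int, int, int, int] = (1, 2, 4, 8)
    upsample_rate: int = 4
    seed: int = 0

    def validate(self) -> None:
        if len(self.decoder_rates) != 4:
            raise ValueError("decoder must have exactly 4 branches")
        stride = 2 ** len(self.stem_channels)
        if stride != self.upsample_rate:
            raise ValueError(
                f"upsample_rate {self.upsample_rate} inconsistent with encoder output stride {stride}"
            )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["stem_channels"] = tuple(d["stem_channels"])
        d["dilated_blocks"] = tuple(tuple(b) for b in d["dilated_blocks"])
        d["decoder_rates"] = tuple(d["decoder_rates"])
        return cls(**d)


def tiny_config(seed: int = 0) -> ModelConfig:
    """Desk-scale preset: output stride 4, one dilated block, 16 channels."""
    return ModelConfig(preset="tiny", seed=seed)


def full_config(seed: int = 0) -> ModelConfig:
    """Production-scale preset: three stem stages (output stride 8) and six
    dilated blocks of four ResUnits with rates cycling (1, 2, 4, 8)."""
    return ModelConfig(
        preset="full",
        stem_channels=(32, 64, 128),
        stem_kernel=7,
        block_channels=128,
        dilated_blocks=tuple((1, 2, 4, 8) for _ in range(6)),
        decoder_rates=(1, 2, 4, 8),
        upsample_rate=8,
        seed=seed,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (the source method leaves these open;
    defaults are the package's documented choices)."""

    folds: int = 5
    crop: int = 600
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 5e-3
    momentum: float = 0.9
    optimizer: str = "adam"
    mirror: bool = True
    random_crop: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch size")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


def load_train_config(path) -> TrainConfig:
    """Read a TrainConfig from a YAML (or JSON) mapping of field names."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    tc = TrainConfig(**data)
    tc.validate()
    return tc


@dataclass
class TrainResult:
    """Per-epoch training history."""

    loss: list[float]
    pixel_accuracy: list[float]

    def summary(self) -> str:
        lines = ["epoch  loss      pixel_acc", "-" * 28]
        for i, (l, a) in enumerate(zip(self.loss, self.pixel_accuracy)):
            lines.append(f"{i + 1:>5}  {l:8.4f}  {a:9.4f}")
        return "\n".join(lines)


class SegmentationModel:
    """The segmentation network: config + parameters + fit/predict."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_prev = 3
        for i, c in enumerate(config.stem_channels):
            if i == 0:
                layers += [Conv2D(c_prev, c, config.stem_kernel, stride=2, rng=rng), ReLU()]
            else:
                layers.append(ResUnit(c_prev, c, stride=2, rng=rng))
            c_prev = c
        if c_prev != config.block_channels:
            layers += [Conv2D(c_prev, config.block_channels, 1, rng=rng), ReLU()]
            c_prev = config.block_channels
        for block in config.dilated_blocks:
            for rate in block:
                layers.append(ResUnit(c_prev, c_prev, dilation=rate, rng=rng))
        self.encoder = Sequential(layers)

        r = config.upsample_rate
        self.branches = []
        for rate in config.decoder_rates:
            conv = Conv2D(c_prev, r * r * config.n_classes, 3, dilation=rate, init="xavier", rng=rng)
            self.branches.append((conv, PixelShuffle(r)))

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[dict]:
        ps = self.encoder.parameters()
        for conv, _ in self.branches:
            ps += conv.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p["value"].size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p["grad"][...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) float input -> (N, H, W, n_classes) logits."""
        r = self.config.upsample_rate
        if x.shape[1] % r or x.shape[2] % r:
            raise ValueError(f"input spatial dims must be divisible by the output stride {r}")
        e = self.encoder.forward(x)
        out = None
        for conv, shuffle in self.branches:
            y = shuffle.forward(conv.forward(e))
            out = y if out is None else out + y
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ge = None
        for conv, shuffle in self.branches:
            g = conv.backward(shuffle.backward(grad))
            ge = g if ge is None else ge + g
        return self.encoder.backward(ge)

    # -- inference ----------------------------------------------------------
    def predict_scores(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch)
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValueError("patch must be H x W x 3")
        x = patch.astype(np.float64)[None] / 255.0 - 0.5
        return self.forward(x)[0]

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Per-pixel argmax over class scores (ties break to the lower class
        index, which np.argmax guarantees)."""
        scores = self.predict_scores(patch)
        return np.argmax(scores, axis=-1).astype(np.uint8)

    def fit(self, dataset, train_config: TrainConfig | None = None) -> TrainResult:
        _, history = train_model(self, dataset, train_config or TrainConfig())
        return history

    def load_pretrained_encoder(self, path) -> None:
        """Optional hook: load externally supplied encoder weights (a .npz
        with arrays enc0, enc1, ... in parameter order)."""
        data = np.load(path)
        params = self.encoder.parameters()
        for i, p in enumerate(params):
            arr = data[f"enc{i}"]
            if arr.shape != p["value"].shape:
                raise ValueError(f"pretrained array enc{i} shape mismatch")
            p["value"][...] = arr


def build_model(config: ModelConfig) -> SegmentationModel:
    return SegmentationModel(config)


def predict_patch(model: SegmentationModel, patch: np.ndarray) -> np.ndarray:
    return model.predict_patch(patch)


# -- training ---------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _augment(img: np.ndarray, mask: np.ndarray, crop: int, tc: TrainConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    h, w = mask.shape
    ch, cw = min(crop, h), min(crop, w)
    if tc.random_crop and (h > ch or w > cw):
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
    else:
        r0 = c0 = 0
    img, mask = img[r0 : r0 + ch, c0 : c0 + cw], mask[r0 : r0 + ch, c0 : c0 + cw]
    if tc.mirror and rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    return img, mask


def train_model(model: SegmentationModel, dataset, tc: TrainConfig | None = None) -> tuple[SegmentationModel, TrainResult]:
    """Minimise mean per-pixel cross-entropy with SGD + momentum.

    ``dataset`` is a sequence of (uint8 RGB image, uint8 label mask) pairs.
    The model is updated in place; the per-epoch loss / pixel-accuracy
    history is returned alongside it.  Deterministic given ``tc.seed``.
    """
    tc = tc or TrainConfig()
    tc.validate()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    r = model.config.upsample_rate
    min_dim = min(min(m.shape[0], m.shape[1]) for _, m in dataset)
    crop = min(tc.crop, min_dim)
    crop -= crop % r  # spatial dims must stay divisible by the output stride
    if crop < r:
        raise ValueError("images too small for the encoder output stride")

    rng = np.random.default_rng(tc.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p["value"]) for p in params]
    second = [np.zeros_like(p["value"]) for p in params] if tc.optimizer == "adam" else None
    step = 0
    n_classes = model.config.n_classes
    history = TrainResult(loss=[], pixel_accuracy=[])

    for _ in range(tc.epochs):
        order = rng.permutation(len(dataset))
        ep_loss, ep_correct, ep_pixels = 0.0, 0, 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xs, ys = [], []
            for i in idx:
                img, mask = dataset[i]
                img, mask = _augment(img, mask, crop, tc, rng)
                xs.append(img.astype(np.float64) / 255.0 - 0.5)
                ys.append(mask.astype(np.int64))
            x = np.stack(xs)
            y = np.stack(ys)
            logits = model.forward(x)
            p = _softmax(logits)
            onehot = np.eye(n_classes)[y]
            npix = y.size
            eps = 1e-12
            loss = float(-(onehot * np.log(p + eps)).sum() / npix)
            model.zero_grad()
            model.backward((p - onehot) / npix)
            step += 1
            if tc.optimizer == "sgd":
                for v, prm in zip(velocity, params):
                    v *= tc.momentum
                    v -= tc.learning_rate * prm["grad"]
                    prm["value"] += v
            else:  # adam (beta1 = momentum, beta2 = 0.999)
                b1, b2, eps_a = tc.momentum, 0.999, 1e-8
                for v, s2, prm in zip(velocity, second, params):
                    g = prm["grad"]
                    v *= b1
                    v += (1 - b1) * g
                    s2 *= b2
                    s2 += (1 - b2) * g * g
                    vhat = v / (1 - b1**step)
                    shat = s2 / (1 - b2**step)
                    prm["value"] -= tc.learning_rate * vhat / (np.sqrt(shat) + eps_a)
            ep_loss += loss * npix
            ep_correct += int((np.argmax(logits, axis=-1) == y).sum())
            ep_pixels += npix
        history.loss.append(ep_loss / ep_pixels)
        history.pixel_accuracy.append(ep_correct / ep_pixels)
    return model, history


def evaluate(model: SegmentationModel, dataset) -> dict:
    """Held-out evaluation: pixel accuracy plus pooled confusion counts for
    each tissue class (background pixels excluded from the per-class
    counts, as in the quantification module)."""
    from ..metrics import ConfusionCounts, confusion

    correct = total = 0
    pooled = {1: ConfusionCounts(0, 0, 0, 0), 2: ConfusionCounts(0, 0, 0, 0)}
    for img, truth in dataset:
        pred = model.predict_patch(img)
        correct += int((pred == truth).sum())
        total += truth.size
        for lab in (1, 2):
            c = confusion(pred, truth, positive_label=lab)
            old = pooled[lab]
            pooled[lab] = ConfusionCounts(old.tp + c.tp, old.fp + c.fp, old.tn + c.tn, old.fn + c.fn)
    return {"pixel_accuracy": correct / total, "confusion": pooled}


@dataclass
class CrossValidationResult:
    """Per-fold held-out metrics from k-fold cross-validation."""

    fold_accuracies: list[float]
    fold_metrics: list[dict]
    histories: list[TrainResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def summary(self) -> str:
        lines = ["fold  held-out pixel accuracy", "-" * 30]
        for i, a in enumerate(self.fold_accuracies):
            lines.append(f"{i + 1:>4}  {a:.4f}")
        lines.append(f"mean  {self.mean_accuracy:.4f}")
        return "\n".join(lines)


def cross_validate(dataset, mc: ModelConfig, tc: TrainConfig) -> CrossValidationResult:
    """Seeded k-fold cross-validation: disjoint folds, each held out once;
    held-out pixels are scored with the quantification metrics."""
    from ..metrics import compute_metrics

    tc.validate()
    if len(dataset) < tc.folds:
        raise ValueError("folds exceed dataset size")
    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(len(dataset))
    folds = np.array_split(order, tc.folds)
    result = CrossValidationResult(fold_accuracies=[], fold_metrics=[], histories=[])
    for f, test_idx in enumerate(folds):
        train_idx = np.concatenate([folds[g] for g in range(tc.folds) if g != f])
        model = SegmentationModel(replace(mc, seed=mc.seed + f))
        _, hist = train_model(model, [dataset[i] for i in train_idx], replace(tc, seed=tc.seed + f))
        ev = evaluate(model, [dataset[i] for i in test_idx])
        metrics = {lab: compute_metrics(cc) for lab, cc in ev["confusion"].items()}
        result.fold_accuracies.append(ev["pixel_accuracy"])
        result.fold_metrics.append(metrics)
        result.histories.append(hist)
    return result


# -- serialization ----------------------------------------------------------

def save_model(model: SegmentationModel, path) -> None:
    """Single portable file: a zip holding the config (JSON) and parameter
    arrays (npy) in traversal order."""
    arrays = {f"p{i}": p["value"] for i, p in enumerate(model.parameters())}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(model.config.to_dict()))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_model(path) -> SegmentationModel:
    with zipfile.ZipFile(path) as zf:
        config = ModelConfig.from_dict(json.loads(zf.read("config.json")))
        model = SegmentationModel(config)
        for i, p in enumerate(model.parameters()):
            arr = np.load(io.BytesIO(zf.read(f"p{i}.npy")))
            p["value"][...] = arr
    return model
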