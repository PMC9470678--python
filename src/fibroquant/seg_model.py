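"""Patient-grouped splits, augmentation enumeration, and a compact
encoder–decoder segmentation network.

The network follows the SegNet recipe: an encoder of ``depth`` blocks, each
one 3×3 convolution → ReLU → stride-2 max-pool whose argmax positions are
remembered, mirrored by a decoder of ``depth`` blocks that unpool into the
remembered positions before convolving, and a final 1×1 convolution to the
five tissue classes.  Training is pixelwise softmax cross-entropy under
Adam with per-epoch shuffling.  Everything — forward, backward, optimizer —
is implemented in NumPy, so the harness runs anywhere and is exactly
reproducible under a seed.

Dataset handling enforces group integrity: all images of one patient land
in the same split.  Augmentation enumerates 49 translation combinations
({−3..3} on X × {−3..3} on Y) and 62 orientation variants (61 rotations at
1° steps in −30..30, plus one horizontal reflection of the unrotated image)
= 3,038 geometric variants per source image, applied identically to image
and label map (bilinear vs nearest-neighbour resampling).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from fibroquant._constants import AIR, AIR_HU, N_CLASSES
from fibroquant.ct_io import LabelMap

__all__ = [
    "SplitSpec",
    "AugmentSpec",
    "TrainConfig",
    "split_by_patient",
    "enumerate_augmentations",
    "SegNetLite",
    "build_network",
    "train",
    "predict",
]


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Train/validation/test proportions with patient-group integrity."""

    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")


def split_by_patient(
    images: Sequence[tuple], spec: SplitSpec
) -> tuple[list, list, list]:
    """Partition (image, label, patient_id) triples into three splits.

    Every patient's images stay together.  Patients are assigned largest
    first (ties broken by a seeded shuffle) to whichever split currently has
    the largest remaining image deficit against its target fraction, which
    gets the realized fractions as close to the spec as group integrity
    allows.  Deterministic given the seed.
    """
    by_patient: dict = {}
    for item in images:
        by_patient.setdefault(item[2], []).append(item)
    if len(by_patient) < 3:
        raise ValueError("need at least 3 distinct patients to form 3 splits")

    rng = np.random.default_rng(spec.seed)
    pids = sorted(by_patient)
    rng.shuffle(pids)
    # largest patients first; the shuffle only breaks size ties
    pids.sort(key=lambda p: -len(by_patient[p]))

    total = sum(len(v) for v in by_patient.values())
    targets = [f * total for f in spec.fractions]
    assigned = [0, 0, 0]
    splits: tuple[list, list, list] = ([], [], [])
    for pid in pids:
        deficits = [targets[i] - assigned[i] for i in range(3)]
        dest = int(np.argmax(deficits))
        splits[dest].extend(by_patient[pid])
        assigned[dest] += len(by_patient[pid])
    return splits


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentSpec:
    """Geometric augmentation grid: translations, rotations, reflection."""

    max_shift: int = 3
    rotation_range: tuple[int, int] = (-30, 30)
    rotation_step: int = 1
    reflection: bool = True

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be non-negative")
        lo, hi = self.rotation_range
        if lo > hi or (hi - lo) % self.rotation_step != 0:
            raise ValueError("rotation step must divide the rotation range")

    @property
    def n_translations(self) -> int:
        s = 2 * self.max_shift + 1
        return s * s

    @property
    def n_orientations(self) -> int:
        lo, hi = self.rotation_range
        return (hi - lo) // self.rotation_step + 1 + (1 if self.reflection else 0)

    @property
    def variants_per_image(self) -> int:
        return self.n_translations * self.n_orientations


def _transform_pair(
    image: np.ndarray, labels: np.ndarray, dx: int, dy: int, angle: float, reflect: bool
) -> tuple[np.ndarray, np.ndarray]:
    img, lab = image, labels
    if reflect:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if angle != 0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, cval=AIR_HU)
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, cval=AIR)
    if dx or dy:
        img = ndimage.shift(img, (dy, dx), order=0, cval=AIR_HU)
        lab = ndimage.shift(lab, (dy, dx), order=0, cval=AIR)
    return img, lab


def enumerate_augmentations(
    image: np.ndarray, labels: np.ndarray, spec: AugmentSpec | None = None
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield every geometric variant of an (image, labels) pair.

    Deterministic order: translations (row-major over dy, dx) × orientations
    (rotations ascending, then the reflection).  The identity transform is
    the variant at dy=dx=0, angle=0.  Labels are resampled with
    nearest-neighbour interpolation, images bilinearly; out-of-frame pixels
    are filled with air.
    """
    spec = spec or AugmentSpec()
    if image.shape != labels.shape:
        raise ValueError("image and labels must be congruent")
    lo, hi = spec.rotation_range
    shifts = range(-spec.max_shift, spec.max_shift + 1)
    for dy, dx in itertools.product(shifts, shifts):
        for angle in range(lo, hi + 1, spec.rotation_step):
            yield _transform_pair(image, labels, dx, dy, float(angle), False)
        if spec.reflection:
            yield _transform_pair(image, labels, dx, dy, 0.0, True)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training recipe.  The dataclass defaults are the full-scale recipe
    (encoder depth 3, 55 epochs, lr 0.002, minibatch 16, Adam, per-epoch
    shuffling, 256×256 inputs); :meth:`desk_scale` returns the reduced
    profile used for fast runs on synthetic data."""

    encoder_depth: int = 3
    epochs: int = 55
    learning_rate: float = 0.002
    minibatch: int = 16
    optimizer: str = "adam"
    shuffle_each_epoch: bool = True
    input_size: int = 256
    base_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_depth < 1:
            raise ValueError("encoder_depth must be >= 1")
        if min(self.epochs, self.learning_rate, self.minibatch, self.input_size) <= 0:
            raise ValueError("all training parameters must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        params = dict(epochs=120, input_size=64, base_channels=8)
        params.update(overrides)
        return cls(**params)


class _Conv:
    """3×3 (or 1×1) same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, ksize: int = 3):
        self.ksize = ksize
        fan_in = ksize * ksize * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout))
        self.b = np.zeros(cout)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.ksize, self.ksize // 2
        n, h, w, _ = x.shape
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        patches = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,H,W,Cin,k,k)
        self._cols = np.ascontiguousarray(patches.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n, h, w, k * k * self.cin
        )
        return self._cols @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.ksize, self.ksize // 2
        n, h, w, _ = dy.shape
        self.dW = np.tensordot(self._cols, dy, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dy.sum(axis=(0, 1, 2))
        dcols = (dy @ self.W.T).reshape(n, h, w, k, k, self.cin)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin))
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool2:
    """2×2 stride-2 max pooling that remembers argmax positions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h // 2, w // 2, c, 4
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.scatter(dy)

    def scatter(self, y: np.ndarray) -> np.ndarray:
        """Place values into the remembered argmax positions (also the
        unpooling forward)."""
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, c, 4))
        np.put_along_axis(out, self._idx[..., None], y[..., None], axis=-1)
        return out.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
            n, h, w, c
        )

    def gather(self, dy_full: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`scatter` (the unpooling backward)."""
        n, h, w, c = self._shape
        xr = dy_full.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h // 2, w // 2, c, 4
        )
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]


class SegNetLite:
    """Encoder–decoder pixel classifier with pooling-index unpooling."""

    def __init__(self, cfg: TrainConfig, n_classes: int = N_CLASSES):
        if cfg.input_size % (2**cfg.encoder_depth) != 0:
            raise ValueError(
                f"input size {cfg.input_size} not divisible by 2^{cfg.encoder_depth}"
            )
        self.cfg = cfg
        self.n_classes = n_classes
        rng = np.random.default_rng(cfg.seed)
        chans = [cfg.base_channels * 2**i for i in range(cfg.encoder_depth)]
        self.enc_convs = []
        self.enc_relus = []
        self.pools = []
        cin = 1
        for c in chans:
            self.enc_convs.append(_Conv(cin, c, rng))
            self.enc_relus.append(_ReLU())
            self.pools.append(_MaxPool2())
            cin = c
        self.dec_convs = []
        self.dec_relus = []
        for i in reversed(range(cfg.encoder_depth)):
            cout = chans[i - 1] if i > 0 else chans[0]
            self.dec_convs.append(_Conv(chans[i], cout, rng))
            self.dec_relus.append(_ReLU())
        self.head = _Conv(chans[0], n_classes, rng, ksize=1)

    # -- parameter bookkeeping ---------------------------------------------
    def _layers_with_params(self):
        return self.enc_convs + self.dec_convs + [self.head]

    @property
    def n_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self._layers_with_params())

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W, 1) normalized intensity → logits (N, H, W, classes)."""
        h = x
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        for i, (conv, relu) in enumerate(zip(self.dec_convs, self.dec_relus)):
            pool = self.pools[self.cfg.encoder_depth - 1 - i]
            h = relu.forward(conv.forward(pool.scatter(h)))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        for i in reversed(range(self.cfg.encoder_depth)):
            pool = self.pools[self.cfg.encoder_depth - 1 - i]
            g = self.dec_convs[i].backward(self.dec_relus[i].backward(g))
            g = pool.gather(g)
        for i in reversed(range(self.cfg.encoder_depth)):
            g = self.pools[i].backward(g)
            g = self.enc_convs[i].backward(self.enc_relus[i].backward(g))

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Mean pixelwise cross-entropy; leaves gradients in the layers."""
        logits = self.forward(x)
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=-1, keepdims=True)
        n_pix = labels.size
        onehot = np.eye(self.n_classes)[labels]
        loss = float(-(onehot * np.log(probs + 1e-12)).sum() / n_pix)
        self.backward((probs - onehot) / n_pix)
        return loss

    def loss(self, x: np.ndarray, labels: np.ndarray) -> float:
        logits = self.forward(x)
        z = logits - logits.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        return float(-np.take_along_axis(logp, labels[..., None], axis=-1).mean())


def normalize_hu(hu: np.ndarray) -> np.ndarray:
    """Map HU to network input: air (−1000) → 0, water (0) → 1."""
    return (np.asarray(hu, dtype=np.float64) + 1000.0) / 1000.0


def build_network(cfg: TrainConfig, n_classes: int = N_CLASSES) -> SegNetLite:
    """Construct the encoder–decoder; raises on indivisible input size."""
    return SegNetLite(cfg, n_classes)


class _Adam:
    def __init__(self, model: SegNetLite, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = {}
        for li, layer in enumerate(model._layers_with_params()):
            for name in ("W", "b"):
                p = getattr(layer, name)
                self.state[(li, name)] = (np.zeros_like(p), np.zeros_like(p))
        self.model = model

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.model._layers_with_params()):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                m, v = self.state[(li, name)]
                m[:] = self.beta1 * m + (1 - self.beta1) * g
                v[:] = self.beta2 * v + (1 - self.beta2) * g * g
                mh = m / (1 - self.beta1**self.t)
                vh = v / (1 - self.beta2**self.t)
                getattr(layer, name)[...] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _stack_dataset(dataset: Sequence[tuple[np.ndarray, np.ndarray]]):
    xs = np.stack([normalize_hu(img)[..., None] for img, _ in dataset])
    ys = np.stack([np.asarray(lab, dtype=np.int64) for _, lab in dataset])
    return xs, ys


def train(
    model: SegNetLite,
    train_set: Sequence[tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]] | None,
    cfg: TrainConfig,
) -> tuple[SegNetLite, dict[str, list[float]]]:
    """Cross-entropy training with Adam, per-epoch shuffling, loss logging.

    ``train_set``/``val_set`` are sequences of (HU image, label map) arrays
    of the configured input size.  Returns the model and a history dict with
    per-epoch ``train_loss`` and (if a validation set is given) ``val_loss``.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer: {cfg.optimizer}")
    xs, ys = _stack_dataset(train_set)
    if xs.shape[1] != cfg.input_size or xs.shape[2] != cfg.input_size:
        raise ValueError("training images do not match the configured input size")
    val = _stack_dataset(val_set) if val_set else None
    opt = _Adam(model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: dict[str, list[float]] = {"train_loss": []}
    if val is not None:
        history["val_loss"] = []
    n = len(train_set)
    for _ in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        losses = []
        for start in range(0, n, cfg.minibatch):
            sel = order[start : start + cfg.minibatch]
            losses.append(model.loss_and_grad(xs[sel], ys[sel]))
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        if val is not None:
            history["val_loss"].append(model.loss(*val))
    return model, history


def predict(model: SegNetLite, image: np.ndarray, **meta) -> LabelMap:
    """Argmax class per pixel of one HU image crop."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape != (model.cfg.input_size, model.cfg.input_size):
        raise ValueError(
            f"image shape {img.shape} does not match input size {model.cfg.input_size}"
        )
    logits = model.forward(normalize_hu(img)[None, ..., None])
    labels = logits[0].argmax(axis=-1).astype(np.uint8)
    return LabelMap(labels, **meta)
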