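"""Convolutional feature-map producers feeding the fuzzy layer.

Two architectures are provided:

``vgg19_shape``
    The canonical VGG-19 block layout (2,2,4,4,4 conv layers with
    64/128/256/512/512 channels, 2x2 max-pooling per block) used for
    dimension contracts: a 224x224 input yields a 7x7x512 pooled map and
    hence 1536 fuzzy features. Weights are randomly initialised; shipping
    transfer-learned weights is out of scope.

``smallnet``
    A three-block network (8/16/32 channels) sized so training and
    feature extraction run in seconds on one CPU; a 64x64 input yields an
    8x8x32 map and 96 fuzzy features.

Every activation is a ReLU capped at 6, so the map entering the fuzzy layer
respects its [0, r_max] contract. The networks are plain numpy: convolution
is expressed as a sum of shifted channel-matrix products (one GEMM per
kernel offset), and the fine-tuning loop backpropagates through the capped
ReLUs, the pooling switches, the mean-of-maxima selector of the fuzzy layer
and a dense softmax head, updating only the blocks at or after
``trainable_from`` plus the head.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fuzzy import MembershipParams, fuzzy_forward, fuzzy_forward_with_masks
from .images import validate_gray

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "Backbone",
    "TrainedModel",
    "TrainingDivergence",
    "vgg19_shape",
    "smallnet",
    "train",
    "extract_cnn_features",
]

R_MAX = 6.0


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture description: conv blocks, input geometry, fine-tune point."""

    name: str
    input_size: tuple[int, int]
    in_channels: int
    #: per block: (number of conv layers, output channels)
    blocks: tuple[tuple[int, int], ...]
    trainable_from: int

    @property
    def channels_out(self) -> int:
        return self.blocks[-1][1]

    @property
    def map_size(self) -> tuple[int, int]:
        h, w = self.input_size
        f = 2 ** len(self.blocks)
        return h // f, w // f


def vgg19_shape(input_size: tuple[int, int] = (224, 224), trainable_from: int = 4) -> BackboneSpec:
    return BackboneSpec(
        name="vgg19_shape",
        input_size=input_size,
        in_channels=3,
        blocks=((2, 64), (2, 128), (4, 256), (4, 512), (4, 512)),
        trainable_from=trainable_from,
    )


def smallnet(input_size: tuple[int, int] = (64, 64), trainable_from: int = 2) -> BackboneSpec:
    return BackboneSpec(
        name="smallnet",
        input_size=input_size,
        in_channels=1,
        blocks=((1, 8), (1, 16), (1, 32)),
        trainable_from=trainable_from,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the fine-tuning loop; ``seed`` fully determines
    weight initialisation, the train/validation split and batch order."""

    learning_rate: float = 0.05
    batch_size: int = 16
    epochs: int = 10
    weight_decay: float = 0.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


# ---------------------------------------------------------------- primitives


def _relu6(x: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, 0.0), R_MAX)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 2-D convolution; x (H,W,Cin), w (k,k,Cin,Cout)."""
    k = w.shape[0]
    r = (k - 1) // 2
    h, wd, cin = x.shape
    cout = w.shape[3]
    xp = np.pad(x, ((r, r), (r, r), (0, 0)))
    out = np.zeros((h * wd, cout))
    for ky in range(k):
        for kx in range(k):
            win = xp[ky : ky + h, kx : kx + wd].reshape(h * wd, cin)
            out += win @ w[ky, kx]
    return out.reshape(h, wd, cout) + b


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray, need_dx: bool
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    k = w.shape[0]
    r = (k - 1) // 2
    h, wd, cin = x.shape
    cout = w.shape[3]
    xp = np.pad(x, ((r, r), (r, r), (0, 0)))
    dflat = dout.reshape(h * wd, cout)
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp) if need_dx else None
    for ky in range(k):
        for kx in range(k):
            win = xp[ky : ky + h, kx : kx + wd].reshape(h * wd, cin)
            dw[ky, kx] = win.T @ dflat
            if need_dx:
                dxp[ky : ky + h, kx : kx + wd] += (dflat @ w[ky, kx].T).reshape(h, wd, cin)
    db = dflat.sum(axis=0)
    dx = dxp[r : r + h, r : r + wd] if need_dx else None
    return dx, dw, db


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h, w, c = x.shape
    tiles = x.reshape(h // 2, 2, w // 2, 2, c).transpose(0, 2, 1, 3, 4).reshape(h // 2, w // 2, 4, c)
    idx = tiles.argmax(axis=2)
    out = np.take_along_axis(tiles, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, in_shape: tuple[int, int, int]) -> np.ndarray:
    h, w, c = in_shape
    tiles = np.zeros((h // 2, w // 2, 4, c))
    np.put_along_axis(tiles, idx[:, :, None, :], dout[:, :, None, :], axis=2)
    return tiles.reshape(h // 2, w // 2, 2, 2, c).transpose(0, 2, 1, 3, 4).reshape(h, w, c)


# ------------------------------------------------------------------ network


class Backbone:
    """A concrete network: architecture spec plus weights.

    Weights are He-initialised from ``seed``; biases start at zero, so an
    all-zero input maps to an all-zero feature map.
    """

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.weights: list[list[tuple[np.ndarray, np.ndarray]]] = []
        cin = spec.in_channels
        for n_convs, cout in spec.blocks:
            block = []
            for _ in range(n_convs):
                fan_in = 9 * cin
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, cin, cout))
                block.append((w, np.zeros(cout)))
                cin = cout
            self.weights.append(block)

    # -- forward -------------------------------------------------------

    def _prepare_input(self, image: np.ndarray) -> np.ndarray:
        img = validate_gray(image)
        if img.shape != self.spec.input_size:
            raise ValueError(f"expected input {self.spec.input_size}, got {img.shape}")
        return np.repeat(img[:, :, None], self.spec.in_channels, axis=2)

    def _forward_block(self, x: np.ndarray, block_idx: int, cache: list | None = None):
        for w, b in self.weights[block_idx]:
            pre = _conv_forward(x, w, b)
            if cache is not None:
                cache.append(("conv", x, w, pre))
            x = _relu6(pre)
        out, idx = _pool_forward(x)
        if cache is not None:
            cache.append(("pool", idx, x.shape))
        return out

    def forward_features(self, image: np.ndarray) -> np.ndarray:
        """Run the full feature extractor; returns the pooled H'xW'xC map."""
        x = self._prepare_input(image)
        for i in range(len(self.weights)):
            x = self._forward_block(x, i)
        return x

    def forward_frozen(self, image: np.ndarray) -> np.ndarray:
        """Forward through the frozen prefix only (blocks before trainable_from)."""
        x = self._prepare_input(image)
        for i in range(self.spec.trainable_from):
            x = self._forward_block(x, i)
        return x

    def forward_trainable(self, frozen_out: np.ndarray, cache: list | None = None) -> np.ndarray:
        x = frozen_out
        for i in range(self.spec.trainable_from, len(self.weights)):
            x = self._forward_block(x, i, cache)
        return x

    # -- backward ------------------------------------------------------

    def backward_trainable(self, cache: list, dout: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients for the trainable blocks' conv layers, in layer order."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        d = dout
        for j in range(len(cache) - 1, -1, -1):
            entry = cache[j]
            if entry[0] == "pool":
                _, idx, in_shape = entry
                d = _pool_backward(d, idx, in_shape)
            else:
                _, x_in, w, pre = entry
                d = d * ((pre > 0.0) & (pre < R_MAX))
                need_dx = j > 0
                dx, dw, db = _conv_backward(x_in, w, d, need_dx)
                grads.append((dw, db))
                d = dx
        grads.reverse()
        return grads

    def trainable_params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for i in range(self.spec.trainable_from, len(self.weights)):
            out.extend(self.weights[i])
        return out

    def set_trainable_params(self, params: Sequence[tuple[np.ndarray, np.ndarray]]) -> None:
        it = iter(params)
        for i in range(self.spec.trainable_from, len(self.weights)):
            self.weights[i] = [next(it) for _ in self.weights[i]]


# ----------------------------------------------------------------- training


@dataclass
class TrainedModel:
    """A fine-tuned backbone plus its dense softmax head."""

    backbone: Backbone
    head_w: np.ndarray
    head_b: np.ndarray
    classes: tuple[str, ...]
    membership: MembershipParams
    val_accuracy: float

    def predict_proba(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = extract_cnn_features(self.backbone, images, self.membership)
        logits = feats @ self.head_w + self.head_b
        return _softmax(logits)

    def predict(self, images: Sequence[np.ndarray]) -> list[str]:
        proba = self.predict_proba(images)
        return [self.classes[i] for i in proba.argmax(axis=1)]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train(
    spec: BackboneSpec,
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    config: TrainConfig,
    membership: MembershipParams | None = None,
    val_fraction: float = 0.2,
) -> TrainedModel:
    """Fine-tune a backbone on labelled images.

    Only the blocks at/after ``spec.trainable_from`` and the dense head are
    updated (plain SGD with weight decay, cross-entropy loss, optional
    dropout on the fuzzy features). The frozen prefix is evaluated once per
    image and cached. Returns the trained model with its held-out
    validation accuracy, the fitness signal for hyperparameter search.
    """
    if membership is None:
        membership = MembershipParams()
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels)))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    y = np.array([classes.index(l) for l in labels])

    rng = np.random.default_rng(config.seed)
    net = Backbone(spec, seed=config.seed)
    c_feat = 3 * spec.channels_out
    head_w = rng.normal(0.0, 1.0 / np.sqrt(c_feat), size=(c_feat, len(classes)))
    head_b = np.zeros(len(classes))

    frozen = [net.forward_frozen(im) for im in images]
    train_idx, val_idx = _stratified_split(y, val_fraction, rng)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("dataset too small for a train/validation split")

    lr, wd = config.learning_rate, config.weight_decay
    for _epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads_w = [(np.zeros_like(w), np.zeros_like(b)) for w, b in net.trainable_params()]
            g_hw = np.zeros_like(head_w)
            g_hb = np.zeros_like(head_b)
            loss = 0.0
            for i in batch:
                cache: list = []
                fmap = net.forward_trainable(frozen[i], cache)
                feats, masks = fuzzy_forward_with_masks(fmap, membership)
                if config.dropout > 0.0:
                    keep = (rng.random(feats.shape) >= config.dropout) / (1.0 - config.dropout)
                    feats_d = feats * keep
                else:
                    keep = None
                    feats_d = feats
                logits = feats_d @ head_w + head_b
                p = _softmax(logits[None, :])[0]
                with np.errstate(divide="ignore"):
                    loss -= float(np.log(p[y[i]]))
                dlogit = p.copy()
                dlogit[y[i]] -= 1.0
                g_hw += np.outer(feats_d, dlogit)
                g_hb += dlogit
                dfeat = head_w @ dlogit
                if keep is not None:
                    dfeat = dfeat * keep
                # mean-of-maxima backward: gradient splits evenly over the
                # selected spatial positions of each (function, channel) pair
                h, w_, c = fmap.shape
                dmap = np.zeros((h * w_, c))
                m = masks.reshape(3, h * w_, c)
                dblocks = dfeat.reshape(3, c)
                for b3 in range(3):
                    counts = m[b3].sum(axis=0)
                    dmap += m[b3] * (dblocks[b3] / counts)
                grads = net.backward_trainable(cache, dmap.reshape(h, w_, c))
                for gacc, g in zip(grads_w, grads):
                    gacc[0][...] += g[0]
                    gacc[1][...] += g[1]
            if not np.isfinite(loss):
                raise TrainingDivergence(f"non-finite loss under config {config}")
            nb = len(batch)
            params = net.trainable_params()
            new_params = []
            for (w, b), (gw, gb) in zip(params, grads_w):
                new_params.append((w - lr * (gw / nb + wd * w), b - lr * gb / nb))
            net.set_trainable_params(new_params)
            head_w = head_w - lr * (g_hw / nb + wd * head_w)
            head_b = head_b - lr * g_hb / nb

    # validation accuracy on the held-out split
    correct = 0
    for i in val_idx:
        fmap = net.forward_trainable(frozen[i])
        feats = fuzzy_forward(fmap, membership)
        logits = feats @ head_w + head_b
        correct += int(np.argmax(logits) == y[i])
    val_acc = correct / len(val_idx)
    return TrainedModel(net, head_w, head_b, classes, membership, val_acc)


def extract_cnn_features(
    backbone: Backbone,
    images: Sequence[np.ndarray],
    membership: MembershipParams | None = None,
) -> np.ndarray:
    """Per-image fuzzy features: forward pass then fuzzification, row-aligned
    with the input order. Works with trained or randomly initialised weights."""
    if membership is None:
        membership = MembershipParams()
    rows = [fuzzy_forward(backbone.forward_features(im), membership) for im in images]
    return np.vstack(rows)
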