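"""Embedded image-contrast convolutional discrimination.

Instead of learning group labels from single images, the discriminator is
trained on *contrasts*: absolute pixel-difference images of ordered pairs,
labelled same-group or different-group.  With n images there are n(n-1)
ordered contrasts, which multiplies the effective training-set size by two
orders of magnitude for museum-scale samples.  A trained model identifies a
single raw image by aggregating its same-group probability against reference
images of each group.

The network is a small LeNet-5 variant (two 4x4 convolution stages of 10 and
20 maps, each followed by a ramp nonlinearity and 2x2 pooling, then a linear
map to 2 outputs).  At the default 28 x 28 input the layer tensors are
10x25x25 -> 10x12x12 -> 20x9x9 -> 20x4x4 -> flatten 320 -> 2; a 40 x 40
input is also supported (flatten 980).  Training is plain seeded SGD on a
softmax cross-entropy objective; the implementation is pure numpy, which is
adequate at this scale, and bitwise deterministic for a given seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .discriminant import ConfusionSummary, confusion_counts
from .images import WingImage, downsample_thumbnail


class DegenerateLabelsError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastPair:
    """An ordered image pair with its same/different-group relation."""

    index_a: int
    index_b: int
    relation: str          # 'within-group' or 'between-group'
    group_a: str
    group_b: str

    def __post_init__(self):
        if self.index_a == self.index_b:
            raise ValueError("contrast requires two distinct images")
        expected = "within-group" if self.group_a == self.group_b else "between-group"
        if self.relation != expected:
            raise ValueError("relation inconsistent with group labels")


@dataclass
class TrainingSchedule:
    """Epoch/iteration/batch bookkeeping for contrast training.

    ``iterations_per_epoch`` defaults (at train time) to
    ceil(replication * n_contrasts / batch_size) with replication 3, which
    reconstructs the published per-round contrast consumption; override it
    for reduced schedules.
    """

    epochs: int = 3
    iterations_per_epoch: int | None = None
    batch_size: int = 64
    shuffle_between_epochs: bool = True
    replication: int = 3
    seed: int = 0

    def contrasts_per_epoch(self, n_contrasts: int | None = None) -> int:
        it = self.resolved_iterations(n_contrasts)
        return it * self.batch_size

    def total_contrasts(self, n_contrasts: int | None = None) -> int:
        return self.epochs * self.contrasts_per_epoch(n_contrasts)

    def resolved_iterations(self, n_contrasts: int | None = None) -> int:
        if self.iterations_per_epoch is not None:
            return self.iterations_per_epoch
        if n_contrasts is None:
            raise ValueError("n_contrasts needed to resolve iterations")
        return math.ceil(self.replication * n_contrasts / self.batch_size)


@dataclass(frozen=True)
class CnnSpec:
    """LeNet-5 layer specification."""

    input_side: int = 28
    conv_channels: tuple[int, int] = (10, 20)
    kernel: int = 4
    pool: int = 2
    n_outputs: int = 2

    def layer_shapes(self) -> list[tuple]:
        s = self.input_side
        if s < 12:
            raise ValueError("input side too small for the kernel arithmetic")
        shapes: list[tuple] = [(1, s, s)]
        c_prev = 1
        for c in self.conv_channels:
            s = s - self.kernel + 1
            if s < 1:
                raise ValueError("input side too small for the kernel arithmetic")
            shapes.append((c, s, s))            # convolution
            shapes.append((c, s, s))            # ramp
            s = s // self.pool
            if s < 1:
                raise ValueError("input side too small for the pool arithmetic")
            shapes.append((c, s, s))            # pooling
            c_prev = c
        shapes.append((c_prev * s * s,))        # flatten
        shapes.append((self.n_outputs,))        # linear
        shapes.append((self.n_outputs,))        # output
        return shapes

    @property
    def flatten_size(self) -> int:
        return int(np.prod(self.layer_shapes()[-3]))


# ---------------------------------------------------------------------------
# numpy LeNet

def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H'*W', C*k*k) patch matrix (valid convolution)."""
    win = np.lib.stride_tricks.sliding_window_view(X, (k, k), axis=(2, 3))
    n, c, hh, ww = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hh * ww, c * k * k), (n, hh, ww, c)


class LeNet:
    """Minimal LeNet-5 variant with explicit forward/backward passes."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        shapes = spec.layer_shapes()
        c1, c2 = spec.conv_channels
        k = spec.kernel
        rng = np.random.default_rng(seed)
        he = lambda fan_in, *shape: rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self.W1 = he(k * k, c1, 1, k, k)
        self.b1 = np.zeros(c1)
        self.W2 = he(c1 * k * k, c2, c1, k, k)
        self.b2 = np.zeros(c2)
        flat = spec.flatten_size
        self.W3 = he(flat, flat, spec.n_outputs)
        self.b3 = np.zeros(spec.n_outputs)

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    # -- forward ----------------------------------------------------------
    def _conv_forward(self, X, W, b):
        k = W.shape[-1]
        cols, (n, hh, ww, c) = _im2col(X, k)
        Wm = W.reshape(W.shape[0], -1)
        out = cols @ Wm.T + b
        out = out.reshape(n, hh, ww, W.shape[0]).transpose(0, 3, 1, 2)
        return out, cols

    def _pool_forward(self, X):
        p = self.spec.pool
        n, c, h, w = X.shape
        h2, w2 = (h // p) * p, (w // p) * p
        Xc = X[:, :, :h2, :w2].reshape(n, c, h2 // p, p, w2 // p, p)
        Xc = Xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 // p, w2 // p, p * p)
        arg = Xc.argmax(axis=-1)
        out = np.take_along_axis(Xc, arg[..., None], axis=-1)[..., 0]
        return out, (arg, (h, w))

    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (N, side, side) in [0, 1] -> logits (N, n_outputs)."""
        X = X[:, None, :, :]
        z1, col1 = self._conv_forward(X, self.W1, self.b1)
        a1 = np.maximum(z1, 0.0)
        p1, pc1 = self._pool_forward(a1)
        z2, col2 = self._conv_forward(p1, self.W2, self.b2)
        a2 = np.maximum(z2, 0.0)
        p2, pc2 = self._pool_forward(a2)
        flat = p2.reshape(len(X), -1)
        logits = flat @ self.W3 + self.b3
        if cache:
            self._cache = (X, col1, z1, a1.shape, pc1, p1, col2, z2, a2.shape, pc2, p2, flat)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.forward(X)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- backward ---------------------------------------------------------
    def _conv_backward(self, dout, cols, X_shape, W):
        n, o, hh, ww = dout.shape
        k = W.shape[-1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, o)
        dW = (dflat.T @ cols).reshape(W.shape)
        db = dflat.sum(axis=0)
        dcols = dflat @ W.reshape(o, -1)
        dX = np.zeros(X_shape)
        c_in = X_shape[1]
        dcols = dcols.reshape(n, hh, ww, c_in, k, k)
        for i in range(k):
            for j in range(k):
                dX[:, :, i:i + hh, j:j + ww] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dW, db, dX

    def _pool_backward(self, dout, pool_cache, in_shape):
        p = self.spec.pool
        arg, (h, w) = pool_cache
        n, c, hp, wp = dout.shape
        dXc = np.zeros((n, c, hp, wp, p * p))
        np.put_along_axis(dXc, arg[..., None], dout[..., None], axis=-1)
        dXc = dXc.reshape(n, c, hp, wp, p, p).transpose(0, 1, 2, 4, 3, 5)
        dX = np.zeros(in_shape)
        dX[:, :, :hp * p, :wp * p] = dXc.reshape(n, c, hp * p, wp * p)
        return dX

    def train_batch(self, X: np.ndarray, y: np.ndarray, lr: float = 0.01) -> float:
        """One SGD step on a batch; returns the mean cross-entropy loss."""
        n = len(X)
        logits = self.forward(X, cache=True)
        (Xi, col1, z1, a1s, pc1, p1, col2, z2, a2s, pc2, p2, flat) = self._cache
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        dW3 = flat.T @ dlogits
        db3 = dlogits.sum(axis=0)
        dflat = dlogits @ self.W3.T
        dp2 = dflat.reshape(p2.shape)
        da2 = self._pool_backward(dp2, pc2, a2s)
        dz2 = da2 * (z2 > 0)
        dW2, db2, dp1 = self._conv_backward(dz2, col2, p1.shape, self.W2)
        da1 = self._pool_backward(dp1, pc1, a1s)
        dz1 = da1 * (z1 > 0)
        dW1, db1, _ = self._conv_backward(dz1, col1, Xi.shape, self.W1)

        for p_, g in zip(self.parameters(), [dW1, db1, dW2, db2, dW3, db3]):
            p_ -= lr * g
        return loss


def build_cnn(spec: CnnSpec | None = None, seed: int = 0) -> LeNet:
    """Initialize a LeNet with seeded weights; shape errors surface here."""
    spec = spec or CnnSpec()
    spec.layer_shapes()   # validates the kernel/pool arithmetic
    return LeNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# contrasts

def enumerate_contrasts(labels) -> list[ContrastPair]:
    """All ordered pairs (i, j), i != j, tagged within/between group; the
    count is n(n-1)."""
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("at least 2 images required")
    pairs = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rel = "within-group" if labels[i] == labels[j] else "between-group"
            pairs.append(ContrastPair(i, j, rel, str(labels[i]), str(labels[j])))
    return pairs


def make_contrast_input(image_a: np.ndarray, image_b: np.ndarray) -> np.ndarray:
    """Per-pixel absolute brightness difference, rescaled to [0, 1]."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("contrast images must share a size")
    return np.abs(a - b) / 255.0


def _thumbnails(images, side: int) -> np.ndarray:
    out = []
    for im in images:
        px = im.pixels if isinstance(im, WingImage) else np.asarray(im)
        if px.shape != (side, side):
            px = downsample_thumbnail(px, (side, side))
        out.append(px.astype(float))
    return np.stack(out)


@dataclass
class TrainedContrastModel:
    net: LeNet
    spec: CnnSpec
    schedule: TrainingSchedule
    loss_trace: list = field(default_factory=list)     # mean loss per epoch
    thumbnail_side: int = 28


def train(contrasts: list[ContrastPair], images, schedule: TrainingSchedule,
          spec: CnnSpec | None = None, lr: float = 0.01) -> TrainedContrastModel:
    """Train the contrast discriminator (class 0 = same group, 1 = different).

    Each epoch consumes iterations_per_epoch x batch_size contrasts drawn by
    cycling seeded random permutations of the contrast list; the order
    reshuffles between epochs.  Deterministic given ``schedule.seed``.
    """
    spec = spec or CnnSpec()
    rels = {c.relation for c in contrasts}
    if len(rels) < 2:
        raise DegenerateLabelsError("need both within- and between-group contrasts")
    thumbs = _thumbnails(images, spec.input_side)
    ia = np.array([c.index_a for c in contrasts])
    ib = np.array([c.index_b for c in contrasts])
    yy = np.array([0 if c.relation == "within-group" else 1 for c in contrasts])

    rng = np.random.default_rng(schedule.seed)
    net = build_cnn(spec, seed=int(rng.integers(2 ** 31)))
    iters = schedule.resolved_iterations(len(contrasts))
    trace = []
    order = rng.permutation(len(contrasts))
    for _epoch in range(schedule.epochs):
        if schedule.shuffle_between_epochs:
            order = rng.permutation(len(contrasts))
        needed = iters * schedule.batch_size
        reps = math.ceil(needed / len(order))
        seq = np.tile(order, reps)[:needed]
        losses = np.empty(iters)
        for it in range(iters):
            sel = seq[it * schedule.batch_size:(it + 1) * schedule.batch_size]
            X = np.abs(thumbs[ia[sel]] - thumbs[ib[sel]]) / 255.0
            losses[it] = net.train_batch(X, yy[sel], lr=lr)
        trace.append(float(losses.mean()))
    return TrainedContrastModel(net=net, spec=spec, schedule=schedule,
                                loss_trace=trace, thumbnail_side=spec.input_side)


def contrast_accuracy(model: TrainedContrastModel, contrasts, images) -> float:
    """Post-hoc same/different classification accuracy over contrasts."""
    thumbs = _thumbnails(images, model.spec.input_side)
    ia = np.array([c.index_a for c in contrasts])
    ib = np.array([c.index_b for c in contrasts])
    yy = np.array([0 if c.relation == "within-group" else 1 for c in contrasts])
    correct = 0
    for start in range(0, len(contrasts), 256):
        sel = slice(start, start + 256)
        X = np.abs(thumbs[ia[sel]] - thumbs[ib[sel]]) / 255.0
        pred = model.net.predict_proba(X).argmax(axis=1)
        correct += int((pred == yy[sel]).sum())
    return correct / len(contrasts)


def identify(model: TrainedContrastModel, query, references, ref_groups):
    """Identify a single image against grouped references.

    score = mean P(same | query, ref in A) - mean P(same | query, ref in B);
    assign group A on score > 0, B on score < 0, and A (with a warning) on an
    exact tie.  Groups are taken in sorted label order.
    """
    ref_groups = np.asarray([str(g) for g in ref_groups])
    groups = sorted(set(ref_groups))
    if len(groups) != 2 or any((ref_groups == g).sum() == 0 for g in groups):
        raise ValueError("references must cover exactly two non-empty groups")
    thumbs = _thumbnails(references, model.spec.input_side)
    q = _thumbnails([query], model.spec.input_side)[0]
    X = np.abs(thumbs - q[None]) / 255.0
    p_same = model.net.predict_proba(X)[:, 0]
    mean_a = p_same[ref_groups == groups[0]].mean()
    mean_b = p_same[ref_groups == groups[1]].mean()
    score = float(mean_a - mean_b)
    if score == 0.0:
        warnings.warn("identification tie; assigning first group")
        return groups[0], score
    return (groups[0] if score > 0 else groups[1]), score


def save_checkpoint(path, model: TrainedContrastModel) -> None:
    """Persist a trained model: layer spec, schedule seed and parameters in
    a single ``.npz`` container."""
    np.savez(path,
             input_side=model.spec.input_side,
             conv_channels=np.array(model.spec.conv_channels),
             kernel=model.spec.kernel, pool=model.spec.pool,
             n_outputs=model.spec.n_outputs,
             seed=model.schedule.seed,
             loss_trace=np.array(model.loss_trace),
             W1=model.net.W1, b1=model.net.b1,
             W2=model.net.W2, b2=model.net.b2,
             W3=model.net.W3, b3=model.net.b3)


def load_checkpoint(path) -> TrainedContrastModel:
    z = np.load(path)
    spec = CnnSpec(input_side=int(z["input_side"]),
                   conv_channels=tuple(int(c) for c in z["conv_channels"]),
                   kernel=int(z["kernel"]), pool=int(z["pool"]),
                   n_outputs=int(z["n_outputs"]))
    net = LeNet(spec, seed=0)
    net.W1, net.b1 = z["W1"], z["b1"]
    net.W2, net.b2 = z["W2"], z["b2"]
    net.W3, net.b3 = z["W3"], z["b3"]
    schedule = TrainingSchedule(seed=int(z["seed"]))
    return TrainedContrastModel(net=net, spec=spec, schedule=schedule,
                                loss_trace=list(z["loss_trace"]),
                                thumbnail_side=spec.input_side)


class ContrastCNNClassifier:
    """sklearn-style wrapper: fit on labelled images (training the contrast
    network on all their pairwise contrasts), predict single images by
    reference aggregation against the training set.

    Parameters mirror :class:`TrainingSchedule`; ``get_params``/``set_params``
    follow the sklearn contract via explicit __init__ arguments.
    """

    def __init__(self, epochs: int = 3, iterations_per_epoch: int | None = None,
                 batch_size: int = 64, input_side: int = 28, lr: float = 0.01,
                 seed: int = 0):
        self.epochs = epochs
        self.iterations_per_epoch = iterations_per_epoch
        self.batch_size = batch_size
        self.input_side = input_side
        self.lr = lr
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("epochs", "iterations_per_epoch", "batch_size",
                 "input_side", "lr", "seed")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, images, y):
        labels = [str(l) for l in y]
        schedule = TrainingSchedule(epochs=self.epochs,
                                    iterations_per_epoch=self.iterations_per_epoch,
                                    batch_size=self.batch_size, seed=self.seed)
        contrasts = enumerate_contrasts(labels)
        spec = CnnSpec(input_side=self.input_side)
        self.model_ = train(contrasts, images, schedule, spec, lr=self.lr)
        self.train_images_ = list(images)
        self.train_labels_ = np.asarray(labels)
        self.classes_ = np.array(sorted(set(labels)))
        return self

    def decision_function(self, images) -> np.ndarray:
        return np.array([identify(self.model_, im, self.train_images_,
                                  self.train_labels_)[1] for im in images])

    def predict(self, images) -> np.ndarray:
        return np.array([identify(self.model_, im, self.train_images_,
                                  self.train_labels_)[0] for im in images])


def cnn_jackknife(images, labels, schedule: TrainingSchedule,
                  spec: CnnSpec | None = None, n_targets: int = 25,
                  seed: int | None = None, lr: float = 0.01) -> ConfusionSummary:
    """Jackknife stability check: for each of ``n_targets`` randomly chosen
    images, retrain on all contrasts not touching it and identify it against
    the remaining images.  Target selection and each fold's training are
    seeded, so the whole procedure is deterministic."""
    labels = np.asarray([str(l) for l in labels])
    n = len(labels)
    if n_targets > n:
        raise ValueError("n_targets exceeds the sample size")
    spec = spec or CnnSpec()
    rng = np.random.default_rng(seed)
    targets = rng.choice(n, size=n_targets, replace=False)
    groups = tuple(sorted(set(labels)))
    truths, preds = [], []
    for fold, t in enumerate(targets):
        keep = np.array([i for i in range(n) if i != t])
        sub_images = [images[i] for i in keep]
        sub_labels = labels[keep]
        contrasts = enumerate_contrasts(sub_labels)
        fold_schedule = TrainingSchedule(
            epochs=schedule.epochs,
            iterations_per_epoch=schedule.iterations_per_epoch,
            batch_size=schedule.batch_size,
            shuffle_between_epochs=schedule.shuffle_between_epochs,
            replication=schedule.replication,
            seed=int(rng.integers(2 ** 31)))
        model = train(contrasts, sub_images, fold_schedule, spec, lr=lr)
        pred, _score = identify(model, images[t], sub_images, sub_labels)
        truths.append(labels[t])
        preds.append(pred)
    counts = confusion_counts(np.array(truths), np.array(preds), groups)
    return ConfusionSummary(counts=counts, groups=groups, mode="jackknife")
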