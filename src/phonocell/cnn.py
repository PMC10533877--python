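"""Shallow LeNet-style CNN for three-class GASF image classification.

The network is the classic two-convolution stack: two conv+max-pool
blocks (defaults 6 and 16 filters of 5x5 with 2x2 pooling), two fully
connected hidden layers (120, 84) and a three-node softmax output,
trained with Adam on cross-entropy.  It is implemented directly in NumPy
(im2col convolutions), which keeps training deterministic under a seed
and fast enough for the GASF image sizes used here (32-64 px).

Splitting is done at the cell level — whole cells go to either the train
or the test partition, stratified so each class and acquisition batch is
equally represented — never at the pixel level, so no pixel of a test
cell can leak into training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .acquisition import ClassLabel

__all__ = ["ModelConfig", "SplitPlan", "Prediction", "LeNet", "make_split",
           "train", "predict", "predict_proba", "save_model", "load_model"]


# ---------------------------------------------------------------------------
# configuration and split plan
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyper-parameters of the shallow CNN.

    ``conv_blocks`` must contain exactly two (filters, kernel, pool)
    triples and ``n_classes`` is fixed at three; both are architectural
    commitments of the classifier, not free knobs.
    """

    conv_blocks: tuple = ((6, 5, 2), (16, 5, 2))
    fc_sizes: tuple = (120, 84)
    n_classes: int = 3
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    rng_seed: int = 0
    val_fraction: float = 0.15
    patience: int = 3
    max_images_per_class: int | None = None

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 2:
            raise ValueError("exactly two convolutional blocks are required")
        if self.n_classes != 3:
            raise ValueError("the classifier has exactly three output classes")
        if len(self.fc_sizes) != 2:
            raise ValueError("exactly two fully connected hidden layers")


@dataclass
class SplitPlan:
    """Cell-level train/test assignment."""

    train_cell_ids: list
    test_cell_ids: list
    fraction_train: float = 0.7
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train_cell_ids) & set(self.test_cell_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class Prediction:
    """Per-image softmax output."""

    probabilities: np.ndarray
    label: ClassLabel
    source: tuple = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be a simplex vector")
        self.probabilities = p


def make_split(cells: Sequence, fraction_train: float = 0.7,
               rng_seed: int | None = None) -> SplitPlan:
    """Stratified cell-level split.

    ``cells`` is a sequence of objects exposing ``cell_id``,
    ``cell_class`` and ``batch_id`` (e.g. PhononScan) or of
    (cell_id, class, batch) triples.  Cells are grouped by (class, batch)
    and each group contributes the same rounded train fraction, so both
    partitions are balanced across classes and acquisition batches.
    """
    if not 0.0 < fraction_train < 1.0:
        raise ValueError("fraction_train must be in (0, 1)")
    entries = []
    for c in cells:
        if hasattr(c, "cell_id"):
            entries.append((c.cell_id, ClassLabel(c.cell_class), c.batch_id))
        else:
            cid, cls, batch = c
            entries.append((cid, ClassLabel(cls), batch))
    groups: dict[tuple, list] = {}
    for cid, cls, batch in entries:
        groups.setdefault((cls, batch), []).append(cid)
    sizes = {k: len(v) for k, v in groups.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(
            "cannot balance split: unequal cells per (class, batch) group: "
            + ", ".join(f"{k[0].name}/batch{k[1]}={v}" for k, v in sorted(sizes.items())))
    size = next(iter(sizes.values()))
    n_train = round(fraction_train * size)
    if n_train < 1 or n_train >= size:
        raise ValueError(
            f"fraction_train={fraction_train} leaves an empty partition for "
            f"groups of {size} cell(s)")
    rng = np.random.default_rng(rng_seed)
    train_ids, test_ids = [], []
    for key in sorted(groups, key=lambda k: (int(k[0]), k[1])):
        ids = sorted(groups[key])
        perm = rng.permutation(len(ids))
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:]]
    return SplitPlan(sorted(train_ids), sorted(test_ids), fraction_train, rng_seed)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv:
    """5x5-style valid convolution, stride 1, via im2col GEMMs.

    Large intermediates (patch matrix, transposed activations, gradients)
    are kept as persistent per-layer buffers so the training loop does not
    cycle tens of MB through the allocator every minibatch.
    ``first_layer`` skips the input-gradient computation, which the
    network's first convolution never needs.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 first_layer: bool = False):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.first_layer = first_layer
        self._bufs: dict = {}

    def _buf(self, name: str, shape) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = self._bufs[name] = np.empty(shape, dtype=np.float32)
        return buf

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.k
        self._x_shape = x.shape
        hp = self._hp = h - k + 1
        wp = self._wp = w - k + 1
        xt = self._buf("xt", (c, b, h, w))
        np.copyto(xt, x.transpose(1, 0, 2, 3))
        cols = self._buf("cols", (c * k * k, b * hp * wp))
        cols6 = cols.reshape(c, k, k, b, hp, wp)
        for i in range(k):
            for j in range(k):
                cols6[:, i, j] = xt[:, :, i:i + hp, j:j + wp]
        self._cols = cols
        wmat = self.w.reshape(self.c_out, -1)
        y = self._buf("y", (self.c_out, b * hp * wp))
        np.matmul(wmat, cols, out=y)
        y += self.b[:, None]
        out = self._buf("out", (b, self.c_out, hp, wp))
        np.copyto(out, y.reshape(self.c_out, b, hp, wp).transpose(1, 0, 2, 3))
        return out

    def backward(self, dy: np.ndarray):
        b = dy.shape[0]
        k, hp, wp = self.k, self._hp, self._wp
        dyf = self._buf("dyf", (self.c_out, b * hp * wp))
        np.copyto(dyf.reshape(self.c_out, b, hp, wp), dy.transpose(1, 0, 2, 3))
        self.dw = (dyf @ self._cols.T).reshape(self.w.shape)
        self.db = dyf.sum(axis=1)
        if self.first_layer:
            return None
        wmat = self.w.reshape(self.c_out, -1)
        dcols = self._buf("dcols", (self.c_in * k * k, b * hp * wp))
        np.matmul(wmat.T, dyf, out=dcols)
        dcols6 = dcols.reshape(self.c_in, k, k, b, hp, wp)
        _, _, h, w = self._x_shape
        dxt = self._buf("dxt", (self.c_in, b, h, w))
        dxt[:] = 0.0
        for i in range(k):
            for j in range(k):
                dxt[:, :, i:i + hp, j:j + wp] += dcols6[:, i, j]
        dx = self._buf("dx", self._x_shape)
        np.copyto(dx, dxt.transpose(1, 0, 2, 3))
        return dx

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    @property
    def grads(self):
        return {"w": self.dw, "b": self.db}


class _Pool:
    """Non-overlapping max pooling (odd trailing rows/cols are cropped)."""

    def __init__(self, size: int):
        self.s = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.s
        b, c, h, w = x.shape
        h2, w2 = h // s, w // s
        self._in_shape = x.shape
        xc = x[:, :, :h2 * s, :w2 * s]
        xr = xc.reshape(b, c, h2, s, w2, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h2, w2, s * s)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.s
        b, c, h, w = self._in_shape
        h2, w2 = h // s, w // s
        dxr = np.zeros((b, c, h2, w2, s * s), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, :h2 * s, :w2 * s] = dxr.reshape(
            b, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h2 * s, w2 * s)
        return dx


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, math.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        dx = dy @ self.w.T
        self._x = None
        return dx

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    @property
    def grads(self):
        return {"w": self.dw, "b": self.db}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class LeNet:
    """Two conv+pool blocks, two hidden FC layers, three-way softmax."""

    def __init__(self, config: ModelConfig, input_side: int):
        self.config = config
        self.input_side = int(input_side)
        rng = np.random.default_rng(config.rng_seed)
        (f1, k1, p1), (f2, k2, p2) = config.conv_blocks
        side = input_side
        side = (side - k1 + 1)
        side = side // p1
        side = (side - k2 + 1)
        side = side // p2
        if side < 1:
            raise ValueError(f"input side {input_side} too small for the "
                             "configured conv/pool stack")
        self.conv1 = _Conv(1, f1, k1, rng, first_layer=True)
        self.pool1 = _Pool(p1)
        self.conv2 = _Conv(f1, f2, k2, rng)
        self.pool2 = _Pool(p2)
        self.relu1, self.relu2 = _ReLU(), _ReLU()
        self.relu3, self.relu4 = _ReLU(), _ReLU()
        self.flat_dim = f2 * side * side
        h1, h2 = config.fc_sizes
        self.fc1 = _Dense(self.flat_dim, h1, rng)
        self.fc2 = _Dense(h1, h2, rng)
        self.fc3 = _Dense(h2, config.n_classes, rng)
        self._layers = [self.conv1, self.conv2, self.fc1, self.fc2, self.fc3]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of images (B, side, side)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.pool1.forward(h)
        h = self.relu2.forward(self.conv2.forward(h))
        h = self.pool2.forward(h)
        self._conv_out_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relu3.forward(self.fc1.forward(h))
        h = self.relu4.forward(self.fc2.forward(h))
        return self.fc3.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc3.backward(dlogits)
        d = self.fc2.backward(self.relu4.backward(d))
        d = self.fc1.backward(self.relu3.backward(d))
        d = d.reshape(self._conv_out_shape)
        d = self.pool2.backward(d)
        d = self.conv2.backward(self.relu2.backward(d))
        d = self.pool1.backward(d)
        self.conv1.backward(self.relu1.backward(d))

    def parameters(self):
        for i, layer in enumerate(self._layers):
            for name, p in layer.params.items():
                yield f"l{i}.{name}", layer, name, p

    def state_dict(self) -> dict:
        return {key: p.copy() for key, _, _, p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self._layers):
            layer.w = state[f"l{i}.w"].copy()
            layer.b = state[f"l{i}.b"].copy()


class _Adam:
    def __init__(self, model: LeNet, lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, b1, b2, eps
        self.m = {k: np.zeros_like(p) for k, _, _, p in model.parameters()}
        self.v = {k: np.zeros_like(p) for k, _, _, p in model.parameters()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for key, layer, name, p in self.model.parameters():
            g = layer.grads[name]
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _balanced_subsample(labels: np.ndarray, batch_ids: np.ndarray,
                        per_class: int | None,
                        rng: np.random.Generator) -> np.ndarray:
    """Indices balanced across classes, spread evenly over batches."""
    idx_out = []
    classes = np.unique(labels)
    n_per = per_class
    if n_per is None:
        n_per = min(int((labels == c).sum()) for c in classes)
    for c in classes:
        sel = np.flatnonzero(labels == c)
        batches = np.unique(batch_ids[sel])
        quota = max(n_per // len(batches), 1)
        chosen = []
        for b in batches:
            pool = sel[batch_ids[sel] == b]
            take = min(quota, pool.size)
            chosen.append(rng.choice(pool, size=take, replace=False))
        chosen = np.concatenate(chosen)
        if chosen.size > n_per:
            chosen = rng.choice(chosen, size=n_per, replace=False)
        idx_out.append(chosen)
    return np.concatenate(idx_out)


def train(dataset, split: SplitPlan, cfg: ModelConfig | None = None,
          verbose: bool = False):
    """Train the CNN on the train-cell images of ``dataset``.

    ``dataset`` must expose ``images`` (N, S, S), ``labels`` (N,),
    ``cell_ids`` (N,) and ``batch_ids`` (N,) (see
    :class:`phonocell.dataset.GasfDataset`).  A validation slice is
    carved from *training* cells for early stopping; test cells are never
    touched.  Returns ``(model, log)`` where ``log`` is a list of
    per-epoch dicts (epoch, train_loss, train_acc, val_acc).
    """
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    cell_ids = np.asarray(dataset.cell_ids)
    labels = np.asarray(dataset.labels)
    batch_ids = np.asarray(dataset.batch_ids)

    known = set(np.unique(cell_ids))
    for cid in list(split.train_cell_ids) + list(split.test_cell_ids):
        if cid not in known:
            raise ValueError(f"cell {cid!r} in split has no images in dataset")

    train_cells = sorted(split.train_cell_ids)
    # validation cells: a slice of training cells, stratified by cell class
    # so neither partition of the training cells loses a class
    cell_class = {}
    for cid in train_cells:
        labs = labels[cell_ids == cid]
        non_bg = labs[labs != 2]
        cell_class[cid] = int(non_bg[0]) if non_bg.size else 2
    n_val = max(int(round(cfg.val_fraction * len(train_cells))), 2)
    by_class: dict[int, list] = {}
    for cid in train_cells:
        by_class.setdefault(cell_class[cid], []).append(cid)
    val_cells: set = set()
    pools = [list(rng.permutation(v)) for v in by_class.values()]
    i = 0
    while len(val_cells) < n_val and any(len(p) > 1 for p in pools):
        pool = pools[i % len(pools)]
        if len(pool) > 1:  # always leave at least one cell per class to fit
            val_cells.add(pool.pop())
        i += 1
    fit_cells = {c for c in train_cells if c not in val_cells}

    in_fit = np.isin(cell_ids, sorted(fit_cells))
    in_val = np.isin(cell_ids, sorted(val_cells))
    fit_idx = np.flatnonzero(in_fit)
    present = np.unique(labels[fit_idx])
    if len(present) < cfg.n_classes:
        raise ValueError(
            f"training set covers only classes {present.tolist()}; "
            "all three classes are required")
    sub = _balanced_subsample(labels[fit_idx], batch_ids[fit_idx],
                              cfg.max_images_per_class, rng)
    fit_idx = fit_idx[sub]
    val_idx = np.flatnonzero(in_val)
    if cfg.max_images_per_class is not None and val_idx.size > 3 * cfg.max_images_per_class // 2:
        val_idx = rng.choice(val_idx, size=3 * cfg.max_images_per_class // 2,
                             replace=False)

    x_fit = np.asarray(dataset.images, dtype=np.float32)[fit_idx]
    y_fit = labels[fit_idx].astype(np.int64)
    x_val = np.asarray(dataset.images, dtype=np.float32)[val_idx]
    y_val = labels[val_idx].astype(np.int64)

    model = LeNet(cfg, input_side=x_fit.shape[-1])
    opt = _Adam(model, cfg.learning_rate)
    n = x_fit.shape[0]
    log = []
    best_val, best_state, stale = -1.0, None, 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        tot_loss, tot_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = x_fit[sel], y_fit[sel]
            logits = model.forward(xb)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits.astype(np.float32))
            opt.step()
            tot_loss += loss * len(yb)
            tot_correct += int((logits.argmax(axis=1) == yb).sum())
        val_acc = float(np.mean(predict_proba(model, x_val).argmax(axis=1) == y_val)) \
            if len(y_val) else float("nan")
        rec = {"epoch": epoch, "train_loss": tot_loss / n,
               "train_acc": tot_correct / n, "val_acc": val_acc}
        log.append(rec)
        if verbose:
            print(f"epoch {epoch:3d}  loss {rec['train_loss']:.4f}  "
                  f"train {rec['train_acc']:.3f}  val {val_acc:.3f}")
        if len(y_val):
            if val_acc > best_val + 1e-4:
                best_val, best_state, stale = val_acc, model.state_dict(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def predict_proba(model: LeNet, images: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Softmax probabilities (N, 3) for a stack of images."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    out = []
    for start in range(0, images.shape[0], batch_size):
        out.append(_softmax(model.forward(images[start:start + batch_size])))
    return np.concatenate(out, axis=0)


def predict(model: LeNet, images: np.ndarray,
            sources: Sequence[tuple] | None = None,
            batch_size: int = 256) -> list[Prediction]:
    """One :class:`Prediction` per input image."""
    probs = predict_proba(model, images, batch_size=batch_size)
    sources = sources or [()] * probs.shape[0]
    return [Prediction(p, ClassLabel(int(p.argmax())), tuple(s))
            for p, s in zip(probs, sources)]


def save_model(model: LeNet, path) -> None:
    """Persist weights plus embedded config (npz + json)."""
    state = model.state_dict()
    meta = json.dumps({"config": asdict(model.config),
                       "input_side": model.input_side})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_model(path) -> LeNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        cfg_dict = meta["config"]
        cfg_dict["conv_blocks"] = tuple(tuple(b) for b in cfg_dict["conv_blocks"])
        cfg_dict["fc_sizes"] = tuple(cfg_dict["fc_sizes"])
        cfg = ModelConfig(**cfg_dict)
        model = LeNet(cfg, input_side=meta["input_side"])
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model
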