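"""Raw-image CNN branch: small convolutional networks on 50x50x3 crops.

The network family stacks 2-5 repeated units ("autoencoders" in the source
tradition of this pipeline, though no reconstruction is involved), each
unit being convolution -> ReLU -> batch normalization -> average pooling,
followed by a fully connected layer and softmax.  Convolutions use "same"
zero padding at stride 1; average pooling uses window = stride =
``pool_size`` with ceiling-mode sizing via edge replication, so the printed
pool sequence 2, 8, 4, 2 on a 50-pixel input is feasible (50 -> 25 -> 4 ->
1 -> 1).  Training is full backpropagation with RMSProp at a constant
learning rate.

Everything here is plain NumPy: forward, backward and the optimizer are
implemented in-repo, which keeps seeded runs bit-reproducible on a fixed
thread configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierResult
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split


class ArchitectureError(ValueError):
    """Raised when a network cannot be built from its architecture."""


@dataclass(frozen=True)
class CNNArchitecture:
    """Symbolic description of one candidate network.

    ``stages`` is an ordered tuple of ``(filters, pool_size)`` pairs; all
    convolutions share the square ``conv_kernel``.
    """

    conv_kernel: int
    stages: tuple[tuple[int, int], ...]
    n_classes: int = 7
    input_hw: int = 50
    in_channels: int = 3

    def __post_init__(self) -> None:
        if not 2 <= len(self.stages) <= 5:
            raise ArchitectureError("network depth must be 2-5 stages")
        if self.conv_kernel < 1:
            raise ArchitectureError("conv kernel must be >= 1")
        for i, (f, p) in enumerate(self.stages):
            if f < 1 or p < 1:
                raise ArchitectureError(f"stage {i}: filters and pool must be >= 1")

    @property
    def name(self) -> str:
        fs = ",".join(str(f) for f, _ in self.stages)
        ps = ",".join(str(p) for _, p in self.stages)
        return f"conv{self.conv_kernel}x{self.conv_kernel}[{fs}|pool {ps}]"


#: The nine candidate architectures of the published search: depths 2-5,
#: conv kernels 2-5, channel counts doubling with depth (VGG-style).
DEFAULT_CANDIDATES: tuple[CNNArchitecture, ...] = (
    CNNArchitecture(2, ((32, 2), (64, 8), (128, 4), (256, 2), (256, 1))),
    CNNArchitecture(2, ((32, 2), (64, 8), (128, 4), (256, 2))),
    CNNArchitecture(2, ((32, 2), (64, 8), (128, 4), (128, 2))),
    CNNArchitecture(2, ((32, 2), (64, 8), (128, 4))),
    CNNArchitecture(2, ((32, 2), (64, 8))),
    CNNArchitecture(3, ((32, 2), (64, 8), (128, 4), (256, 2))),
    CNNArchitecture(4, ((32, 2), (64, 8), (128, 4), (256, 2))),
    CNNArchitecture(5, ((32, 2), (64, 8), (128, 4), (256, 2))),
    CNNArchitecture(2, ((16, 1), (32, 4), (64, 2), (128, 1), (128, 1))),
)

#: The selected production architecture: four stages of 32/64/128/256
#: filters, 2x2 convolutions, pools 2, 8, 4, 2.
DEFAULT_ARCHITECTURE = DEFAULT_CANDIDATES[1]


@dataclass(frozen=True)
class TrainConfig:
    """RMSProp training settings (constant learning rate)."""

    learning_rate: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 128
    seed: int = 0
    rho: float = 0.9  # RMSProp decay
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_crop(crop: np.ndarray, size: int = 50) -> np.ndarray:
    """Bicubic resize of an RGB crop straight to ``size x size`` (aspect
    ratio not preserved), scaled to [0, 1] float32."""
    from PIL import Image

    crop = np.asarray(crop)
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ValueError("crop must be an RGB HxWx3 array")
    if crop.shape[0] < 8 or crop.shape[1] < 8:
        raise ValueError("crop smaller than 8x8 pixels")
    img = Image.fromarray(crop.astype(np.uint8))
    out = img.resize((size, size), Image.BICUBIC)
    return np.asarray(out, dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# layers (NHWC throughout)


class Conv2D:
    """Stride-1 convolution with 'same' zero padding."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))  # He initialization
        self.W = rng.normal(0.0, scale, size=(k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k
        self.pb = (k - 1) // 2  # pad before
        self.pa = k // 2  # pad after

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, H, W, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pb, self.pa), (self.pb, self.pa), (0, 0)))
        out = np.broadcast_to(self.b, (N, H, W, self.W.shape[3])).copy()
        for u in range(self.k):
            for v in range(self.k):
                out += xp[:, u : u + H, v : v + W, :] @ self.W[u, v]
        self._xp, self._hw = xp, (H, W)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H, W = self._hw
        xp = self._xp
        self.dW = np.empty_like(self.W)
        self.db = dout.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for u in range(self.k):
            for v in range(self.k):
                sl = xp[:, u : u + H, v : v + W, :]
                self.dW[u, v] = np.tensordot(sl, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, u : u + H, v : v + W, :] += dout @ self.W[u, v].T
        return dxp[:, self.pb : self.pb + H, self.pb : self.pb + W, :]

    def params(self):
        return [(self, "W"), (self, "b")]


class ReLU:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class BatchNorm:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._accum: dict | None = None

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            if self._accum is not None:
                m = x.shape[0] * x.shape[1] * x.shape[2]
                self._accum["n"] += m
                self._accum["sum"] += m * mu
                self._accum["sumsq"] += m * (var + mu**2)
            else:
                self.run_mean = (
                    1 - self.momentum
                ) * self.run_mean + self.momentum * mu
                self.run_var = (
                    1 - self.momentum
                ) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 1, 2))
        self.dbeta = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        return (
            self._istd
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1, 2))
                - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1, 2))
            )
        )

    def params(self):
        return [(self, "gamma"), (self, "beta")]


class AvgPool:
    """Window = stride = p average pooling, ceiling mode via edge padding."""

    n_params = 0

    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.p
        if p == 1:
            self._shape = x.shape
            return x
        N, H, W, C = x.shape
        Hp = -(-H // p) * p
        Wp = -(-W // p) * p
        xp = np.pad(x, ((0, 0), (0, Hp - H), (0, Wp - W), (0, 0)), mode="edge")
        self._shape = x.shape
        return xp.reshape(N, Hp // p, p, Wp // p, p, C).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.p
        if p == 1:
            return dout
        N, H, W, C = self._shape
        g = np.repeat(np.repeat(dout, p, axis=1), p, axis=2) / (p * p)
        if g.shape[1] > H:  # fold edge-replicated rows back onto the last row
            g[:, H - 1, :, :] += g[:, H:, :, :].sum(axis=1)
            g = g[:, :H, :, :]
        if g.shape[2] > W:
            g[:, :, W - 1, :] += g[:, :, W:, :].sum(axis=2)
            g = g[:, :, :W, :]
        return g

    def params(self):
        return []


class Flatten:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self, "W"), (self, "b")]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# network


@dataclass
class LayerInfo:
    name: str
    output_shape: tuple[int, ...]
    n_params: int


class Network:
    """A built network: ordered layers plus its symbolic shape audit."""

    def __init__(self, arch: CNNArchitecture, rng: np.random.Generator):
        self.arch = arch
        self.layers: list = []
        self.plan: list[LayerInfo] = []
        h = arch.input_hw
        c = arch.in_channels
        for si, (filters, pool) in enumerate(arch.stages):
            if h < 1:
                raise ArchitectureError(
                    f"stage {si}: spatial size collapsed below 1 pixel"
                )
            conv = Conv2D(arch.conv_kernel, c, filters, rng)
            self.layers += [conv, ReLU(), BatchNorm(filters), AvgPool(pool)]
            self.plan.append(LayerInfo(f"conv{si}", (h, h, filters), conv.n_params))
            self.plan.append(LayerInfo(f"relu{si}", (h, h, filters), 0))
            self.plan.append(LayerInfo(f"bnorm{si}", (h, h, filters), 2 * filters))
            h = -(-h // pool)  # ceiling-mode pooling
            self.plan.append(LayerInfo(f"pool{si}", (h, h, filters), 0))
            c = filters
        n_flat = h * h * c
        if n_flat < 1:
            raise ArchitectureError("flattened feature vector is empty")
        dense = Dense(n_flat, arch.n_classes, rng)
        self.layers += [Flatten(), dense]
        self.plan.append(LayerInfo("flatten", (n_flat,), 0))
        self.plan.append(LayerInfo("dense", (arch.n_classes,), dense.n_params))

    @property
    def n_params(self) -> int:
        return sum(li.n_params for li in self.plan)

    @property
    def input_size(self) -> int:
        return self.arch.input_hw**2 * self.arch.in_channels

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = [
            softmax(self.forward(x[i : i + batch], train=False))
            for i in range(0, len(x), batch)
        ]
        return np.vstack(out)

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def param_refs(self):
        for layer in self.layers:
            yield from layer.params()

    def refresh_batchnorm_stats(self, X: np.ndarray, batch: int = 128) -> None:
        """Re-estimate batch-norm population statistics over a dataset.

        With tiny datasets (a handful of minibatches per epoch) the running
        averages kept during training lag behind the final weights; one
        frozen-weight pass replaces them with the exact population mean and
        variance of the final activations.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            bn._accum = {
                "n": 0,
                "sum": np.zeros_like(bn.run_mean),
                "sumsq": np.zeros_like(bn.run_var),
            }
        for i in range(0, len(X), batch):
            self.forward(X[i : i + batch], train=True)
        for bn in bns:
            acc = bn._accum
            bn.run_mean = acc["sum"] / acc["n"]
            bn.run_var = acc["sumsq"] / acc["n"] - bn.run_mean**2
            bn._accum = None


def build_cnn(arch: CNNArchitecture, seed: int = 0) -> Network:
    """Build a network and its per-layer shape/parameter audit."""
    return Network(arch, np.random.default_rng(seed))


class RMSProp:
    def __init__(self, net: Network, cfg: TrainConfig):
        self.cfg = cfg
        self.refs = list(net.param_refs())
        self.cache = [np.zeros_like(getattr(obj, name)) for obj, name in self.refs]

    def step(self) -> None:
        c = self.cfg
        for i, (obj, name) in enumerate(self.refs):
            g = getattr(obj, "d" + name)
            self.cache[i] = c.rho * self.cache[i] + (1 - c.rho) * g * g
            getattr(obj, name)[...] -= (
                c.learning_rate * g / (np.sqrt(self.cache[i]) + c.eps)
            )


@dataclass
class TrainedCNN:
    """A trained network with its learning curves."""

    network: Network
    classes: np.ndarray
    loss_curve: list[float]
    acc_curve: list[float]  # per-epoch accuracy on training batches, percent
    seed: int

    @property
    def arch(self) -> CNNArchitecture:
        return self.network.arch

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.network.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]


def train_cnn(
    arch: CNNArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> TrainedCNN:
    """Minimize softmax cross-entropy with RMSProp.

    ``X`` is ``(N, H, W, 3)`` preprocessed float input; ``y`` holds class
    labels (any hashable values; at least two distinct).  Per-epoch
    shuffling is seeded; identical seeds reproduce the loss curve exactly.
    Divergence (NaN loss) raises ``RuntimeError`` naming the epoch.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    class_index = {c: i for i, c in enumerate(classes)}
    yi = np.array([class_index[c] for c in y])
    onehot = np.eye(len(classes))[yi]

    rng = np.random.default_rng(cfg.seed)
    net = Network(arch, rng)
    if arch.n_classes != len(classes):
        raise ValueError(
            f"architecture expects {arch.n_classes} classes, data has {len(classes)}"
        )
    opt = RMSProp(net, cfg)
    loss_curve: list[float] = []
    acc_curve: list[float] = []
    n = len(X)
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            sel = perm[start : start + cfg.batch_size]
            xb, tb = X[sel], onehot[sel]
            logits = net.forward(xb, train=True)
            p = softmax(logits)
            loss = -np.mean(np.sum(tb * np.log(p + 1e-12), axis=1))
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
            losses.append(loss * len(sel))
            correct += int((np.argmax(p, axis=1) == yi[sel]).sum())
            net.backward((p - tb) / len(sel))
            opt.step()
        loss_curve.append(float(np.sum(losses) / n))
        acc_curve.append(100.0 * correct / n)
    net.refresh_batchnorm_stats(X, cfg.batch_size)
    return TrainedCNN(net, classes, loss_curve, acc_curve, cfg.seed)


def evaluate_cnn(
    model: TrainedCNN, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, list[str]]:
    """Argmax-of-softmax evaluation.

    Returns ``(accuracy percent, confusion-matrix counts, class names)``;
    confusion rows are true classes.  Test classes unseen at training are
    necessarily mispredicted and trigger a warning.
    """
    y = np.asarray(y)
    unseen = set(np.unique(y)) - set(model.classes)
    if unseen:
        warnings.warn(f"classes unseen at training: {sorted(map(str, unseen))}")
    pred = model.predict(np.asarray(X, dtype=np.float64))
    classes = sorted(set(map(str, model.classes)) | set(map(str, np.unique(y))))
    cm = confusion_matrix(y.astype(str), pred.astype(str), labels=classes)
    acc = 100.0 * float(np.mean(pred.astype(str) == y.astype(str)))
    return acc, cm, classes


def architecture_search(
    candidates: list[CNNArchitecture],
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    paper_mode: bool = False,
    val_fraction: float = 0.1,
) -> tuple[list[dict], int]:
    """Train every candidate and select the best.

    By default each candidate is scored on a stratified validation split
    carved from the training data; with ``paper_mode=True`` (and a test set
    supplied) selection uses the test set instead, mirroring protocols that
    compare candidates directly on held-out accuracy at the price of
    selection leakage.  Ties resolve to the fewest parameters.  Candidates
    that fail to build are recorded as failed rows and skipped.
    """
    if paper_mode:
        if X_test is None:
            raise ValueError("paper_mode selection needs a test set")
        X_sel, y_sel = X_test, y_test
        X_fit, y_fit = X_train, y_train
    else:
        tr, va = train_test_split(
            np.arange(len(X_train)),
            test_size=val_fraction,
            random_state=cfg.seed,
            stratify=y_train,
        )
        X_fit, y_fit = X_train[tr], y_train[tr]
        X_sel, y_sel = X_train[va], y_train[va]

    rows: list[dict] = []
    for arch in candidates:
        row: dict = {"arch": arch.name}
        try:
            net_probe = build_cnn(arch, seed=cfg.seed)
            row["n_params"] = net_probe.n_params
            model = train_cnn(arch, X_fit, y_fit, cfg)
            row["train_accuracy"], _, _ = evaluate_cnn(model, X_fit, y_fit)
            row["val_accuracy"], _, _ = evaluate_cnn(model, X_sel, y_sel)
            if X_test is not None and not paper_mode:
                row["test_accuracy"], _, _ = evaluate_cnn(model, X_test, y_test)
            elif paper_mode:
                row["test_accuracy"] = row["val_accuracy"]
            row["model"] = model
        except (ArchitectureError, RuntimeError, ValueError) as exc:
            row["failed"] = str(exc)
        rows.append(row)
    ok = [i for i, r in enumerate(rows) if "failed" not in r]
    if not ok:
        raise RuntimeError("every candidate architecture failed")
    best = max(ok, key=lambda i: (rows[i]["val_accuracy"], -rows[i]["n_params"]))
    return rows, best
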