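"""Three-class tissue classifier: a small AlexNet-style CNN in NumPy.

Architecture (defaults): four convolution blocks, each a zero-padded
same-size convolution (stride 1) + ReLU + max pooling, with 16/32/32/32
feature maps, 5x5/5x5/5x5/3x3 kernels and 2/4/5/5 pooling windows
(pooling stride equals the window, so a 1000x1000x3 input reaches a
5x5 grid after the fourth pool); the 32 final maps are flattened into a
1024-neuron fully connected layer, followed by dropout (p = 0.5) and a
3-way softmax over (control, CD, EE).

Forward and backward passes are implemented directly with im2col + BLAS
matrix multiplies; training uses mini-batch Adam on the categorical
cross-entropy. Everything is seeded and deterministic on fixed BLAS
settings, and inference runs with dropout disabled.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Sequence

import numpy as np

from .imgprep import Patch, RgbImage, extract_test_patches

CLASS_ORDER = ("control", "CD", "EE")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by the product of the pooling
    windows (200 for the default 2*4*5*5) so every pool divides its
    input exactly; the fully connected fan-in then adapts as
    ``conv_feature_maps[-1] * (input_size / pool_product)**2``.
    """

    conv_feature_maps: tuple[int, ...] = (16, 32, 32, 32)
    conv_kernels: tuple[int, ...] = (5, 5, 5, 3)
    pool_windows: tuple[int, ...] = (2, 4, 5, 5)
    fc_width: int = 1024
    dropout_p: float = 0.5
    n_classes: int = 3
    input_size: int = 1000
    dtype: str = "float32"

    def __post_init__(self) -> None:
        n = len(self.conv_feature_maps)
        if not (len(self.conv_kernels) == len(self.pool_windows) == n):
            raise ConfigurationError("conv/pool tuples must have equal length")
        if any(v < 1 for v in self.conv_feature_maps + self.conv_kernels + self.pool_windows):
            raise ConfigurationError("all feature-map, kernel and pool sizes must be >= 1")
        if any(k % 2 == 0 for k in self.conv_kernels):
            raise ConfigurationError("conv kernels must be odd for same-size zero padding")
        if self.input_size % self.pool_product != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by the pooling "
                f"product {self.pool_product}"
            )
        if not (0.0 <= self.dropout_p < 1.0):
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.fc_width < 1 or self.n_classes < 2:
            raise ConfigurationError("fc_width >= 1 and n_classes >= 2 required")

    @property
    def pool_product(self) -> int:
        return int(np.prod(self.pool_windows))

    def grid_sides(self) -> list[int]:
        """Spatial side length after each pooling layer."""
        sides, s = [], self.input_size
        for w in self.pool_windows:
            s //= w
            sides.append(s)
        return sides

    @property
    def flattened_size(self) -> int:
        return self.conv_feature_maps[-1] * self.grid_sides()[-1] ** 2

    def layer_names(self) -> list[str]:
        n = len(self.conv_feature_maps)
        return [f"conv{i+1}" for i in range(n)] + [f"pool{i+1}" for i in range(n)]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer_name!r}")


@dataclass(frozen=True)
class ClassProbabilities:
    p_control: float
    p_cd: float
    p_ee: float

    def __post_init__(self) -> None:
        a = self.as_array()
        if np.any(a < -1e-9) or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError(f"not a probability triple: {a}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_control, self.p_cd, self.p_ee])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "ClassProbabilities":
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def argmax_label(self) -> str:
        # ties resolved to the first class in CLASS_ORDER
        return CLASS_ORDER[int(np.argmax(self.as_array()))]


# ---------------------------------------------------------------------------
# layers


def _conv_same(xp: np.ndarray, weight: np.ndarray, h: int, w: int) -> np.ndarray:
    """Stride-1 valid convolution of a pre-padded (N, C, H+2p, W+2p) input,
    written as a sum of shifted batched matmuls (fast for few channels)."""
    n = xp.shape[0]
    out_c, _, k, _ = weight.shape
    out = np.zeros((n, out_c, h * w), dtype=xp.dtype)
    for di in range(k):
        for dj in range(k):
            seg = xp[:, :, di : di + h, dj : dj + w].reshape(n, -1, h * w)
            out += np.matmul(weight[:, :, di, dj], seg)
    return out.reshape(n, out_c, h, w)


class _ConvSame:
    """Stride-1 convolution with same-size zero padding."""

    def __init__(
        self,
        in_c: int,
        out_c: int,
        k: int,
        rng: np.random.Generator,
        dtype,
        needs_input_grad: bool = True,
    ):
        scale = math.sqrt(2.0 / (in_c * k * k))  # He initialization
        self.weight = (rng.standard_normal((out_c, in_c, k, k)) * scale).astype(dtype)
        self.bias = np.zeros(out_c, dtype=dtype)
        self.k = k
        self.needs_input_grad = needs_input_grad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = _conv_same(xp, self.weight.astype(x.dtype), h, w)
        out += self.bias[:, None, None]
        if train:
            self._cache = (xp, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        xp, (n, c, h, w) = self._cache
        self._cache = None
        k = self.k
        doutf = dout.reshape(n, -1, h * w)
        dweight = np.empty_like(self.weight)
        for di in range(k):
            for dj in range(k):
                seg = xp[:, :, di : di + h, dj : dj + w].reshape(n, c, h * w)
                dweight[:, :, di, dj] = np.einsum("nfx,ncx->fc", doutf, seg)
        self.dweight = dweight
        self.dbias = dout.sum(axis=(0, 2, 3))
        if not self.needs_input_grad:  # first layer: no upstream to feed
            return None
        # dx is the same-padded convolution of dout with flipped, transposed kernels
        w_t = np.ascontiguousarray(self.weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        p = k // 2
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        return _conv_same(dp, w_t.astype(dout.dtype), h, w)


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class _MaxPool:
    """Max pooling with stride equal to the window; input side must divide."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        n, c, h, w = x.shape
        view = x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
        flat = view.reshape(n, c, h // k, w // k, k * k)
        if train:
            # route gradient to the first maximum in each window
            self._arg = flat.argmax(axis=-1)
            self._shape = (n, c, h, w)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // k, w // k, k * k), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        self._arg = None
        view = flat.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return view.reshape(n, c, h, w)


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator, dtype):
        scale = math.sqrt(2.0 / fan_in)
        self.weight = (rng.standard_normal((fan_in, fan_out)) * scale).astype(dtype)
        self.bias = np.zeros(fan_out, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dweight = self._x.T @ dout
        self.dbias = dout.sum(axis=0)
        self._x = None
        return dout @ self.weight.T


class _Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        self.p = p

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        if not train or self.p == 0.0:
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


# ---------------------------------------------------------------------------
# model


@dataclass
class TrainedModel:
    """Network weights + architecture + fixed class order.

    Built untrained by :func:`build_model`; :func:`train_model` updates
    the weights in place and records the per-epoch training loss.
    """

    config: NetworkConfig
    class_order: tuple[str, str, str] = CLASS_ORDER
    training_seed: int | None = None
    init_seed: int = 0
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        cfg = self.config
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(self.init_seed)
        self.convs: list[_ConvSame] = []
        self.pools: list[_MaxPool] = []
        in_c = 3
        for li, (maps, k, pw) in enumerate(
            zip(cfg.conv_feature_maps, cfg.conv_kernels, cfg.pool_windows)
        ):
            self.convs.append(
                _ConvSame(in_c, maps, k, rng, dtype, needs_input_grad=li > 0)
            )
            self.pools.append(_MaxPool(pw))
            in_c = maps
        self.fc = _Dense(cfg.flattened_size, cfg.fc_width, rng, dtype)
        self.dropout = _Dropout(cfg.dropout_p)
        self.head = _Dense(cfg.fc_width, cfg.n_classes, rng, dtype)

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[tuple[str, object, str]]:
        out = []
        for i, conv in enumerate(self.convs):
            out.append((f"conv{i+1}.weight", conv, "weight"))
            out.append((f"conv{i+1}.bias", conv, "bias"))
        out.append(("fc.weight", self.fc, "weight"))
        out.append(("fc.bias", self.fc, "bias"))
        out.append(("head.weight", self.head, "weight"))
        out.append(("head.bias", self.head, "bias"))
        return out

    # -- forward/backward --------------------------------------------------
    def _forward_logits(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        collect: dict | None = None,
    ) -> np.ndarray:
        self._relus = []
        h = x
        for i, (conv, pool) in enumerate(zip(self.convs, self.pools)):
            r = _ReLU()
            h = conv.forward(h, train)
            h = r.forward(h, train)
            if collect is not None:
                collect[f"conv{i+1}"] = h
            h = pool.forward(h, train)
            if collect is not None:
                collect[f"pool{i+1}"] = h
            self._relus.append(r)
        self._flat = _Flatten()
        self._fc_relu = _ReLU()
        h = self._flat.forward(h, train)
        h = self.fc.forward(h, train)
        h = self._fc_relu.forward(h, train)
        h = self.dropout.forward(h, train, rng)
        return self.head.forward(h, train)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dropout.backward(d) if self.config.dropout_p > 0 else d
        d = self._fc_relu.backward(d)
        d = self.fc.backward(d)
        d = self._flat.backward(d)
        for conv, relu, pool in zip(
            reversed(self.convs), reversed(self._relus), reversed(self.pools)
        ):
            d = pool.backward(d)
            d = relu.backward(d)
            d = conv.backward(d)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a (N, H, W, 3) uint8 / [0,1] float batch."""
        x = _to_input(batch, self.config)
        logits = self._forward_logits(x, train=False)
        return _softmax(logits.astype(np.float64))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _to_input(batch: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Normalize (N, H, W, 3) pixels to [0, 1] NCHW in the model dtype."""
    x = np.asarray(batch)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1] != cfg.input_size or x.shape[2] != cfg.input_size:
        raise ValueError(
            f"input spatial shape {x.shape[1]}x{x.shape[2]} does not match "
            f"model input_size {cfg.input_size}"
        )
    if x.dtype == np.uint8:
        x = x.astype(cfg.dtype) / 255.0
    else:
        x = x.astype(cfg.dtype)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def build_model(config: NetworkConfig, init_seed: int = 0) -> TrainedModel:
    """Construct an untrained network with seeded He-initialized weights."""
    return TrainedModel(config=config, init_seed=init_seed)


def _patch_pixels(p) -> np.ndarray:
    if isinstance(p, Patch):
        return p.pixels
    if isinstance(p, RgbImage):
        return p.pixels
    return np.asarray(p)


def train_model(
    model: TrainedModel,
    patches: Sequence,
    labels: Sequence[str],
    tcfg: TrainingConfig,
) -> TrainedModel:
    """Train in place with mini-batch Adam on categorical cross-entropy.

    ``patches`` may be Patch objects or (H, W, 3) arrays; ``labels`` are
    class names from the model's class order and every class must be
    represented. Records mean per-epoch loss in ``model.loss_history``.
    """
    order = {c: i for i, c in enumerate(model.class_order)}
    missing = [c for c in model.class_order if c not in set(labels)]
    if missing:
        raise ValueError(f"training data lacks class(es): {', '.join(missing)}")
    bad = sorted({l for l in labels if l not in order})
    if bad:
        raise ValueError(f"unknown training label(s): {', '.join(map(str, bad))}")
    if len(patches) != len(labels):
        raise ValueError("patches and labels must have equal length")

    cfg = model.config
    x_all = np.stack([_patch_pixels(p) for p in patches])
    y_all = np.array([order[l] for l in labels], dtype=np.int64)
    n = len(y_all)
    rng = np.random.default_rng(tcfg.seed)
    dtype = np.dtype(cfg.dtype)

    params = [(getattr(layer, attr), layer, attr) for _, layer, attr in model.parameters()]
    if tcfg.optimizer_name == "adam":
        m_state = [np.zeros_like(p) for p, _, _ in params]
        v_state = [np.zeros_like(p) for p, _, _ in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

    model.loss_history = []
    model.training_seed = tcfg.seed
    for _epoch in range(tcfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start : start + tcfg.batch_size]
            xb = _to_input(x_all[idx], cfg)
            yb = y_all[idx]
            logits = model._forward_logits(xb, train=True, rng=rng)
            probs = _softmax(logits.astype(np.float64))
            eps_p = 1e-12
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps_p))
            epoch_loss += loss * len(yb)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(dtype)
            model._backward(dlogits)
            grads = [getattr(layer, "d" + attr) for _, layer, attr in params]
            if tcfg.optimizer_name == "adam":
                t += 1
                for j, ((p, layer, attr), g) in enumerate(zip(params, grads)):
                    m_state[j] = beta1 * m_state[j] + (1 - beta1) * g
                    v_state[j] = beta2 * v_state[j] + (1 - beta2) * g * g
                    mhat = m_state[j] / (1 - beta1**t)
                    vhat = v_state[j] / (1 - beta2**t)
                    p -= (tcfg.learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(dtype)
            else:
                for (p, layer, attr), g in zip(params, grads):
                    p -= (tcfg.learning_rate * g).astype(dtype)
        model.loss_history.append(epoch_loss / n)
    return model


def predict_patch(model: TrainedModel, patch) -> ClassProbabilities:
    """Class probabilities for a single patch (dropout off)."""
    probs = model.predict_proba(_patch_pixels(patch)[None])
    return ClassProbabilities.from_array(probs[0])


def predict_image(model: TrainedModel, image: RgbImage) -> ClassProbabilities:
    """Image-level probabilities: mean over the 15 standard test patches.

    Patches sharing (offset, reflection) are pixel-identical, so only
    unique patches are run and the mean is multiplicity-weighted — exact
    for the degenerate geometries of images near the patch size.
    """
    patches = extract_test_patches(image, patch_size=model.config.input_size)
    keys = [(p.offset, p.reflection) for p in patches]
    unique: dict = {}
    counts: dict = {}
    for key, p in zip(keys, patches):
        counts[key] = counts.get(key, 0) + 1
        unique.setdefault(key, p)
    batch = np.stack([p.pixels for p in unique.values()])
    probs = model.predict_proba(batch)
    weights = np.array([counts[k] for k in unique], dtype=np.float64)
    mean = (probs * weights[:, None]).sum(axis=0) / weights.sum()
    return ClassProbabilities.from_array(mean)


def predict_case(
    model: TrainedModel, images: Sequence[RgbImage]
) -> tuple[ClassProbabilities, str]:
    """Case-level prediction: mean of image-level probability triples;
    label is the argmax with ties broken by class order."""
    if len(images) == 0:
        raise ValueError("a case must contain at least one image")
    triples = np.stack([predict_image(model, im).as_array() for im in images])
    mean = ClassProbabilities.from_array(triples.mean(axis=0))
    return mean, mean.argmax_label()


def layer_activations(model: TrainedModel, image_or_patch, layer: str) -> np.ndarray:
    """Post-ReLU activations at a named layer, as (rows, cols, maps).

    ``convN`` names the rectified convolution output before pooling
    (for the default architecture at 1000x1000 input, conv4 is a
    25 x 25 x 32 grid); ``poolN`` names the pooled output.
    """
    valid = model.config.layer_names()
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; valid: {', '.join(valid)}")
    x = _to_input(_patch_pixels(image_or_patch)[None], model.config)
    collect: dict[str, np.ndarray] = {}
    model._forward_logits(x, train=False, collect=collect)
    return np.ascontiguousarray(
        collect[layer][0].transpose(1, 2, 0).astype(np.float64)
    )


# ---------------------------------------------------------------------------
# checkpoint io


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file checkpoint: weights (npz) + config/class order (json)."""
    meta = {
        "format_version": 1,
        "config": {
            "conv_feature_maps": list(model.config.conv_feature_maps),
            "conv_kernels": list(model.config.conv_kernels),
            "pool_windows": list(model.config.pool_windows),
            "fc_width": model.config.fc_width,
            "dropout_p": model.config.dropout_p,
            "n_classes": model.config.n_classes,
            "input_size": model.config.input_size,
            "dtype": model.config.dtype,
        },
        "class_order": list(model.class_order),
        "training_seed": model.training_seed,
        "init_seed": model.init_seed,
        "loss_history": model.loss_history,
    }
    buf = BytesIO()
    arrays = {name: getattr(layer, attr) for name, layer, attr in model.parameters()}
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version in {path}")
        npz = np.load(BytesIO(zf.read("weights.npz")))
        c = meta["config"]
        config = NetworkConfig(
            conv_feature_maps=tuple(c["conv_feature_maps"]),
            conv_kernels=tuple(c["conv_kernels"]),
            pool_windows=tuple(c["pool_windows"]),
            fc_width=c["fc_width"],
            dropout_p=c["dropout_p"],
            n_classes=c["n_classes"],
            input_size=c["input_size"],
            dtype=c["dtype"],
        )
        model = TrainedModel(
            config=config,
            class_order=tuple(meta["class_order"]),
            training_seed=meta["training_seed"],
            init_seed=meta["init_seed"],
            loss_history=list(meta["loss_history"]),
        )
        for name, layer, attr in model.parameters():
            setattr(layer, attr, npz[name])
    return model
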