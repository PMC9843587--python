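"""The somatic-vs-non-somatic classifier.

Architecture: four 3x3 convolutional layers (ReLU + 2x2 max-pooling after
each) over the C x W x H pileup tensor; the convolutional output is
flattened, concatenated with the 10-value meta vector and passed through
four dense layers, the last a single unit whose sigmoid output is the
somatic pseudoprobability. Training minimizes binary cross-entropy with
AdamW on mini-batches of 32; after a first stage of 15 epochs the learning
rate drops by a factor of 10 for 5 more epochs. The minority class is
upsampled (sampling with replacement, redrawn each epoch) to parity.

The network is implemented directly on NumPy (im2col convolutions backed by
BLAS matrix products), which keeps the package dependency-light and is fast
enough for the tensor sizes this pipeline produces on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults sized for CPU training)."""

    in_channels: int = 14
    conv_channels: tuple[int, ...] = (8, 16, 32, 32)
    kernel: int = 3
    pool: int = 2
    dense: tuple[int, ...] = (64, 32, 16)  # hidden widths; a final 1-unit layer is implied
    meta_width: int = 10
    dropout: float = 0.3  # on hidden dense layers, training only
    # Map the p-hot quality channels into the Phred (log) domain at the input
    # stage: raw error probabilities compress high-quality information into a
    # sliver near 0/1 that gradient descent finds unreliably; in log space the
    # same information is linear in the Phred score.
    phred_domain_qualities: bool = True
    phred_scale: float = 5.0  # decades mapped onto [0, 1]

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 4 or len(self.dense) != 3:
            raise ValueError("default architecture contract: 4 conv and 4 dense layers")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    epochs_stage1: int = 15
    lr_divisor: float = 10.0
    epochs_stage2: int = 5
    seed: int = 0
    upsample: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs_stage1 < 0 or self.epochs_stage2 < 0:
            raise ValueError("invalid training configuration")


def _conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded k x k convolution in channel-first layout.

    ``x`` is (Cin, N, H, W); ``weight`` is (Cout, Cin, k, k). The convolution
    is evaluated as k*k shifted GEMMs against the flattened input, which
    keeps peak memory at one output-sized buffer instead of an im2col patch
    matrix (the dominant cost on a single CPU).
    """
    cin, n, h, w = x.shape
    cout, _, k, _ = weight.shape
    p = k // 2
    xflat = x.reshape(cin, n * h * w)
    yp = np.zeros((cout, n, h + 2 * p, w + 2 * p), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            contrib = (weight[:, :, ki, kj] @ xflat).reshape(cout, n, h, w)
            yp[:, :, 2 * p - ki : 2 * p - ki + h, 2 * p - kj : 2 * p - kj + w] += contrib
    y = np.ascontiguousarray(yp[:, :, p : p + h, p : p + w])
    y += bias[:, None, None, None]
    return y


def _conv_backward(
    dy: np.ndarray, x: np.ndarray, weight: np.ndarray, need_dx: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Gradients of :func:`_conv_forward`; returns (dweight, dbias, dx)."""
    cin, n, h, w = x.shape
    cout, _, k, _ = weight.shape
    p = k // 2
    xflat = x.reshape(cin, n * h * w)
    dyp = np.zeros((cout, n, h + 2 * p, w + 2 * p), dtype=np.float32)
    dyp[:, :, p : p + h, p : p + w] = dy
    dweight = np.empty_like(weight)
    dx = np.zeros((cin, n * h * w), dtype=np.float32) if need_dx else None
    for ki in range(k):
        for kj in range(k):
            dys = np.ascontiguousarray(
                dyp[:, :, 2 * p - ki : 2 * p - ki + h, 2 * p - kj : 2 * p - kj + w]
            ).reshape(cout, n * h * w)
            dweight[:, :, ki, kj] = dys @ xflat.T
            if need_dx:
                dx += weight[:, :, ki, kj].T @ dys
    dbias = dy.sum(axis=(1, 2, 3))
    return dweight, dbias, dx.reshape(cin, n, h, w) if need_dx else None


def _maxpool_forward(x: np.ndarray, pool: int) -> tuple[np.ndarray, np.ndarray]:
    """2D max pooling over the trailing axes of (C, N, H, W); returns (y, argmax)."""
    c, n, h, w = x.shape
    hp, wp = h // pool, w // pool
    xr = (
        x[:, :, : hp * pool, : wp * pool]
        .reshape(c, n, hp, pool, wp, pool)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(c, n, hp, wp, pool * pool)
    )
    arg = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return y, arg


def _maxpool_backward(dy: np.ndarray, arg: np.ndarray, in_hw: tuple[int, int], pool: int) -> np.ndarray:
    c, n, hp, wp = dy.shape
    h, w = in_hw
    dxr = np.zeros((c, n, hp, wp, pool * pool), dtype=np.float32)
    np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=-1)
    dx = np.zeros((c, n, h, w), dtype=np.float32)
    dx[:, :, : hp * pool, : wp * pool] = (
        dxr.reshape(c, n, hp, wp, pool, pool).transpose(0, 1, 2, 4, 3, 5).reshape(c, n, hp * pool, wp * pool)
    )
    return dx


class SomaticCNN:
    """Convolutional classifier mapping (tensor, meta) to a somatic score.

    Construct through :func:`build_model` so the input geometry is validated
    against the pileup configuration.
    """

    def __init__(self, cfg: ModelConfig, input_hw: tuple[int, int], seed: int = 0):
        self.cfg = cfg
        self.input_hw = tuple(input_hw)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = cfg.in_channels
        h, w = self.input_hw
        for i, c_out in enumerate(cfg.conv_channels):
            fan_in = c_in * cfg.kernel * cfg.kernel
            self.params[f"convW{i}"] = (
                rng.standard_normal((c_out, c_in, cfg.kernel, cfg.kernel)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"convb{i}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
            h //= cfg.pool
            w //= cfg.pool
            if h < 1 or w < 1:
                raise ValueError("input spatial size too small for the conv/pool stack")
        self.flat_dim = c_in * h * w
        self._conv_out_hw: tuple[int, int] = (h, w)
        widths = [self.flat_dim + cfg.meta_width, *cfg.dense, 1]
        for i in range(len(widths) - 1):
            fan_in = widths[i]
            self.params[f"denseW{i}"] = (rng.standard_normal((widths[i + 1], fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
            self.params[f"denseb{i}"] = np.zeros(widths[i + 1], dtype=np.float32)
        self.n_dense = len(widths) - 1

    # ------------------------------------------------------------------ forward
    def forward(
        self,
        x: np.ndarray,
        meta: np.ndarray,
        keep_cache: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Logits for a batch; ``x`` is (N, C, W, H), ``meta`` is (N, 10).

        ``dropout_rng`` enables inverted dropout on the hidden dense layers
        (training mode); inference leaves it None and is deterministic.
        """
        cfg = self.cfg
        x = np.asarray(x, dtype=np.float32)
        meta = np.asarray(meta, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != cfg.in_channels or x.shape[2:] != self.input_hw:
            raise ValueError(
                f"tensor batch shape {x.shape} does not match model input "
                f"({cfg.in_channels}, {self.input_hw[0]}, {self.input_hw[1]})"
            )
        if meta.shape != (x.shape[0], cfg.meta_width):
            raise ValueError("meta batch shape mismatch")
        cache: dict = {"conv_in": [], "relu": [], "pool_arg": [], "pre_pool_hw": []}
        # internal layout is channel-first (C, N, H, W) so the convolution
        # GEMMs run on contiguous flattened views
        a = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        if cfg.phred_domain_qualities:
            q = a[4:8]
            stretched = 1.0 + np.log10(np.maximum(q, 1e-30), dtype=np.float32) / cfg.phred_scale
            a[4:8] = np.where(q > 0, np.clip(stretched, 0.0, 1.0), 0.0)
        for i in range(len(cfg.conv_channels)):
            z = _conv_forward(a, self.params[f"convW{i}"], self.params[f"convb{i}"])
            relu_mask = z > 0
            z *= relu_mask
            pooled, arg = _maxpool_forward(z, cfg.pool)
            if keep_cache:
                cache["conv_in"].append(a)
                cache["relu"].append(relu_mask)
                cache["pool_arg"].append(arg)
                cache["pre_pool_hw"].append(z.shape[2:])
            a = pooled
        n = x.shape[0]
        flat = np.ascontiguousarray(a.transpose(1, 0, 2, 3)).reshape(n, -1)
        d = np.concatenate([flat, meta], axis=1)
        dense_in = []
        drop_masks: list[np.ndarray | None] = []
        p_drop = self.cfg.dropout
        for i in range(self.n_dense):
            if keep_cache:
                dense_in.append(d)
            z = d @ self.params[f"denseW{i}"].T + self.params[f"denseb{i}"]
            if i < self.n_dense - 1:
                d = np.maximum(z, 0.0)
                if dropout_rng is not None and p_drop > 0.0:
                    mask = (dropout_rng.random(d.shape) >= p_drop).astype(np.float32) / (1.0 - p_drop)
                    d = d * mask
                    drop_masks.append(mask)
                else:
                    drop_masks.append(None)
            else:
                d = z
        logits = d[:, 0]
        if keep_cache:
            cache["dense_in"] = dense_in
            cache["drop_masks"] = drop_masks
            cache["conv_out_shape"] = a.shape
            self._cache = cache
        return logits

    def predict(self, x: np.ndarray, meta: np.ndarray) -> np.ndarray:
        """Sigmoid scores in (0, 1); deterministic."""
        z = self.forward(x, meta, keep_cache=False)
        return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))

    # ----------------------------------------------------------------- backward
    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients for the last cached forward pass."""
        cfg = self.cfg
        cache = self._cache
        grads: dict[str, np.ndarray] = {}
        d = dlogits[:, None].astype(np.float32)
        for i in range(self.n_dense - 1, -1, -1):
            inp = cache["dense_in"][i]
            grads[f"denseW{i}"] = d.T @ inp
            grads[f"denseb{i}"] = d.sum(axis=0)
            d = d @ self.params[f"denseW{i}"]
            if i > 0:
                mask = cache["drop_masks"][i - 1]
                if mask is not None:
                    d = d * mask
                d = d * (cache["dense_in"][i] > 0)
        c, n, h, w = cache["conv_out_shape"]
        da = np.ascontiguousarray(d[:, : self.flat_dim].reshape(n, c, h, w).transpose(1, 0, 2, 3))
        for i in range(len(cfg.conv_channels) - 1, -1, -1):
            dz = _maxpool_backward(da, cache["pool_arg"][i], cache["pre_pool_hw"][i], cfg.pool)
            dz *= cache["relu"][i]
            dw, db, da = _conv_backward(dz, cache["conv_in"][i], self.params[f"convW{i}"], need_dx=i > 0)
            grads[f"convW{i}"] = dw
            grads[f"convb{i}"] = db
        self._cache = None
        return grads


def build_model(cfg: ModelConfig, pileup_cfg=None, seed: int = 0) -> SomaticCNN:
    """Instantiate the classifier, validating against the pileup geometry."""
    if pileup_cfg is not None:
        if pileup_cfg.C != cfg.in_channels:
            raise ValueError(
                f"pileup channel count {pileup_cfg.C} does not match model input channels {cfg.in_channels}"
            )
        input_hw = (pileup_cfg.W, pileup_cfg.H)
    else:
        input_hw = (150, 70)
    return SomaticCNN(cfg, input_hw, seed=seed)


class _AdamW:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            # decoupled weight decay (biases included; negligible at this scale)
            params[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * params[k])


def _balanced_indices(labels: np.ndarray, rng: np.random.Generator, upsample: bool) -> np.ndarray:
    """Epoch sample indices with the minority class upsampled to parity."""
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    if not upsample or len(pos) == len(neg):
        idx = np.concatenate([pos, neg])
    else:
        minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
        extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
        idx = np.concatenate([majority, minority, extra])
    rng.shuffle(idx)
    return idx


def train_classifier(
    tensors: np.ndarray,
    meta: np.ndarray,
    labels: Sequence[int],
    cfg: TrainConfig,
    model_cfg: ModelConfig | None = None,
    model: SomaticCNN | None = None,
) -> tuple[SomaticCNN, list[dict]]:
    """Train the classifier on encoded tensors; returns (model, training log).

    ``labels`` are binary (1 = somatic). The log holds one entry per epoch
    with the mean loss, learning rate and the sampled class counts.
    """
    tensors = np.asarray(tensors, dtype=np.float32)
    meta = np.asarray(meta, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    if model is None:
        model_cfg = model_cfg or ModelConfig(in_channels=tensors.shape[1])
        model = SomaticCNN(model_cfg, tensors.shape[2:], seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    drop_rng = np.random.default_rng(cfg.seed + 2) if model.cfg.dropout > 0 else None
    opt = _AdamW(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    log: list[dict] = []
    total_epochs = cfg.epochs_stage1 + cfg.epochs_stage2
    for epoch in range(total_epochs):
        lr = cfg.learning_rate if epoch < cfg.epochs_stage1 else cfg.learning_rate / cfg.lr_divisor
        opt.lr = lr
        idx = _balanced_indices(labels, rng, cfg.upsample)
        losses = []
        for start in range(0, len(idx), cfg.batch_size):
            batch = idx[start : start + cfg.batch_size]
            y = labels[batch].astype(np.float64)
            z = model.forward(tensors[batch], meta[batch], keep_cache=True, dropout_rng=drop_rng)
            p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            grads = model.backward(((p - y) / len(batch)).astype(np.float32))
            opt.step(model.params, grads)
            losses.append(loss)
        log.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss": float(np.mean(losses)),
                "n_sampled_pos": int(np.sum(labels[idx] == 1)),
                "n_sampled_neg": int(np.sum(labels[idx] == 0)),
            }
        )
    return model, log


def predict_scores(model: SomaticCNN, tensors: np.ndarray, meta: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """One score in (0, 1) per variant; identical batches give identical scores."""
    tensors = np.asarray(tensors, dtype=np.float32)
    meta = np.asarray(meta, dtype=np.float32)
    out = np.empty(len(tensors), dtype=np.float64)
    for start in range(0, len(tensors), batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = model.predict(tensors[sl], meta[sl])
    return out


def save_checkpoint(model: SomaticCNN, path: str, pileup_hash: str = "", train_cfg: TrainConfig | None = None) -> None:
    """Serialize weights plus the model/pileup configuration."""
    header = {
        "model_cfg": asdict(model.cfg),
        "input_hw": list(model.input_hw),
        "pileup_hash": pileup_hash,
        "train_cfg": asdict(train_cfg) if train_cfg else None,
    }
    np.savez_compressed(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path: str) -> tuple[SomaticCNN, str]:
    """Restore a checkpoint; returns (model, pileup configuration hash)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        mc = header["model_cfg"]
        cfg = ModelConfig(
            in_channels=mc["in_channels"],
            conv_channels=tuple(mc["conv_channels"]),
            kernel=mc["kernel"],
            pool=mc["pool"],
            dense=tuple(mc["dense"]),
            meta_width=mc["meta_width"],
        )
        model = SomaticCNN(cfg, tuple(header["input_hw"]), seed=0)
        for k in model.params:
            model.params[k] = data[k].copy()
    return model, header["pileup_hash"]
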