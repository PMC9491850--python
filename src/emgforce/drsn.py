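"""1-D deep residual shrinkage network (DRSN) for force regression.

The network stacks residual shrinkage building units (RSBU): each unit's
residual branch is conv -> batch-norm -> ReLU -> conv -> batch-norm, whose
output features are denoised by soft thresholding with a per-sample threshold
learned by a squeeze-and-excitation style subnetwork (global average pool of
|features| -> dense -> BN -> ReLU -> dense -> sigmoid).  The threshold for
channel c is tau_c = alpha_c * mean|x|_c with alpha_c in (0,1), so it is
positive, never exceeds the mean absolute activation, and adapts per sample.
A global average pool and a dense head regress the scalar force.

Built on the package's numpy reverse-mode autodiff core; training uses Adam
on mean-squared error with z-scored inputs and targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, conv1d, soft_threshold_op
from .windows import WindowedDataset

__all__ = [
    "soft_threshold",
    "soft_threshold_grad",
    "senet_squeeze",
    "learn_threshold",
    "residual_block_forward",
    "RsbuUnit",
    "DrsnConfig",
    "DrsnModel",
    "train_drsn",
    "predict_force",
    "save_drsn",
    "load_drsn",
]

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# elementary operations (plain numpy surface)

def soft_threshold(x, tau):
    """Shrinkage: x-tau for x>tau, 0 for |x|<=tau, x+tau for x<-tau."""
    x = np.asarray(x, dtype=float)
    tau_arr = np.asarray(tau, dtype=float)
    if (tau_arr < 0).any():
        raise ValueError("tau must be >= 0")
    out = np.sign(x) * np.maximum(np.abs(x) - tau_arr, 0.0)
    return float(out) if np.isscalar(tau) and out.ndim == 0 else out


def soft_threshold_grad(x, tau):
    """Subgradient of the shrinkage w.r.t. its input: 1 if |x|>tau else 0."""
    x = np.asarray(x, dtype=float)
    tau_arr = np.asarray(tau, dtype=float)
    if (tau_arr < 0).any():
        raise ValueError("tau must be >= 0")
    g = (np.abs(x) > tau_arr).astype(float)
    return float(g) if g.ndim == 0 else g


def senet_squeeze(feature_map: np.ndarray) -> np.ndarray:
    """Global average pool: per-channel mean over the length axis.

    Accepts (C, L) or (N, C, L); returns (C,) or (N, C).
    """
    fm = np.asarray(feature_map, dtype=float)
    return fm.mean(axis=-1)


# ---------------------------------------------------------------------------
# layers

class _Conv:
    def __init__(self, rng, cin, cout, k, stride=1):
        scale = np.sqrt(2.0 / (cin * k))
        self.w = Tensor(rng.standard_normal((cout, cin, k)) * scale, True)
        self.b = Tensor(np.zeros(cout), True)
        self.stride, self.pad = stride, k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, self.stride, self.pad)

    def named_params(self, p):
        return [(f"{p}.w", self.w), (f"{p}.b", self.b)]

    def named_buffers(self, p):
        return []


class _BatchNorm:
    """Per-channel batch normalization for (N, C, L) or (N, C) inputs."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c), True)
        self.beta = Tensor(np.zeros(c), True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        conv_shape = x.data.ndim == 3
        axes = (0, 2) if conv_shape else (0,)
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            v = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * v.data.ravel()
            xn = xc / (v + self.eps).sqrt()
        else:
            shape = (1, -1, 1) if conv_shape else (1, -1)
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var + self.eps).reshape(shape)
            xn = (x - Tensor(mu)) / Tensor(sd)
        shape = (1, -1, 1) if conv_shape else (1, -1)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)

    def named_params(self, p):
        return [(f"{p}.gamma", self.gamma), (f"{p}.beta", self.beta)]

    def named_buffers(self, p):
        return [(f"{p}.running_mean", self.running_mean),
                (f"{p}.running_var", self.running_var)]

    def set_buffers(self, mean, var):
        self.running_mean, self.running_var = mean.copy(), var.copy()


class _Dense:
    def __init__(self, rng, din, dout):
        self.w = Tensor(rng.standard_normal((din, dout)) * np.sqrt(2.0 / din), True)
        self.b = Tensor(np.zeros(dout), True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def named_params(self, p):
        return [(f"{p}.w", self.w), (f"{p}.b", self.b)]

    def named_buffers(self, p):
        return []


# ---------------------------------------------------------------------------
# residual shrinkage building unit

class RsbuUnit:
    """Residual shrinkage building unit.

    ``mode='channel_wise'`` learns one threshold scaling per feature channel;
    ``mode='channel_shared'`` learns a single scaling per sample applied to
    the global mean absolute activation.  With the residual branch zeroed the
    unit is the identity on matching shapes.
    """

    def __init__(self, rng, cin, cout, kernel_size=3, stride=1,
                 mode="channel_wise", shrinkage=True):
        if mode not in ("channel_wise", "channel_shared"):
            raise ValueError("mode must be channel_wise or channel_shared")
        self.conv1 = _Conv(rng, cin, cout, kernel_size, stride)
        self.bn1 = _BatchNorm(cout)
        self.conv2 = _Conv(rng, cout, cout, kernel_size, 1)
        self.bn2 = _BatchNorm(cout)
        self.fc1 = _Dense(rng, cout, cout)
        self.bnf = _BatchNorm(cout)
        self.fc2 = _Dense(rng, cout, cout if mode == "channel_wise" else 1)
        self.shortcut = None
        if cin != cout or stride != 1:
            self.shortcut = _Conv(rng, cin, cout, 1, stride)
        self.mode = mode
        self.shrinkage = shrinkage

    def learn_threshold(self, r: Tensor, training: bool) -> Tensor:
        """tau per (sample, channel): alpha * mean|r|, alpha = sigmoid(subnet)."""
        z = r.abs().mean(axis=2)                       # (N, C) squeeze
        a = self.fc2(self.bnf(self.fc1(z), training).relu()).sigmoid()
        if self.mode == "channel_wise":
            tau = a * z                                # (N, C)
        else:
            tau = a * z.mean(axis=1, keepdims=True)    # (N, 1)
        return tau.reshape(tau.shape[0], -1, 1)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        r = self.bn1(self.conv1(x), training).relu()
        r = self.bn2(self.conv2(r), training)
        if self.shrinkage:
            tau = self.learn_threshold(r, training)
            r = soft_threshold_op(r, tau)
        s = x if self.shortcut is None else self.shortcut(x)
        return s + r

    def _children(self):
        ch = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2),
              ("bn2", self.bn2), ("fc1", self.fc1), ("bnf", self.bnf),
              ("fc2", self.fc2)]
        if self.shortcut is not None:
            ch.append(("shortcut", self.shortcut))
        return ch

    def named_params(self, p):
        return [np for n, c in self._children() for np in c.named_params(f"{p}.{n}")]

    def named_buffers(self, p):
        return [nb for n, c in self._children() for nb in c.named_buffers(f"{p}.{n}")]


def learn_threshold(feature_map: np.ndarray, unit: RsbuUnit) -> np.ndarray:
    """Thresholds the unit's subnetwork assigns to a feature map (eval mode)."""
    fm = np.asarray(feature_map, dtype=float)
    single = fm.ndim == 2
    if single:
        fm = fm[None]
    tau = unit.learn_threshold(Tensor(fm), training=False).data[..., 0]
    return tau[0] if single else tau


def residual_block_forward(x: np.ndarray, unit: RsbuUnit) -> np.ndarray:
    """Eval-mode forward pass of one unit on (N, C, L) or (C, L) input."""
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    y = unit.forward(Tensor(arr), training=False).data
    return y[0] if single else y


# ---------------------------------------------------------------------------
# full network

@dataclass(frozen=True)
class DrsnConfig:
    """Architecture and training hyperparameters."""

    n_units: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    mode: str = "channel_wise"          # or channel_shared
    shrinkage: bool = True              # False = shrinkage-ablated ResNet
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10                  # early stopping on validation MSE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if len(self.channels) != self.n_units:
            raise ValueError("channels must list one width per unit")
        if min(self.channels) < 1 or self.kernel_size < 1 or self.batch_size < 1:
            raise ValueError("counts must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class _Drsn:
    """Stem conv + RSBU stack + global average pool + dense head."""

    def __init__(self, config: DrsnConfig, c_in: int):
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        self.stem = _Conv(rng, c_in, ch[0], config.kernel_size, 1)
        self.stem_bn = _BatchNorm(ch[0])
        self.units = []
        prev = ch[0]
        for i, c in enumerate(ch):
            stride = 2 if (i > 0 and c != prev) else 1
            self.units.append(RsbuUnit(rng, prev, c, config.kernel_size, stride,
                                       config.mode, config.shrinkage))
            prev = c
        self.head = _Dense(rng, ch[-1], 1)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        h = self.stem_bn(self.stem(x), training).relu()
        for u in self.units:
            h = u.forward(h, training)
        pooled = h.mean(axis=2)                        # (N, C)
        return self.head(pooled).reshape(-1)

    def _children(self):
        ch = [("stem", self.stem), ("stem_bn", self.stem_bn)]
        ch += [(f"unit{i}", u) for i, u in enumerate(self.units)]
        ch.append(("head", self.head))
        return ch

    def named_params(self):
        return [np for n, c in self._children() for np in c.named_params(n)]

    def named_buffers(self):
        return [nb for n, c in self._children() for nb in c.named_buffers(n)]

    def params(self):
        return [t for _, t in self.named_params()]


@dataclass
class DrsnModel:
    """Trained network plus the input/target normalization it was fitted with."""

    config: DrsnConfig
    c_in: int
    net: _Drsn
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    history: dict = field(default_factory=lambda: {"train_mse": [], "val_mse": []})


class _Adam:
    def __init__(self, params, lr):
        self.params, self.lr = params, lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _normalize(X: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (X - mean) / std


def _forward_numpy(model: DrsnModel, X: np.ndarray) -> np.ndarray:
    n_ch = model.c_in
    Xn = _normalize(X, model.x_mean, model.x_std)
    seqs = Xn.reshape(len(Xn), n_ch, -1)
    out = model.net.forward(Tensor(seqs), training=False).data
    return out * model.y_std + model.y_mean


def train_drsn(config: DrsnConfig, train_dataset: WindowedDataset,
               val_dataset: WindowedDataset) -> DrsnModel:
    """Fit the network by Adam on MSE with early stopping on validation MSE.

    Inputs and targets are z-scored with training-set statistics (stored in
    the model).  ``epochs=0`` returns the initialized model unchanged.
    Raises ``RuntimeError`` naming the epoch if the loss becomes NaN.
    """
    if len(train_dataset) == 0 or len(val_dataset) == 0:
        raise ValueError("datasets must be non-empty")
    Xtr_raw, ytr = train_dataset.X, train_dataset.y
    x_mean = Xtr_raw.mean(axis=0)
    x_std = np.maximum(Xtr_raw.std(axis=0), 1e-12)
    y_mean, y_std = float(ytr.mean()), float(max(ytr.std(), 1e-12))
    c_in = train_dataset.n_channels if train_dataset.kind == "raw" else 1

    net = _Drsn(config, c_in)
    model = DrsnModel(config=config, c_in=c_in, net=net, x_mean=x_mean,
                      x_std=x_std, y_mean=y_mean, y_std=y_std)

    Xtr = _normalize(Xtr_raw, x_mean, x_std).reshape(len(Xtr_raw), c_in, -1)
    ytr_n = (ytr - y_mean) / y_std
    Xva = _normalize(val_dataset.X, x_mean, x_std).reshape(len(val_dataset), c_in, -1)
    yva_n = (val_dataset.y - y_mean) / y_std

    params = net.params()
    opt = _Adam(params, config.lr)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    best_val = np.inf
    best_state = None
    since_best = 0

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(Xtr))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue    # batch-norm needs at least 2 samples
            pred = net.forward(Tensor(Xtr[idx]), training=True)
            err = pred - Tensor(ytr_n[idx])
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_pred = net.forward(Tensor(Xva), training=False).data
        val_mse = float(np.mean((val_pred - yva_n) ** 2))
        if not np.isfinite(val_mse):
            raise RuntimeError(f"NaN/inf validation loss at epoch {epoch}")
        model.history["train_mse"].append(float(np.mean(epoch_losses)))
        model.history["val_mse"].append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_state = ([p.data.copy() for p in params],
                          [b.copy() for _, b in net.named_buffers()])
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    if best_state is not None:
        for p, d in zip(params, best_state[0]):
            p.data = d
        for (_, buf), saved in zip(net.named_buffers(), best_state[1]):
            buf[...] = saved
    return model


def predict_force(model: DrsnModel, dataset: WindowedDataset) -> np.ndarray:
    """Predicted force per window, in the original force units."""
    if len(dataset) == 0:
        return np.empty(0)
    return _forward_numpy(model, dataset.X)


# ---------------------------------------------------------------------------
# checkpointing: save -> load -> predict is bit-identical

def save_drsn(model: DrsnModel, path) -> None:
    arrays = {f"param:{n}": t.data for n, t in model.net.named_params()}
    arrays.update({f"buffer:{n}": b for n, b in model.net.named_buffers()})
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config),
            "c_in": model.c_in, "y_mean": model.y_mean, "y_std": model.y_std,
            "history": model.history}
    np.savez(path, x_mean=model.x_mean, x_std=model.x_std,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_drsn(path) -> DrsnModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_d = meta["config"]
        cfg_d["channels"] = tuple(cfg_d["channels"])
        config = DrsnConfig(**cfg_d)
        net = _Drsn(config, meta["c_in"])
        for n, t in net.named_params():
            t.data = z[f"param:{n}"].copy()
        for n, b in net.named_buffers():
            b[...] = z[f"buffer:{n}"]
        model = DrsnModel(config=config, c_in=meta["c_in"], net=net,
                          x_mean=z["x_mean"].copy(), x_std=z["x_std"].copy(),
                          y_mean=meta["y_mean"], y_std=meta["y_std"],
                          history=meta["history"])
    return model
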