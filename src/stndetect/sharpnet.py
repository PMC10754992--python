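"""Threshold-sharpened spiking detectors (S-LSTM / SNN) and their training.

The detectors are ordinary recurrent/dense networks whose activations are
bounded rectified linear units (bRELU)

    h_{a,b}(x) = 1            if x >= b
               = (x-a)/(b-a)  if a < x < b
               = 0            if x <= a

with the symmetry constraint |b - 0.5| = |a - 0.5|.  During training the
half-width w = (b - a)/2 is gradually driven to zero ("sharpening"), so each
unit's activation collapses to a 0/1 threshold at 0.5 and the trained network
emits binary spikes, while gradients remain available throughout training.
Sharpening advances layer by layer from the input side, and pauses whenever
the training loss is changing too fast (the adaptive schedule).

Everything is plain NumPy: forward, backpropagation(-through-time) and the
adadelta optimizer are implemented here so the sharpening states can live
inside the gradient path.

Input encoding: a sample's zero-padded spike-time vector (ms) is scaled by
1/T_max into [0, 1] and consumed as a length-L_max sequence of scalars by the
recurrent architectures, or as a flat vector by the feedforward one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .spikegen import SpikeDataset

__all__ = [
    "BRELUState",
    "LayerSpec",
    "DetectorSpec",
    "SharpenPolicy",
    "TrainConfig",
    "TrainedDetector",
    "brelu",
    "brelu_grad",
    "sharpen",
    "adaptive_schedule",
    "build_detector",
    "init_detector",
    "train",
    "predict",
    "export_weights",
    "import_weights",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bounded ReLU and sharpening

@dataclass(frozen=True)
class BRELUState:
    """The (alpha, beta) pair of a bounded ReLU, symmetric about 0.5."""

    alpha: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha > self.beta:
            raise ValueError("alpha must not exceed beta")
        if abs(abs(self.beta - 0.5) - abs(self.alpha - 0.5)) > 1e-9:
            raise ValueError("bRELU must be symmetric: |beta-0.5| == |alpha-0.5|")
        if not 0.0 <= self.width <= 0.5 + 1e-12:
            raise ValueError("half-width must lie in [0, 0.5]")

    @property
    def width(self) -> float:
        """Half-width w = (beta - alpha) / 2 of the linear segment."""
        return (self.beta - self.alpha) / 2.0

    @classmethod
    def from_width(cls, w: float) -> "BRELUState":
        return cls(alpha=0.5 - w, beta=0.5 + w)


def brelu(x, state: BRELUState):
    """Bounded ReLU; a hard threshold at 0.5 when fully sharpened (w = 0)."""
    x = np.asarray(x, dtype=float)
    if state.beta == state.alpha:
        return (x >= state.beta).astype(float)
    return np.clip((x - state.alpha) / (state.beta - state.alpha), 0.0, 1.0)


def brelu_grad(x, state: BRELUState):
    """d brelu/dx: 1/(beta-alpha) on the open linear segment, else 0."""
    x = np.asarray(x, dtype=float)
    if state.beta == state.alpha:
        return np.zeros_like(x)
    g = 1.0 / (state.beta - state.alpha)
    return np.where((x > state.alpha) & (x < state.beta), g, 0.0)


def sharpen(state: BRELUState, delta: float) -> BRELUState:
    """Narrow the linear segment by ``delta``; idempotent at w = 0."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return BRELUState.from_width(max(0.0, state.width - delta))


# ---------------------------------------------------------------------------
# architecture specs

RECURRENT = "recurrent-spiking"
DENSE = "dense-spiking"
OUTPUT = "output"

_PRESETS = {
    "slstm8": [
        (RECURRENT, 64), (RECURRENT, 64),
        (DENSE, 256), (DENSE, 128), (DENSE, 64), (DENSE, 32), (DENSE, 16),
        (OUTPUT, 2),
    ],
    "slstm7": [
        (RECURRENT, 64), (RECURRENT, 64),
        (DENSE, 256), (DENSE, 128), (DENSE, 64), (DENSE, 32),
        (OUTPUT, 2),
    ],
    "snn7": [
        (DENSE, 256), (DENSE, 128), (DENSE, 64), (DENSE, 64), (DENSE, 32),
        (DENSE, 16), (OUTPUT, 2),
    ],
}
_EXPECTED_DEPTH = {"slstm8": 8, "slstm7": 7, "snn7": 7}


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    width: int


@dataclass
class DetectorSpec:
    """Ordered layer list of one of the three detector architectures."""

    arch_id: str
    layers: list[LayerSpec]
    brelu_states: list[BRELUState] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arch_id in _EXPECTED_DEPTH and len(self.layers) != _EXPECTED_DEPTH[self.arch_id]:
            raise ValueError(
                f"{self.arch_id} must have {_EXPECTED_DEPTH[self.arch_id]} layers"
            )
        if self.layers[-1].kind != OUTPUT or self.layers[-1].width != 2:
            raise ValueError("final layer must be the 2-unit output layer")
        if not self.brelu_states:
            self.brelu_states = [BRELUState() for _ in self.layers]
        if len(self.brelu_states) != len(self.layers):
            raise ValueError("one bRELU state per layer required")

    @property
    def sharpness(self) -> float:
        """Total sharpness, sum over layers of (0.5 - w)."""
        return float(sum(0.5 - s.width for s in self.brelu_states))


def build_detector(arch_id: str, width_scale: float = 1.0,
                   widths: list[int] | None = None) -> DetectorSpec:
    """Instantiate a named preset, optionally scaling/overriding hidden widths."""
    if arch_id not in _PRESETS:
        raise ValueError(f"unknown architecture {arch_id!r}; choose from {sorted(_PRESETS)}")
    preset = _PRESETS[arch_id]
    layers = []
    for i, (kind, w) in enumerate(preset):
        if kind != OUTPUT:
            w = widths[i] if widths is not None else max(2, int(round(w * width_scale)))
        layers.append(LayerSpec(kind, w))
    return DetectorSpec(arch_id=arch_id, layers=layers)


# ---------------------------------------------------------------------------
# training configuration and the adaptive sharpening schedule

@dataclass(frozen=True)
class SharpenPolicy:
    """When and how fast the bRELU half-widths shrink during training.

    Sharpening starts at ``start_epoch`` (0-based), advances the input-most
    unsharpened layer by ``delta`` per epoch, and pauses in any epoch where
    the relative training-loss change over the last ``patience`` epochs
    exceeds ``loss_tol``.
    """

    start_epoch: int = 20
    delta: float = 0.01
    patience: int = 3
    loss_tol: float = 0.05


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.05
    batch_size: int = 128
    seed: int = 0
    policy: SharpenPolicy = SharpenPolicy()
    rho: float = 0.95        # adadelta decay
    eps: float = 1e-6        # adadelta stabilizer
    # "softmax": MSE between the softmax of the output pre-activations and
    # the one-hot target (shift-invariant, so the common offset of the two
    # output units is not a trainable — and not an unstable — direction).
    # "direct": MSE on the bRELU'd output activations themselves.
    decode: str = "softmax"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _loss_is_smooth(losses: list[float], epoch: int, policy: SharpenPolicy) -> bool:
    """Relative loss change over the patience window is within tolerance."""
    lo = max(1, epoch - policy.patience + 1)
    for e in range(lo, epoch + 1):
        if e >= len(losses):
            break
        prev = max(abs(losses[e - 1]), 1e-12)
        if abs(losses[e] - losses[e - 1]) / prev > policy.loss_tol:
            return False
    return True


def adaptive_schedule(history: list[float], policy: SharpenPolicy) -> list[float]:
    """Per-epoch sharpening increments implied by a training-loss history.

    Epoch ``e`` advances by ``policy.delta`` iff ``e >= start_epoch`` and the
    loss has been smooth over the patience window; otherwise the increment is
    0.  The cumulative schedule is therefore monotone non-decreasing.
    """
    if not history:
        raise ValueError("history must be non-empty")
    out = []
    for e in range(len(history)):
        advance = e >= policy.start_epoch and _loss_is_smooth(history, e, policy)
        out.append(policy.delta if advance else 0.0)
    return out


# ---------------------------------------------------------------------------
# parameters, forward and backward passes

def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def _init_params(spec: DetectorSpec, n_input: int, rng: np.random.Generator) -> list[dict]:
    params = []
    d_in = 1 if spec.layers[0].kind == RECURRENT else n_input
    for layer in spec.layers:
        h = layer.width
        if layer.kind == RECURRENT:
            b = np.zeros(4 * h)
            b[h:2 * h] = 1.0  # forget-gate bias favors retention at init
            # input weights scale with 1/sqrt(fan_in) alone: the first layer
            # sees a single scalar per step and needs O(1) weights to move
            # the gates at all
            lim = np.sqrt(3.0 / d_in)
            params.append({
                "Wx": rng.uniform(-lim, lim, size=(d_in, 4 * h)),
                "Wh": _glorot(rng, h, 4 * h),
                "b": b,
            })
        else:
            # dense pre-activations are batch-centered (mean-only batch
            # normalization) with a learned offset b, initialized to the
            # bRELU midpoint 0.5 so units start in the linear segment.
            # _mu/_mu_t hold the running mean used at inference; they are
            # state, not optimized parameters.
            params.append({
                "W": _glorot(rng, d_in, h),
                "b": np.full(h, 0.5),
                "_mu": np.zeros(h),
                "_mu_t": np.zeros(1),
            })
        d_in = h
    return params


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _lstm_forward(x_seq, p, state: BRELUState, mm):
    """x_seq: (B, T, D) -> outputs h_seq (B, T, H) with bRELU'd hidden states."""
    B, T, D = x_seq.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = {"x": x_seq, "i": [], "f": [], "o": [], "g": [], "c": [],
             "tc": [], "hhat": [], "hprev": [], "cprev": []}
    h_seq = np.empty((B, T, H))
    # the input projection has no recurrence: compute it for every timestep
    # in one matrix product
    xproj = mm(x_seq.reshape(B * T, D), p["Wx"]).reshape(B, T, 4 * H)
    for t in range(T):
        z = xproj[:, t, :] + mm(h, p["Wh"]) + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        o = _sigmoid(z[:, 2 * H:3 * H])
        g = np.tanh(z[:, 3 * H:])
        cache["hprev"].append(h)
        cache["cprev"].append(c)
        c = f * c + i * g
        tc = np.tanh(c)
        # pre-activation is offset to the bRELU midpoint: a sharpened unit
        # emits a spike exactly when its signed output o*tanh(c) exceeds 0
        hhat = o * tc + 0.5
        h = brelu(hhat, state)
        for k, v in (("i", i), ("f", f), ("o", o), ("g", g), ("c", c),
                     ("tc", tc), ("hhat", hhat)):
            cache[k].append(v)
        h_seq[:, t, :] = h
    return h_seq, cache


def _lstm_backward(dh_seq, p, state: BRELUState, cache):
    """BPTT through one LSTM layer; returns (dx_seq, grads)."""
    x_seq = cache["x"]
    B, T, D = x_seq.shape
    H = p["Wh"].shape[0]
    dz_all = np.empty((B, T, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, o, g = cache["i"][t], cache["f"][t], cache["o"][t], cache["g"][t]
        tc, hhat = cache["tc"][t], cache["hhat"][t]
        dh = dh_seq[:, t, :] + dh_next
        dhhat = dh * brelu_grad(hhat, state)
        do = dhhat * tc
        dc = dc_next + dhhat * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * cache["cprev"][t]
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
             dg * (1 - g * g)], axis=1)
        dz_all[:, t, :] = dz
        dh_next = dz @ p["Wh"].T
        dc_next = dc * f
    # weight gradients and input gradients batched over all timesteps
    dz_flat = dz_all.reshape(B * T, 4 * H)
    h_prev = np.stack(cache["hprev"], axis=1).reshape(B * T, H)
    grads = {
        "Wx": x_seq.reshape(B * T, D).T @ dz_flat,
        "Wh": h_prev.T @ dz_flat,
        "b": dz_flat.sum(axis=0),
    }
    dx_seq = (dz_flat @ p["Wx"].T).reshape(B, T, D)
    return dx_seq, grads


def _default_mm(x, W):
    return x @ W


_BN_MOMENTUM = 0.9


def _forward(spec: DetectorSpec, params: list[dict], X: np.ndarray,
             mm=_default_mm, want_cache: bool = False,
             training: bool = False):
    """Full forward pass.

    X is the (B, L) matrix of normalized spike-time vectors.  Returns
    (z_out, y_out, caches): pre-threshold output activations, thresholded
    outputs, and per-layer caches for backprop.
    """
    caches: list = []
    if spec.layers[0].kind == RECURRENT:
        a = X[:, :, None]  # (B, T, 1) sequence of scalars
    else:
        a = X
    z_out = None
    for li, layer in enumerate(spec.layers):
        st = spec.brelu_states[li]
        p = params[li]
        if layer.kind == RECURRENT:
            a, cache = _lstm_forward(a, p, st, mm)
            # the dense stack reads the time-average of the last recurrent
            # layer's spiking outputs — a firing-rate readout that survives
            # the zero-padding tail of the input sequence
            nxt = spec.layers[li + 1] if li + 1 < len(spec.layers) else None
            pooled = nxt is not None and nxt.kind != RECURRENT
            caches.append({"kind": RECURRENT, "cache": cache, "T": a.shape[1],
                           "pooled": pooled})
            if pooled:
                a = a.mean(axis=1)
        else:
            z_lin = mm(a, p["W"])
            if training:
                bm = z_lin.mean(axis=0)
                p["_mu_t"][0] += 1.0
                p["_mu"] *= _BN_MOMENTUM
                p["_mu"] += (1.0 - _BN_MOMENTUM) * bm
            else:
                t = p["_mu_t"][0]
                # debiased running mean; a never-trained layer centers at 0
                bm = p["_mu"] / (1.0 - _BN_MOMENTUM ** t) if t > 0 else 0.0
            z = z_lin - bm + p["b"]
            y = brelu(z, st)
            caches.append({"kind": layer.kind, "x": a, "z": z})
            if layer.kind == OUTPUT:
                z_out = z
            a = y
    return z_out, a, (caches if want_cache else None)


def _backward(spec: DetectorSpec, params: list[dict], caches: list,
              d_y_out: np.ndarray, dz_out: np.ndarray | None = None) -> list[dict]:
    """Backprop the loss gradient w.r.t. the output activations.

    ``dz_out``, when given, is the loss gradient w.r.t. the output layer's
    pre-threshold activations and bypasses the output bRELU (used by the
    softmax decode).
    """
    grads: list[dict | None] = [None] * len(spec.layers)
    da = d_y_out
    for li in range(len(spec.layers) - 1, -1, -1):
        st = spec.brelu_states[li]
        cache = caches[li]
        if li == len(spec.layers) - 1 and dz_out is not None:
            dzlin = dz_out - dz_out.mean(axis=0)  # through batch centering
            grads[li] = {"W": cache["x"].T @ dzlin, "b": dz_out.sum(axis=0)}
            da = dzlin @ params[li]["W"].T
            continue
        if cache["kind"] == RECURRENT:
            if cache["pooled"]:
                T = cache["T"]
                dh_seq = np.repeat(da[:, None, :] / T, T, axis=1)
            else:
                dh_seq = da
            da, g = _lstm_backward(dh_seq, params[li], st, cache["cache"])
            if li == 0:
                pass  # gradient w.r.t. the input sequence is discarded
            grads[li] = g
        else:
            dz = da * brelu_grad(cache["z"], st)
            dzlin = dz - dz.mean(axis=0)  # through batch centering
            grads[li] = {"W": cache["x"].T @ dzlin, "b": dz.sum(axis=0)}
            da = dzlin @ params[li]["W"].T
    return grads  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# the trained artifact

@dataclass
class TrainedDetector:
    spec: DetectorSpec
    params: list[dict]
    history: dict[str, list[float]]
    T_max: float
    L_max: int
    seed: int = 0

    def inputs_from(self, ds: SpikeDataset) -> np.ndarray:
        if ds.L_max != self.L_max:
            raise ValueError(
                f"dataset L_max {ds.L_max} does not match detector {self.L_max}"
            )
        return ds.times_matrix() / self.T_max

    def forward(self, X: np.ndarray, mm=_default_mm):
        z, y, _ = _forward(self.spec, self.params, X, mm=mm)
        return z, y


def init_detector(spec: DetectorSpec, L_max: int, T_max: float,
                  seed: int = 0) -> TrainedDetector:
    rng = np.random.default_rng(seed)
    return TrainedDetector(
        spec=spec,
        params=_init_params(spec, L_max, rng),
        history={"loss": [], "train_acc": [], "val_acc": [], "sharpness": []},
        T_max=T_max,
        L_max=L_max,
        seed=seed,
    )


class _Adadelta:
    """Adadelta with a learning-rate multiplier (rho/eps per the classic rule)."""

    def __init__(self, params: list[dict], lr: float, rho: float, eps: float):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.Eg = [{k: np.zeros_like(v) for k, v in p.items()
                    if not k.startswith("_")} for p in params]
        self.Ed = [{k: np.zeros_like(v) for k, v in p.items()
                    if not k.startswith("_")} for p in params]

    def step(self, params: list[dict], grads: list[dict]) -> None:
        for p, g, eg, ed in zip(params, grads, self.Eg, self.Ed):
            for k in eg:
                eg[k] = self.rho * eg[k] + (1 - self.rho) * g[k] ** 2
                dx = -np.sqrt(ed[k] + self.eps) / np.sqrt(eg[k] + self.eps) * g[k]
                ed[k] = self.rho * ed[k] + (1 - self.rho) * dx ** 2
                p[k] += self.lr * dx


def _advance_sharpening(spec: DetectorSpec, delta: float) -> None:
    """Narrow the input-most layer that is not yet fully sharp."""
    if delta <= 0:
        return
    for li, st in enumerate(spec.brelu_states):
        if st.width > 0:
            spec.brelu_states[li] = sharpen(st, delta)
            return


def _accuracy(z_out: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(_argmax_class(z_out) == labels))


def _argmax_class(z_out: np.ndarray) -> np.ndarray:
    ties = z_out[:, 0] == z_out[:, 1]
    if np.any(ties):
        log.warning("%d tied output activations resolved to class 0", ties.sum())
    return (z_out[:, 1] > z_out[:, 0]).astype(int)


def _batched_forward(det: TrainedDetector, X: np.ndarray, mm=_default_mm,
                     batch: int = 512) -> np.ndarray:
    outs = [det.forward(X[i:i + batch], mm=mm)[0] for i in range(0, len(X), batch)]
    return np.concatenate(outs)


def train(spec: DetectorSpec, train_ds: SpikeDataset, val_ds: SpikeDataset,
          cfg: TrainConfig) -> TrainedDetector:
    """Train a detector with MSE loss, adadelta, and adaptive sharpening.

    Deterministic for a fixed ``cfg.seed``.  The per-epoch history records
    mean training loss, train/validation accuracy and total sharpness.
    """
    if train_ds.L_max != val_ds.L_max or train_ds.T_max != val_ds.T_max:
        raise ValueError("train and validation datasets must share L_max and T_max")
    spec = DetectorSpec(spec.arch_id, list(spec.layers),
                        list(spec.brelu_states))  # private copy; mutated below
    det = init_detector(spec, train_ds.L_max, train_ds.T_max, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    Xtr = det.inputs_from(train_ds)
    ytr = train_ds.labels
    Xva = det.inputs_from(val_ds)
    yva = val_ds.labels
    if set(np.unique(ytr)) - {0, 1}:
        raise ValueError("labels must be binary")
    onehot = np.eye(2)[ytr]
    opt = _Adadelta(det.params, cfg.learning_rate, cfg.rho, cfg.eps)
    n = len(Xtr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, tb = Xtr[idx], onehot[idx]
            z, y, caches = _forward(spec, det.params, xb, want_cache=True,
                                    training=True)
            if cfg.decode == "softmax":
                p = _softmax(z)
                err = p - tb
                dp = 2.0 * err / err.size
                dz = p * (dp - np.sum(dp * p, axis=1, keepdims=True))
                loss = float(np.mean(err ** 2))
                grads = _backward(spec, det.params, caches,
                                  np.zeros_like(dz), dz_out=dz)
            else:
                err = y - tb
                loss = float(np.mean(err ** 2))
                dy = 2.0 * err / err.size
                grads = _backward(spec, det.params, caches, dy)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            losses.append(loss)
            opt.step(det.params, grads)
        det.history["loss"].append(float(np.mean(losses)))
        det.history["train_acc"].append(
            _accuracy(_batched_forward(det, Xtr), ytr))
        det.history["val_acc"].append(
            _accuracy(_batched_forward(det, Xva), yva))
        det.history["sharpness"].append(spec.sharpness)
        log.info(
            "epoch %3d loss %.5f train_acc %.4f val_acc %.4f sharpness %.3f",
            epoch, det.history["loss"][-1], det.history["train_acc"][-1],
            det.history["val_acc"][-1], spec.sharpness)
        deltas = adaptive_schedule(det.history["loss"], cfg.policy)
        _advance_sharpening(spec, deltas[-1])
    return det


def predict(det: TrainedDetector, ds: SpikeDataset, mode: str = "binary",
            mm=_default_mm) -> np.ndarray:
    """Binary labels (argmax of output pre-threshold activations; tie -> 0)
    or PD-unit scores for ranking metrics such as AUC."""
    z = _batched_forward(det, det.inputs_from(ds), mm=mm)
    if mode == "binary":
        return _argmax_class(z)
    if mode == "score":
        return z[:, 1]
    raise ValueError("mode must be 'binary' or 'score'")


# ---------------------------------------------------------------------------
# weight archive (HDF5)

def export_weights(det: TrainedDetector, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["arch_id"] = det.spec.arch_id
        f.attrs["seed"] = det.seed
        f.attrs["T_max"] = det.T_max
        f.attrs["L_max"] = det.L_max
        f.attrs["epochs"] = len(det.history["loss"])
        hist = f.create_group("history")
        for k, v in det.history.items():
            hist.create_dataset(k, data=np.asarray(v, dtype=float))
        for li, (layer, p, st) in enumerate(
                zip(det.spec.layers, det.params, det.spec.brelu_states)):
            g = f.create_group(f"layer_{li:03d}")
            g.attrs["kind"] = layer.kind
            g.attrs["width"] = layer.width
            g.attrs["alpha"] = st.alpha
            g.attrs["beta"] = st.beta
            for k, v in p.items():
                g.create_dataset(k, data=v)
    return path


def import_weights(path: str | Path) -> TrainedDetector:
    with h5py.File(Path(path), "r") as f:
        layers, states, params = [], [], []
        li = 0
        while f"layer_{li:03d}" in f:
            g = f[f"layer_{li:03d}"]
            layers.append(LayerSpec(g.attrs["kind"], int(g.attrs["width"])))
            states.append(BRELUState(float(g.attrs["alpha"]), float(g.attrs["beta"])))
            params.append({k: np.array(g[k]) for k in g})
            li += 1
        spec = DetectorSpec(str(f.attrs["arch_id"]), layers, states)
        history = {k: list(np.array(f["history"][k])) for k in f["history"]}
        return TrainedDetector(
            spec=spec,
            params=params,
            history=history,
            T_max=float(f.attrs["T_max"]),
            L_max=int(f.attrs["L_max"]),
            seed=int(f.attrs["seed"]),
        )
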