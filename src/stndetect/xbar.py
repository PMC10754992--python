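"""Simulated memristive crossbar inference.

A weight matrix is encoded on a differential pair of conductance crossbars
(one for positive parts, one for negative magnitudes), each cell quantized
to 2**precision_bits uniform levels between 1/R_off and 1/R_on.  Inference
runs the analog vector-matrix multiplication I_j = sum_i V_i * G_ij per
subarray tile (default 128 x 128); subtraction of the two crossbars' currents
and rescaling recovers the signed weighted sum, which feeds the software
activation/threshold stages of the trained detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sharpnet
from .spikegen import SpikeDataset

__all__ = [
    "DeviceModel",
    "CrossbarPair",
    "vmm",
    "weights_to_conductance",
    "conductance_to_weight",
    "tiled_matmul",
    "crossbar_predict",
]


@dataclass(frozen=True)
class DeviceModel:
    """Memristor device and array parameters."""

    R_on: float = 6e3          # ohm, low-resistance state
    R_off: float = 6e3 * 150   # ohm, high-resistance state
    read_voltage: float = 0.5  # V
    precision_bits: int = 2    # levels per device = 2**bits
    subarray: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if not self.R_off > self.R_on > 0:
            raise ValueError("require R_off > R_on > 0")
        if self.precision_bits < 1:
            raise ValueError("precision_bits must be >= 1")
        if min(self.subarray) < 1:
            raise ValueError("subarray dimensions must be >= 1")

    @property
    def g_min(self) -> float:
        return 1.0 / self.R_off

    @property
    def g_max(self) -> float:
        return 1.0 / self.R_on

    def levels(self) -> np.ndarray:
        """The uniform conductance grid of 2**precision_bits levels."""
        return np.linspace(self.g_min, self.g_max, 2 ** self.precision_bits)


@dataclass(frozen=True)
class CrossbarPair:
    """Positive/negative conductance matrices implementing a signed weight
    matrix as G_pos - G_neg (both offset by g_min, which cancels)."""

    G_pos: np.ndarray
    G_neg: np.ndarray
    device: DeviceModel
    scale: float  # weight units per siemens of differential conductance

    def __post_init__(self) -> None:
        if self.G_pos.shape != self.G_neg.shape:
            raise ValueError("G_pos and G_neg must share a shape")


def vmm(V: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Analog crossbar product: I_j = sum_i V_i G_ij (V volts, G siemens)."""
    V = np.asarray(V, dtype=float)
    G = np.asarray(G, dtype=float)
    if V.shape[-1] != G.shape[0]:
        raise ValueError(
            f"shape mismatch: input of length {V.shape[-1]} into "
            f"{G.shape[0]}-row crossbar")
    return V @ G


def _quantize(G: np.ndarray, device: DeviceModel) -> np.ndarray:
    lv = device.levels()
    step = lv[1] - lv[0] if lv.size > 1 else 0.0
    if step == 0.0:
        return np.full_like(G, lv[0])
    k = np.clip(np.round((G - lv[0]) / step), 0, lv.size - 1)
    return lv[0] + k * step


def weights_to_conductance(W: np.ndarray, device: DeviceModel) -> CrossbarPair:
    """Map a signed weight matrix onto a quantized differential pair.

    [0, max|W|] maps linearly onto [g_min, g_max]; positive entries program
    the positive crossbar, negative magnitudes the negative one, the other
    cell of each pair rests at g_min.
    """
    W = np.asarray(W, dtype=float)
    w_max = float(np.max(np.abs(W))) if W.size else 0.0
    g_span = device.g_max - device.g_min
    if w_max == 0.0:
        g = np.full(W.shape, device.g_min)
        return CrossbarPair(G_pos=g, G_neg=g.copy(), device=device, scale=1.0)
    scale = w_max / g_span
    G_pos = device.g_min + np.maximum(W, 0.0) / scale
    G_neg = device.g_min + np.maximum(-W, 0.0) / scale
    return CrossbarPair(
        G_pos=_quantize(G_pos, device),
        G_neg=_quantize(G_neg, device),
        device=device,
        scale=scale,
    )


def conductance_to_weight(pair: CrossbarPair) -> np.ndarray:
    """Inverse of the mapping (exact before rounding): the g_min offsets of
    the differential pair cancel, so W = (G_pos - G_neg) * scale."""
    return (pair.G_pos - pair.G_neg) * pair.scale


def tiled_matmul(pair: CrossbarPair, X: np.ndarray) -> np.ndarray:
    """Differential current X @ (G_pos - G_neg), computed tile by tile.

    Matrices larger than the device subarray are partitioned into tiles of at
    most (rows, cols); partial bit-line currents are summed.  Exactly equals
    the untiled differential vmm.
    """
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[None, :]
    n_in, n_out = pair.G_pos.shape
    tr, tc = pair.device.subarray
    out = np.zeros((X.shape[0], n_out))
    for r in range(0, n_in, tr):
        for c in range(0, n_out, tc):
            gp = pair.G_pos[r:r + tr, c:c + tc]
            gn = pair.G_neg[r:r + tr, c:c + tc]
            v = X[:, r:r + tr]
            out[:, c:c + tc] += vmm(v, gp) - vmm(v, gn)
    return out[0] if squeeze else out


def crossbar_predict(det: "sharpnet.TrainedDetector", ds: SpikeDataset,
                     device: DeviceModel | None = None,
                     mode: str = "binary") -> np.ndarray:
    """Run detector inference with every weight matrix product executed on a
    simulated crossbar pair.

    Activations in [0, 1] are applied as read_voltage-scaled word-line
    voltages; bit-line currents are converted back to weight units by
    1 / (read_voltage * scale) before the software bias/threshold stages, so
    inference is numerically identical to software in the fine-quantization
    limit.  Biases stay in software.
    """
    device = device or DeviceModel()
    pairs: dict[int, CrossbarPair] = {}
    for p in det.params:
        for name, W in p.items():
            if name != "b":
                pairs[id(W)] = weights_to_conductance(W, device)

    vr = device.read_voltage

    def mm(x: np.ndarray, W: np.ndarray) -> np.ndarray:
        pair = pairs[id(W)]
        current = tiled_matmul(pair, x * vr)
        return current * (pair.scale / vr)

    return sharpnet.predict(det, ds, mode, mm=mm)
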