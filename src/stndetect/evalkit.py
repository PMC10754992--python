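"""Evaluation: confusion counts, the ten performance measures, AUC,
beta-band spectral analysis, and the Gaussian timing-noise robustness
protocol.

The positive class is PD throughout.  Metrics with a zero denominator are
reported as NaN and flagged, never silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import sharpnet
from .spikegen import (
    PD,
    SpikeDataset,
    SpikeTrainSample,
    generate_dataset,
    split_dataset,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "NoiseSpec",
    "confusion",
    "metrics_from_confusion",
    "auc_from_scores",
    "evaluate",
    "add_timing_noise",
    "psd",
    "beta_band_power",
    "noise_robustness_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with PD as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_matrix(self) -> np.ndarray:
        """Rows = true (healthy, PD); columns = predicted (healthy, PD)."""
        return np.array([[self.TN, self.FP], [self.FN, self.TP]])


@dataclass(frozen=True)
class MetricsReport:
    """The ten derived performance measures plus the underlying counts.

    Undefined ratios (zero denominator) are NaN and listed in ``undefined``.
    """

    counts: ConfusionCounts
    ACC: float
    MCR: float
    AUC: float
    precision: float
    recall: float
    specificity: float
    FPR: float
    FNR: float
    F1: float
    MCC: float
    undefined: tuple[str, ...] = ()

    _FIELDS = ("ACC", "MCR", "AUC", "precision", "recall", "specificity",
               "FPR", "FNR", "F1", "MCC")

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in self._FIELDS})

    def rounded(self, decimals: int = 4) -> dict[str, float]:
        """Display rounding used in report tables."""
        return {k: round(getattr(self, k), decimals) for k in self._FIELDS}


def confusion(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (predictions == 1))),
        TN=int(np.sum((labels == 0) & (predictions == 0))),
        FP=int(np.sum((labels == 0) & (predictions == 1))),
        FN=int(np.sum((labels == 1) & (predictions == 0))),
    )


def auc_from_scores(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    from scipy.stats import rankdata

    r = rankdata(scores)
    u = np.sum(r[labels == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _ratio(num: float, den: float, name: str, undef: list[str]) -> float:
    if den == 0:
        undef.append(name)
        return math.nan
    return num / den


def metrics_from_confusion(c: ConfusionCounts, labels=None,
                           scores=None) -> MetricsReport:
    """All Table-style measures from the counts; AUC only if scores given."""
    undef: list[str] = []
    n = c.total
    acc = _ratio(c.TP + c.TN, n, "ACC", undef)
    prec = _ratio(c.TP, c.TP + c.FP, "precision", undef)
    rec = _ratio(c.TP, c.TP + c.FN, "recall", undef)
    spec_ = _ratio(c.TN, c.TN + c.FP, "specificity", undef)
    fpr = 1.0 - spec_ if not math.isnan(spec_) else math.nan
    fnr = 1.0 - rec if not math.isnan(rec) else math.nan
    if math.isnan(prec) or math.isnan(rec) or (prec + rec) == 0:
        undef.append("F1")
        f1 = math.nan
    else:
        f1 = 2 * prec * rec / (prec + rec)
    denom = math.sqrt(
        float(c.TP + c.FP) * float(c.TP + c.FN)
        * float(c.TN + c.FP) * float(c.TN + c.FN))
    mcc = _ratio(float(c.TP) * c.TN - float(c.FP) * c.FN, denom, "MCC", undef)
    if scores is not None:
        if labels is None:
            raise ValueError("labels are required to compute AUC from scores")
        auc = auc_from_scores(labels, scores)
    else:
        undef.append("AUC")
        auc = math.nan
    return MetricsReport(
        counts=c, ACC=acc, MCR=1.0 - acc if not math.isnan(acc) else math.nan,
        AUC=auc, precision=prec, recall=rec, specificity=spec_, FPR=fpr,
        FNR=fnr, F1=f1, MCC=mcc, undefined=tuple(undef),
    )


def evaluate(det: "sharpnet.TrainedDetector", ds: SpikeDataset) -> MetricsReport:
    labels = ds.labels
    pred = sharpnet.predict(det, ds, "binary")
    scores = sharpnet.predict(det, ds, "score")
    return metrics_from_confusion(confusion(labels, pred), labels, scores)


# ---------------------------------------------------------------------------
# Gaussian spike-timing noise

@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian jitter on every nonzero spike time (ms)."""

    mu: float = 0.0
    sigma: float = 0.0
    seed: int = 0
    applies_to: str = "both"  # train | val | both

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.applies_to not in ("train", "val", "both"):
            raise ValueError("applies_to must be train, val or both")


def add_timing_noise(ds: SpikeDataset, spec: NoiseSpec) -> SpikeDataset:
    """Replace every nonzero spike time x by x + N(mu, sigma), in place in the
    vector (padding zeros untouched, order NOT re-sorted), clipped to
    (0, T_max].  Deterministic under the NoiseSpec seed."""
    rng = np.random.default_rng(spec.seed)
    mat = ds.times_matrix()
    nz = mat > 0
    noise = rng.normal(spec.mu, spec.sigma, size=mat.shape)
    noisy = np.where(nz, np.clip(mat + noise, 1e-3, ds.T_max), 0.0)
    noisy = np.round(noisy, 3)
    samples = [
        SpikeTrainSample(spike_times=noisy[i], label=s.label,
                         sample_id=s.sample_id, source=s.source)
        for i, s in enumerate(ds.samples)
    ]
    prov = dict(ds.provenance)
    prov["noise"] = {"mu": spec.mu, "sigma": spec.sigma, "seed": spec.seed}
    return SpikeDataset(samples=samples, T_max=ds.T_max, L_max=ds.L_max,
                        provenance=prov)


# ---------------------------------------------------------------------------
# spectral analysis

def psd(trains, duration: float, bin_ms: float = 1.0,
        window_ms: float = 1000.0, overlap: float = 0.5,
        smooth_ms: float = 5.0):
    """Welch power spectrum of one spike train or a population.

    ``trains`` is an array of spike times (ms) or a list of such arrays;
    lists are summed into one population train.  Spikes are binned at
    ``bin_ms`` resolution, convolved with a Gaussian kernel of width
    ``smooth_ms`` (the usual spike-density smoothing; it attenuates the
    harmonics of regular firing that would otherwise alias band
    comparisons), and a Welch-averaged periodogram with ``window_ms``
    segments at the given overlap is returned as ``(freqs_hz, power)``.
    Pass ``smooth_ms=0`` for the raw binned train.
    """
    if isinstance(trains, np.ndarray) and trains.ndim == 1:
        trains = [trains]
    n_bins = int(round(duration / bin_ms))
    counts = np.zeros(n_bins)
    for t in trains:
        t = np.asarray(t, dtype=float)
        t = t[(t > 0) & (t <= duration)]
        idx = np.minimum((t / bin_ms).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
    if smooth_ms > 0:
        half = int(np.ceil(4 * smooth_ms / bin_ms))
        x = np.arange(-half, half + 1) * bin_ms
        kern = np.exp(-0.5 * (x / smooth_ms) ** 2)
        kern /= kern.sum()
        counts = np.convolve(counts, kern, mode="same")
    fs = 1000.0 / bin_ms
    nperseg = min(n_bins, int(round(window_ms / bin_ms)))
    freqs, power = _signal.welch(
        counts - counts.mean(), fs=fs, nperseg=nperseg,
        noverlap=int(overlap * nperseg), detrend=False)
    return freqs, power


def beta_band_power(spectrum, lo: float = 13.0, hi: float = 30.0) -> float:
    """Integral of the spectrum over [lo, hi] Hz (0 for an empty band)."""
    freqs, power = spectrum
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        return float(power[m].sum())
    return float(np.trapezoid(power[m], freqs[m]))


def mean_beta_power(ds: SpikeDataset, label: int, bin_ms: float = 1.0) -> float:
    """Mean per-sample beta-band power over one class of a dataset."""
    vals = [
        beta_band_power(psd(s.times, ds.T_max, bin_ms=bin_ms))
        for s in ds.samples if s.label == label
    ]
    if not vals:
        raise ValueError("no samples of the requested label")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# noise-robustness protocol

def noise_robustness_report(
    arch_id: str,
    noise_settings: list[tuple[float, float]] = ((7.0, 4.0), (15.0, 12.0), (30.0, 25.0)),
    *,
    params=None,
    n_groups: int = 50,
    neurons_per_group: int = 15,
    duration: float = 2500.0,
    train_frac: float = 0.75,
    seeds: tuple[int, ...] = (0, 1, 2),
    train_cfg: "sharpnet.TrainConfig | None" = None,
    width_scale: float = 1.0,
    applies_to: str = "both",
) -> pd.DataFrame:
    """Train/evaluate under a clean baseline and each (mu, sigma) jitter.

    The same split fraction and training protocol are used throughout; noise
    is applied to the partitions named by ``applies_to``.  Returns one row
    per (setting, seed) with the full metric set.
    """
    from .spikegen import PhenoParams

    params = params or PhenoParams()
    cfg = train_cfg or sharpnet.TrainConfig()
    rows = []
    settings = [None] + [tuple(s) for s in noise_settings]
    for seed in seeds:
        ds = generate_dataset(params, n_groups, neurons_per_group, duration,
                              seed=seed)
        tr, va = split_dataset(ds, train_frac, stratified=True, seed=seed)
        for setting in settings:
            tr_s, va_s = tr, va
            if setting is not None:
                mu, sigma = setting
                if applies_to in ("train", "both"):
                    tr_s = add_timing_noise(
                        tr, NoiseSpec(mu, sigma, seed=seed * 1000 + 1))
                if applies_to in ("val", "both"):
                    va_s = add_timing_noise(
                        va, NoiseSpec(mu, sigma, seed=seed * 1000 + 2))
            spec = sharpnet.build_detector(arch_id, width_scale=width_scale)
            det = sharpnet.train(spec, tr_s, va_s,
                                 _dc_replace(cfg, seed=seed))
            rep = evaluate(det, va_s)
            row = {"setting": "clean" if setting is None
                   else f"mu{setting[0]:g}_sigma{setting[1]:g}",
                   "mu": 0.0 if setting is None else setting[0],
                   "sigma": 0.0 if setting is None else setting[1],
                   "seed": seed}
            row.update(rep.rounded())
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
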