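"""Synthetic STN spike-timing datasets for healthy and parkinsonian states.

The classifier's unit of input is one neuron's zero-padded vector of spike
times (milliseconds) over a fixed observation window.  Healthy trains are
refractory-modified Poisson processes; parkinsonian (PD) trains are
inhomogeneous Poisson processes whose rate is modulated sinusoidally in the
beta band (13-30 Hz), reproducing the two biomarkers that separate the
states in STN recordings: denser firing and elevated beta-band power.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "T_MAX_DEFAULT",
    "L_MAX_DEFAULT",
    "HEALTHY",
    "PD",
    "SpikeTrainSample",
    "SpikeDataset",
    "PhenoParams",
    "SpikeOverflowError",
    "DatasetFormatError",
    "generate_sample",
    "generate_dataset",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]

T_MAX_DEFAULT = 2500.0  # ms, observation window
L_MAX_DEFAULT = 128     # padded vector length; > expected max spike count
_TIME_RESOLUTION = 1e-3  # ms; file storage resolution (3 decimals)

HEALTHY = 0
PD = 1


class SpikeOverflowError(RuntimeError):
    """A generated train exceeded the padded vector length L_max."""


class DatasetFormatError(ValueError):
    """A dataset file violates the on-disk contract (names row/column)."""


@dataclass(frozen=True)
class SpikeTrainSample:
    """One neuron's zero-padded spike-time vector with its state label.

    ``spike_times`` has fixed length ``L_max``: genuine spikes occupy a
    prefix of strictly positive times, trailing entries are padding zeros.
    """

    spike_times: np.ndarray
    label: int
    sample_id: str
    source: str = "pheno"  # pheno | circuit | file

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )

    @property
    def n_spikes(self) -> int:
        return int(np.count_nonzero(self.spike_times))

    @property
    def times(self) -> np.ndarray:
        """The nonzero (genuine) spike times."""
        return self.spike_times[self.spike_times > 0]


@dataclass
class SpikeDataset:
    """A labeled collection of spike-timing samples plus provenance."""

    samples: list[SpikeTrainSample]
    T_max: float
    L_max: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def class_counts(self) -> tuple[int, int]:
        lab = self.labels
        return int(np.sum(lab == HEALTHY)), int(np.sum(lab == PD))

    def times_matrix(self) -> np.ndarray:
        """(n_samples, L_max) matrix of padded spike times in ms."""
        return np.stack([s.spike_times for s in self.samples])

    def validate(self, require_sorted: bool = True) -> None:
        for k, s in enumerate(self.samples):
            if s.spike_times.shape != (self.L_max,):
                raise ValueError(
                    f"sample {k} ({s.sample_id}): length "
                    f"{s.spike_times.shape} != L_max={self.L_max}"
                )
            _validate_sample_times(
                s.spike_times,
                self.T_max,
                require_sorted=require_sorted and s.source != "file",
                ident=s.sample_id,
            )
        h, p = self.class_counts
        if h + p != len(self.samples):
            raise ValueError("class counts do not partition the dataset")


def _validate_sample_times(
    v: np.ndarray, t_max: float, require_sorted: bool, ident: str
) -> None:
    nz = np.flatnonzero(v)
    if nz.size:
        if nz[-1] != nz.size - 1:
            raise ValueError(f"{ident}: padding zeros must trail the spikes")
        t = v[: nz.size]
        if np.any(t <= 0) or np.any(t > t_max):
            raise ValueError(f"{ident}: spike times must lie in (0, {t_max}]")
        if np.any(np.diff(t) <= 0):
            if require_sorted:
                raise ValueError(f"{ident}: spike times not strictly increasing")
            warnings.warn(
                f"{ident}: unsorted spike times accepted (perturbed data)",
                stacklevel=3,
            )


@dataclass(frozen=True)
class PhenoParams:
    """Parameters of the phenomenological spike generator.

    rate_healthy / rate_pd are mean firing rates in Hz; the PD rate is
    modulated as ``rate_pd * (1 + mod_depth * sin(2*pi*beta_freq*t + phi))``
    with a uniform random phase per sample.  ``refractory`` (ms) enforces a
    minimum inter-spike interval without biasing the mean rate.
    """

    rate_healthy: float = 10.0
    rate_pd: float = 25.0
    beta_freq: float = 20.0
    mod_depth: float = 0.8
    refractory: float = 3.0

    def __post_init__(self) -> None:
        if not self.rate_pd > self.rate_healthy >= 0:
            raise ValueError("require rate_pd > rate_healthy >= 0")
        if not 13.0 <= self.beta_freq <= 30.0:
            raise ValueError("beta_freq must lie in the beta band [13, 30] Hz")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must lie in [0, 1]")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pad(times: np.ndarray, l_max: int, ident: str) -> np.ndarray:
    if times.size > l_max:
        raise SpikeOverflowError(
            f"{ident}: {times.size} spikes exceed L_max={l_max}"
        )
    out = np.zeros(l_max)
    # storage resolution is 0.001 ms, so file round-trips are bit-stable
    out[: times.size] = np.round(times, 3)
    return out


def _homogeneous_train(
    rate_hz: float, duration: float, refractory: float, rng: np.random.Generator
) -> np.ndarray:
    """Renewal train with mean rate ``rate_hz`` and a dead time.

    Gaps are refractory + Exp(mean 1/rate - refractory), so the mean
    inter-spike interval equals 1/rate exactly.
    """
    if rate_hz <= 0:
        return np.empty(0)
    mean_gap = 1000.0 / rate_hz  # ms
    if refractory >= mean_gap:
        raise ValueError("refractory period exceeds the mean inter-spike gap")
    # expected count + 8 sd margin, so truncation is essentially impossible
    n_draw = int(duration / mean_gap + 8 * np.sqrt(duration / mean_gap) + 16)
    gaps = refractory + rng.exponential(mean_gap - refractory, size=n_draw)
    t = np.cumsum(gaps)
    return t[t <= duration]


def _beta_modulated_train(
    rate_hz: float,
    beta_freq: float,
    mod_depth: float,
    duration: float,
    refractory: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson train by thinning, with a dead time."""
    if rate_hz <= 0:
        return np.empty(0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    lam_max = rate_hz * (1.0 + mod_depth)  # Hz
    cand = _homogeneous_train(lam_max, duration, 0.0, rng)
    lam = rate_hz * (
        1.0 + mod_depth * np.sin(2.0 * np.pi * beta_freq * cand / 1000.0 + phi)
    )
    keep = rng.uniform(size=cand.size) * lam_max < lam
    t = cand[keep]
    if refractory > 0 and t.size > 1:
        # enforce the dead time sequentially
        kept = [t[0]]
        for x in t[1:]:
            if x - kept[-1] >= refractory:
                kept.append(x)
        t = np.array(kept)
    return t


def generate_sample(
    params: PhenoParams,
    state: int,
    duration: float,
    rng: np.random.Generator,
    *,
    L_max: int = L_MAX_DEFAULT,
    sample_id: str = "sample",
) -> SpikeTrainSample:
    """Draw one labeled spike-timing sample of the given state."""
    if state not in (HEALTHY, PD):
        raise ValueError(f"state must be {HEALTHY} (healthy) or {PD} (PD)")
    if state == HEALTHY:
        t = _homogeneous_train(params.rate_healthy, duration, params.refractory, rng)
    else:
        t = _beta_modulated_train(
            params.rate_pd,
            params.beta_freq,
            params.mod_depth,
            duration,
            params.refractory,
            rng,
        )
    return SpikeTrainSample(
        spike_times=_pad(t, L_max, sample_id),
        label=state,
        sample_id=sample_id,
        source="pheno",
    )


def generate_dataset(
    params: PhenoParams,
    n_groups: int,
    neurons_per_group: int,
    duration: float = T_MAX_DEFAULT,
    *,
    seed: int = 0,
    L_max: int = L_MAX_DEFAULT,
    T_max: float | None = None,
    states: Sequence[int] = (HEALTHY, PD),
) -> SpikeDataset:
    """Generate ``len(states) * n_groups * neurons_per_group`` samples.

    A "group" is a recording of ``neurons_per_group`` neurons; the classifier
    consumes the per-neuron samples individually, groups exist only in the
    sample identifiers.
    """
    if n_groups < 1 or neurons_per_group < 1:
        raise ValueError("n_groups and neurons_per_group must be >= 1")
    T_max = float(duration if T_max is None else T_max)
    if duration > T_max:
        raise ValueError("duration must not exceed T_max")
    rng = np.random.default_rng(seed)
    names = {HEALTHY: "healthy", PD: "pd"}
    samples: list[SpikeTrainSample] = []
    for state in states:
        for g in range(n_groups):
            for n in range(neurons_per_group):
                sid = f"{names[state]}-g{g:04d}-n{n:02d}"
                samples.append(
                    generate_sample(
                        params, state, duration, rng, L_max=L_max, sample_id=sid
                    )
                )
    return SpikeDataset(
        samples=samples,
        T_max=T_max,
        L_max=L_max,
        provenance={
            "generator": "pheno",
            "params": params.to_dict(),
            "seed": int(seed),
            "duration": float(duration),
            "n_groups": int(n_groups),
            "neurons_per_group": int(neurons_per_group),
        },
    )


def split_dataset(
    ds: SpikeDataset,
    train_frac: float,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[SpikeDataset, SpikeDataset]:
    """Shuffle and split into train/validation partitions.

    The train partition holds ``round(train_frac * N)`` samples; with
    ``stratified`` the per-class proportions are preserved to within one
    sample.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    n = len(ds)
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    labels = ds.labels
    if stratified:
        classes = np.unique(labels)
        if any(np.sum(labels == c) == 0 for c in classes) or classes.size < 2:
            raise ValueError("stratified split requires samples of both classes")
        take: list[np.ndarray] = []
        rest: list[np.ndarray] = []
        quota = {c: int(round(train_frac * np.sum(labels == c))) for c in classes}
        # reconcile rounding so the overall train size is exact
        drift = n_train - sum(quota.values())
        order = sorted(classes, key=lambda c: -np.sum(labels == c))
        i = 0
        while drift != 0:
            c = order[i % len(order)]
            quota[c] += 1 if drift > 0 else -1
            drift += -1 if drift > 0 else 1
            i += 1
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            take.append(idx[: quota[c]])
            rest.append(idx[quota[c] :])
        train_idx = np.concatenate(take)
        val_idx = np.concatenate(rest)
        rng.shuffle(train_idx)
        rng.shuffle(val_idx)
    else:
        perm = rng.permutation(n)
        train_idx, val_idx = perm[:n_train], perm[n_train:]

    def subset(idx: np.ndarray, part: str) -> SpikeDataset:
        prov = dict(ds.provenance)
        prov.update({"split": part, "train_frac": train_frac, "split_seed": seed})
        return SpikeDataset(
            samples=[ds.samples[i] for i in idx],
            T_max=ds.T_max,
            L_max=ds.L_max,
            provenance=prov,
        )

    return subset(train_idx, "train"), subset(val_idx, "val")


# ---------------------------------------------------------------------------
# serialization: CSV table + JSON sidecar manifest

def _manifest_path(path: Path) -> Path:
    return path.with_suffix(".manifest.json")


def write_dataset(ds: SpikeDataset, path: str | Path) -> Path:
    """Write the dataset as CSV plus a JSON manifest; returns the CSV path."""
    path = Path(path)
    ds.validate(require_sorted=False)
    cols = [f"t_{i + 1:03d}" for i in range(ds.L_max)]
    mat = np.round(ds.times_matrix(), 3)
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "n_spikes", [s.n_spikes for s in ds.samples])
    df.insert(0, "source", [s.source for s in ds.samples])
    df.insert(0, "label", [s.label for s in ds.samples])
    df.insert(0, "sample_id", [s.sample_id for s in ds.samples])
    df.to_csv(path, index=False, float_format="%.3f")
    h, p = ds.class_counts
    manifest = {
        "T_max": ds.T_max,
        "L_max": ds.L_max,
        "class_counts": {"healthy": h, "pd": p},
        "provenance": ds.provenance,
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(path: str | Path) -> SpikeDataset:
    """Read a dataset written by :func:`write_dataset`, enforcing invariants.

    Sorted spike-time prefixes are required for sources ``pheno``/``circuit``;
    files (e.g. noise-perturbed exports re-read from disk) may carry unsorted
    prefixes, which are accepted with a warning.
    """
    path = Path(path)
    mpath = _manifest_path(path)
    if not mpath.exists():
        raise DatasetFormatError(f"missing manifest {mpath}")
    manifest = json.loads(mpath.read_text())
    t_max = float(manifest["T_max"])
    l_max = int(manifest["L_max"])
    df = pd.read_csv(path)
    expected = ["sample_id", "label", "source", "n_spikes"] + [
        f"t_{i + 1:03d}" for i in range(l_max)
    ]
    if list(df.columns) != expected:
        raise DatasetFormatError(
            f"{path}: bad header, first mismatch at column "
            f"{next(i for i, (a, b) in enumerate(zip(df.columns, expected)) if a != b)}"
        )
    samples = []
    for row_i, row in enumerate(df.itertuples(index=False)):
        v = np.array(row[4:], dtype=float)
        try:
            _validate_sample_times(v, t_max, require_sorted=False, ident=str(row[0]))
        except ValueError as exc:
            nz = np.flatnonzero((v <= 0) | (v > t_max))
            col = f"t_{nz[0] + 1:03d}" if nz.size else "?"
            raise DatasetFormatError(
                f"{path}: row {row_i + 2}, column {col}: {exc}"
            ) from exc
        if int(row[3]) != int(np.count_nonzero(v)):
            raise DatasetFormatError(
                f"{path}: row {row_i + 2}, column n_spikes: "
                f"declared {row[3]} but found {np.count_nonzero(v)}"
            )
        samples.append(
            SpikeTrainSample(
                spike_times=v,
                label=int(row[1]),
                sample_id=str(row[0]),
                source=str(row[2]),
            )
        )
    counts = manifest.get("class_counts", {})
    ds = SpikeDataset(
        samples=samples,
        T_max=t_max,
        L_max=l_max,
        provenance=manifest.get("provenance", {}),
    )
    h, p = ds.class_counts
    if counts and (counts.get("healthy") != h or counts.get("pd") != p):
        raise DatasetFormatError(
            f"{path}: manifest class_counts {counts} do not match file ({h}, {p})"
        )
    return ds
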