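"""Simplified cortical-basal-ganglia-thalamus spiking network.

Eight interconnected populations — regular cortex (RC), inhibitory cortex
(IC), direct/indirect-pathway striatum (dSTR/iSTR), subthalamic nucleus
(STN), globus pallidus externa/interna (GPe/GPi) and thalamus (TH) — of
Izhikevich single-compartment neurons with current-based exponential
synapses.  The connectivity follows the classical direct/indirect/
hyperdirect-pathway wiring: cortex and striatum connect stochastically,
the pallidal and thalamic projections are structured.

The parkinsonian state is controlled by a dopamine scalar (healthy = 1,
pd = 0.2 by default): falling dopamine strengthens the striatal
(iSTR -> GPe) inhibitory efficacy and the cortico-subthalamic gain, which
pushes the reciprocally coupled STN-GPe loop into a beta-band (13-30 Hz)
oscillation and raises STN firing rates — the two biomarkers the detector
is trained on.  The neuron model is a deliberately reduced stand-in for
conductance-based biophysics; the simulator is validated on those biomarker
properties, not on membrane-potential trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spikegen import (
    HEALTHY,
    L_MAX_DEFAULT,
    PD,
    SpikeDataset,
    SpikeTrainSample,
)

__all__ = [
    "REGIONS",
    "CircuitConfig",
    "ConnectivityRealization",
    "build_network",
    "simulate",
    "extract_stn_dataset",
    "generate_circuit_dataset",
    "SimulationError",
]

REGIONS = ("RC", "IC", "dSTR", "iSTR", "STN", "GPe", "GPi", "TH")

# Izhikevich (a, b, c, d) presets and tonic drive per region.  RC/striatum
# are regular-spiking, IC and the pallidal nuclei fast-spiking, STN and TH
# rebound-capable low-threshold types.
_NEURON_PRESETS = {
    "RC": (0.02, 0.2, -65.0, 8.0),
    "IC": (0.10, 0.2, -65.0, 2.0),
    "dSTR": (0.02, 0.2, -65.0, 8.0),
    "iSTR": (0.02, 0.2, -65.0, 8.0),
    "STN": (0.005, 0.265, -65.0, 2.0),
    "GPe": (0.10, 0.2, -65.0, 2.0),
    "GPi": (0.10, 0.2, -65.0, 2.0),
    "TH": (0.02, 0.25, -65.0, 0.05),
}

_BASELINE_DRIVE = {
    "RC": 4.0, "IC": 2.0, "dSTR": 2.5, "iSTR": 2.5,
    "STN": 3.0, "GPe": 4.0, "GPi": 4.0, "TH": 1.5,
}

# dopamine-sensitive projection gains: each rule's weight is multiplied by
# 1 + k * (1 - dopamine).  Depletion strengthens striatal inhibitory
# efficacy, the cortico-subthalamic (hyperdirect) drive, and the reciprocal
# STN-GPe loop whose resonance produces the beta rhythm.
_PD_GAIN = {
    "iSTR->GPe": 3.0,
    "RC->STN": 4.0,
    "GPe->STN": 1.0,
    "STN->GPe": 2.0,
}

# synaptic base weights per projection rule (current units)
_BASE_WEIGHTS = {
    "TH->RC": 1.5, "IC->RC": 1.0, "RC->IC": 1.5,
    "RC->dSTR": 1.2, "dSTR->dSTR": 0.6,
    "RC->iSTR": 1.2, "iSTR->iSTR": 0.6,
    "GPe->STN": 1.6, "RC->STN": 1.2,
    "GPe->GPe": 0.6, "iSTR->GPe": 0.35,
    "dSTR->GPi": 0.35, "GPe->GPi": 0.8,
    "STN->GPe": 1.2, "STN->GPi": 1.2,
    "GPi->TH": 1.0,
}


class SimulationError(RuntimeError):
    """Numerical blow-up during integration (names time and neuron)."""


@dataclass(frozen=True)
class CircuitConfig:
    region_size: int = 10
    state: str = "healthy"  # healthy | pd
    dopamine: float | None = None  # defaults: healthy 1.0, pd 0.2
    dt: float = 0.1          # ms
    duration: float = 2500.0  # ms
    seed: int = 0
    stochastic_in_degree: int = 3
    stn_feedback_fraction: float = 0.5  # share of GPe/GPi with STN input
    synaptic_delay: float = 3.0   # ms
    tau_exc: float = 5.0     # ms
    tau_inh: float = 12.0    # ms
    noise_sigma: float = 1.5  # membrane current noise

    def __post_init__(self) -> None:
        if self.region_size < 2:
            raise ValueError("region_size must be >= 2 (GPe needs two peers)")
        if self.state not in ("healthy", "pd"):
            raise ValueError("state must be 'healthy' or 'pd'")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dopamine is not None and not 0.0 <= self.dopamine <= 1.0:
            raise ValueError("dopamine must lie in [0, 1]")

    @property
    def dopamine_level(self) -> float:
        if self.dopamine is not None:
            return self.dopamine
        return 1.0 if self.state == "healthy" else 0.2


@dataclass
class ConnectivityRealization:
    """Signed, weighted directed edge list with per-edge rule provenance."""

    region_size: int
    edges: list[tuple[int, int, int, float, str]] = field(default_factory=list)
    # (src, dst, sign(+1/-1), weight, rule)

    def offset(self, region: str) -> int:
        return REGIONS.index(region) * self.region_size

    def neurons(self, region: str) -> range:
        o = self.offset(region)
        return range(o, o + self.region_size)

    def in_edges(self, dst: int):
        return [e for e in self.edges if e[1] == dst]

    def weight_matrix(self) -> np.ndarray:
        n = self.region_size * len(REGIONS)
        W = np.zeros((n, n))
        for src, dst, sign, w, _rule in self.edges:
            W[src, dst] += sign * w
        return W


def build_network(cfg: CircuitConfig,
                  rng: np.random.Generator | None = None) -> ConnectivityRealization:
    """Realize the connectivity rules for one network instance.

    Stochastic projections (cortex/striatum and the structured ">= 1 source"
    rules) use a fixed in-degree, drawn without replacement and excluding
    self-edges; all random choices come from ``rng``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    net = ConnectivityRealization(region_size=cfg.region_size)
    N = cfg.region_size
    k = min(cfg.stochastic_in_degree, N)
    lam = cfg.dopamine_level
    gain = {rule: 1.0 + k * (1.0 - lam) for rule, k in _PD_GAIN.items()}

    def offs(region: str) -> int:
        return REGIONS.index(region) * N

    def connect(rule: str, dst_local: int, sources: np.ndarray, sign: int) -> None:
        src_region, dst_region = rule.split("->")
        w = _BASE_WEIGHTS[rule] * gain.get(rule, 1.0)
        for s in np.atleast_1d(sources):
            net.edges.append(
                (offs(src_region) + int(s), offs(dst_region) + dst_local,
                 sign, w, rule))

    def pick(n_choices: int, n_pick: int, exclude: int | None = None) -> np.ndarray:
        pool = np.arange(n_choices)
        if exclude is not None:
            pool = pool[pool != exclude]
        return rng.choice(pool, size=min(n_pick, pool.size), replace=False)

    all_idx = np.arange(N)
    for j in range(N):
        # cortex: RC <- TH (exc, random), RC <- IC (inh, random)
        connect("TH->RC", j, pick(N, k), +1)
        connect("IC->RC", j, pick(N, k), -1)
        # IC <- RC (exc, random)
        connect("RC->IC", j, pick(N, k), +1)
        # striatum: exc from RC, lateral inhibition within each pathway
        connect("RC->dSTR", j, pick(N, k), +1)
        connect("dSTR->dSTR", j, pick(N, k, exclude=j), -1)
        connect("RC->iSTR", j, pick(N, k), +1)
        connect("iSTR->iSTR", j, pick(N, k, exclude=j), -1)
        # STN <- GPe (inh), STN <- RC (exc)
        connect("GPe->STN", j, pick(N, k), -1)
        connect("RC->STN", j, pick(N, k), +1)
        # GPe <- exactly two other GPe (inh) and ALL iSTR (inh)
        connect("GPe->GPe", j, pick(N, 2, exclude=j), -1)
        connect("iSTR->GPe", j, all_idx, -1)
        # GPi <- ALL dSTR (inh) and >= 1 GPe (inh)
        connect("dSTR->GPi", j, all_idx, -1)
        connect("GPe->GPi", j, pick(N, k), -1)
        # TH <- GPi (inh) only
        connect("GPi->TH", j, pick(N, k), -1)
    # a configured subset of GPe and GPi receives STN excitation
    n_fb = int(round(cfg.stn_feedback_fraction * N))
    for region, rule in (("GPe", "STN->GPe"), ("GPi", "STN->GPi")):
        targets = rng.choice(N, size=n_fb, replace=False)
        for j in targets:
            connect(rule, int(j), pick(N, k), +1)
    return net


def simulate(net: ConnectivityRealization, cfg: CircuitConfig,
             rng: np.random.Generator | None = None) -> dict[str, list[np.ndarray]]:
    """Integrate the network; returns per-region lists of spike-time arrays.

    Fixed-step explicit integration (two half-steps for the membrane
    equation, the standard scheme for this neuron model) at ``cfg.dt``;
    white membrane noise scales as 1/sqrt(dt) so its integrated variance is
    step-size independent.
    """
    if net.region_size != cfg.region_size:
        raise ValueError("network and config disagree on region_size")
    rng = np.random.default_rng(cfg.seed + 7919) if rng is None else rng
    n = cfg.region_size * len(REGIONS)
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    d = np.empty(n)
    I0 = np.empty(n)
    for ri, region in enumerate(REGIONS):
        sl = slice(ri * cfg.region_size, (ri + 1) * cfg.region_size)
        a[sl], b[sl], c[sl], d[sl] = _NEURON_PRESETS[region]
        I0[sl] = _BASELINE_DRIVE[region]
    W = net.weight_matrix()
    W_exc = np.maximum(W, 0.0)
    W_inh = np.maximum(-W, 0.0)
    has_edges = np.any(W != 0.0)
    dt = cfg.dt
    steps = int(round(cfg.duration / dt))
    delay_steps = max(1, int(round(cfg.synaptic_delay / dt)))
    decay_e = np.exp(-dt / cfg.tau_exc)
    decay_i = np.exp(-dt / cfg.tau_inh)
    v = np.full(n, -65.0)
    u = b * v
    s_exc = np.zeros(n)
    s_inh = np.zeros(n)
    buf = np.zeros((delay_steps, n))
    spikes: list[list[float]] = [[] for _ in range(n)]
    noise_scale = cfg.noise_sigma / np.sqrt(dt)
    for step in range(steps):
        t = (step + 1) * dt
        arrived = buf[step % delay_steps]
        s_exc *= decay_e
        s_inh *= decay_i
        if has_edges:
            s_exc += arrived @ W_exc
            s_inh += arrived @ W_inh
        I = I0 + noise_scale * rng.standard_normal(n) + s_exc - s_inh
        # two half-steps for v improve stability of the quadratic term
        for _ in range(2):
            v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u += dt * a * (b * v - u)
        fired = v >= 30.0
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            region = REGIONS[bad // cfg.region_size]
            raise SimulationError(
                f"non-finite membrane potential at t={t:.1f} ms, neuron "
                f"{bad} ({region})")
        if np.any(fired):
            for i in np.flatnonzero(fired):
                spikes[i].append(t)
            v[fired] = c[fired]
            u[fired] += d[fired]
        buf[step % delay_steps] = fired.astype(float)
    out: dict[str, list[np.ndarray]] = {}
    for ri, region in enumerate(REGIONS):
        sl = range(ri * cfg.region_size, (ri + 1) * cfg.region_size)
        out[region] = [np.array(spikes[i]) for i in sl]
    return out


def mean_rate(trains: list[np.ndarray], duration: float) -> float:
    """Mean firing rate (Hz) over a list of spike-time arrays (ms)."""
    return float(np.mean([t.size for t in trains]) / (duration / 1000.0))


def extract_stn_dataset(runs: list[dict[str, list[np.ndarray]]],
                        labels: list[int],
                        duration: float,
                        *,
                        T_max: float | None = None,
                        L_max: int = L_MAX_DEFAULT,
                        provenance: dict | None = None) -> SpikeDataset:
    """One sample per STN neuron per run, labeled by the run's state."""
    if len(runs) != len(labels):
        raise ValueError("one label per run required")
    T_max = float(duration if T_max is None else T_max)
    names = {HEALTHY: "healthy", PD: "pd"}
    samples = []
    for ri, (run, label) in enumerate(zip(runs, labels)):
        for ni, t in enumerate(run["STN"]):
            if t.size and t[-1] > duration:
                raise ValueError(
                    f"run {ri}: spikes beyond the stated duration {duration}")
            if t.size > L_max:
                from .spikegen import SpikeOverflowError

                raise SpikeOverflowError(
                    f"run {ri}, STN neuron {ni}: {t.size} spikes exceed "
                    f"L_max={L_max}")
            vec = np.zeros(L_max)
            vec[: t.size] = np.round(t, 3)
            samples.append(SpikeTrainSample(
                spike_times=vec, label=label,
                sample_id=f"{names[label]}-r{ri:04d}-stn{ni:02d}",
                source="circuit"))
    return SpikeDataset(samples=samples, T_max=T_max, L_max=L_max,
                        provenance=provenance or {"generator": "circuit"})


def generate_circuit_dataset(n_runs_per_state: int,
                             cfg: CircuitConfig | None = None,
                             seed: int = 0) -> SpikeDataset:
    """Convenience wrapper: simulate both states and collect STN samples."""
    base = cfg or CircuitConfig()
    runs, labels = [], []
    for state, label in (("healthy", HEALTHY), ("pd", PD)):
        for r in range(n_runs_per_state):
            run_cfg = CircuitConfig(
                region_size=base.region_size, state=state,
                dopamine=base.dopamine, dt=base.dt, duration=base.duration,
                seed=seed + 104729 * label + r,
                stochastic_in_degree=base.stochastic_in_degree,
                stn_feedback_fraction=base.stn_feedback_fraction,
                synaptic_delay=base.synaptic_delay, tau_exc=base.tau_exc,
                tau_inh=base.tau_inh, noise_sigma=base.noise_sigma)
            net = build_network(run_cfg)
            runs.append(simulate(net, run_cfg))
            labels.append(label)
    return extract_stn_dataset(
        runs, labels, duration=base.duration,
        provenance={"generator": "circuit", "seed": seed,
                    "n_runs_per_state": n_runs_per_state,
                    "region_size": base.region_size,
                    "duration": base.duration})
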