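"""Clock-driven simulation of the noisy leaky integrate-and-fire network.

Each neuron's membrane potential is a superposition of double-exponential
postsynaptic kernels ``eps(t) = exp(-t/tau_m) - exp(-t/tau_s)`` driven by
recurrent spikes (weights J_ij) and by Poisson noise events with Gaussian
amplitudes.  Crossing the threshold emits a spike and resets the neuron
to zero, discarding all input received before the spike.  The integrator
uses exact exponential propagators on the equivalent two-variable system

    dv/dt = -v/tau_m + (1/tau_s - 1/tau_m) s,      ds/dt = -s/tau_s,

so membrane trajectories between events are exact at step boundaries, not
Euler approximations.  An optional short-term synaptic depression variant
multiplies a presynaptic neuron's outgoing weights by ``f_stsd`` at each
of its spikes, with exponential recovery toward the learned weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
from numba import njit

from .learning import WeightMatrix

logger = logging.getLogger(__name__)

#: conventions for mapping the noise level alpha (ms^-1) to the per-neuron
#: Gaussian amplitude scale sigma_i; both combine alpha, the event rate rho
#: and the row energy sum_j J_ij^2 (see NoiseModel).
NOISE_CONVENTIONS = ("sqrt-alpha-rho", "alpha-sqrt-rho")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (times in ms, rates in ms^-1, J in threshold units)."""

    alpha: float = 0.06
    t_total: float = 300_000.0
    t_transient: float = 60_000.0
    tau_m: float = 10.0
    tau_s: float = 5.0
    theta: float = 1.0
    rho: float = 1.0
    dt: float = 0.1
    seed: int = 0
    max_spikes: int = 10_000_000
    noise_convention: str = "sqrt-alpha-rho"
    noise_gain: float = 1.4
    spike_capacity: int | None = None

    def __post_init__(self) -> None:
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("need tau_m > tau_s > 0")
        if self.dt > self.tau_s / 10.0:
            raise ValueError("dt must be at most tau_s/10 for faithful stepping")
        if not self.t_total > self.t_transient >= 0:
            raise ValueError("need t_total > t_transient >= 0")
        if self.alpha < 0 or self.rho < 0:
            raise ValueError("alpha and rho must be non-negative")
        if self.noise_convention not in NOISE_CONVENTIONS:
            raise ValueError(f"noise_convention must be one of {NOISE_CONVENTIONS}")
        if self.noise_gain <= 0:
            raise ValueError("noise_gain must be positive")


@dataclass(frozen=True)
class STSDConfig:
    """Short-term synaptic depression: multiplicative weakening per
    presynaptic spike, recovering toward the learned weight."""

    enabled: bool = False
    tau_r: float = 10.0
    f_stsd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.f_stsd <= 1.0:
            raise ValueError("f_stsd must be in (0, 1]")
        if not self.tau_r > 0:
            raise ValueError("tau_r must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Per-neuron noise amplitude scale derived from the weight matrix.

    Noise events arrive as a Poisson process of rate ``rho`` per neuron;
    each event adds a zero-mean Gaussian impulse of standard deviation
    ``sigma_i`` to the neuron's synaptic trace.  ``sigma_i`` couples the
    noise level ``alpha`` to the neuron's incoming synaptic energy
    ``E_i = sum_j J_ij^2`` so that strongly connected neurons (leaders)
    feel proportionally stronger noise.  Two conventions are supported:

    - ``"sqrt-alpha-rho"`` (default): ``sigma_i = sqrt(g (alpha/rho) E_i)``;
    - ``"alpha-sqrt-rho"``: ``sigma_i = alpha sqrt(g rho E_i)``.

    With ``rho = 1 ms^-1`` and gain ``g = 1`` these read
    ``sqrt(alpha E_i)`` and ``alpha sqrt(E_i)``.  ``g`` is a single
    dimensionless gain calibrated once against the phase-diagram
    landmarks (quiescent regime at low strength/noise, sustained replay
    at high strength/noise, ignition near the transition); see the
    methods note.
    """

    rho: float
    sigma: np.ndarray

    @classmethod
    def from_row_energy(cls, config: SimConfig, row_energy: np.ndarray) -> "NoiseModel":
        row_energy = np.asarray(row_energy, dtype=float)
        if np.any(row_energy < 0):
            raise ValueError("row energy must be non-negative")
        if config.noise_convention == "alpha-sqrt-rho":
            sigma = config.alpha * np.sqrt(config.noise_gain * config.rho * row_energy)
        else:
            if config.rho > 0:
                sigma = np.sqrt(config.noise_gain * config.alpha / config.rho * row_energy)
            else:
                sigma = np.zeros_like(row_energy)
        return cls(rho=config.rho, sigma=sigma)


def epsilon_kernel(t, tau_m: float = 10.0, tau_s: float = 5.0):
    """Normalized postsynaptic potential kernel ``exp(-t/tau_m) - exp(-t/tau_s)``.

    Zero at ``t = 0``, single interior maximum at
    ``t* = tau_m tau_s / (tau_m - tau_s) * ln(tau_m/tau_s)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("epsilon kernel is causal; t must be >= 0")
    out = np.exp(-t / tau_m) - np.exp(-t / tau_s)
    if out.ndim == 0:
        return float(out)
    return out


def draw_noise(
    config: SimConfig,
    row_energy: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    n_steps: int = 1,
) -> np.ndarray:
    """Per-step summed noise impulses, shape ``(n_steps, n_neurons)``.

    Each neuron receives ``Poisson(rho dt)`` events per step, each with an
    i.i.d. Gaussian amplitude of standard deviation ``sigma_i``; events
    within a step are applied together at the step boundary, so only their
    sum matters and it is drawn exactly as ``sigma_i sqrt(k) z``.
    """
    model = NoiseModel.from_row_energy(config, row_energy)
    n = model.sigma.size
    counts = rng.poisson(config.rho * dt, size=(n_steps, n))
    z = rng.standard_normal(size=(n_steps, n))
    return model.sigma[None, :] * np.sqrt(counts) * z


def depress_and_recover(
    j_dyn: np.ndarray,
    j0: np.ndarray,
    spikes: list[tuple[int, int]],
    dt: float,
    stsd: STSDConfig,
    n_steps: int,
) -> np.ndarray:
    """Reference dynamics of the depressed weight matrix over ``n_steps``.

    Per step the matrix relaxes toward the resting weights,
    ``J <- J0 + (J - J0) exp(-dt/tau_r)``; a spike of presynaptic neuron
    ``j`` at step ``k`` (given as ``(k, j)`` pairs) scales column ``j`` by
    ``f_stsd`` at the end of that step.  This mirrors, matrix-wide, the
    per-column factor the simulator tracks implicitly.
    """
    if not stsd.enabled:
        raise ValueError("short-term depression is not enabled")
    j_dyn = np.array(j_dyn, dtype=float)
    j0 = np.asarray(j0, dtype=float)
    decay = np.exp(-dt / stsd.tau_r)
    by_step: dict[int, list[int]] = {}
    for k, j in spikes:
        by_step.setdefault(int(k), []).append(int(j))
    for k in range(n_steps):
        j_dyn = j0 + (j_dyn - j0) * decay
        for j in by_step.get(k, ()):
            j_dyn[:, j] *= stsd.f_stsd
    return j_dyn


@dataclass
class SpikeRaster:
    """Timestamped spikes of one run: parallel ``times`` (ms) / ``ids`` arrays."""

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    t_total: float
    t_transient: float = 0.0
    meta: dict = field(default_factory=dict)
    v_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must be parallel arrays")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def window(self, t_start: float, t_stop: float | None = None) -> "SpikeRaster":
        """Sub-raster with spikes in ``[t_start, t_stop)`` (times unshifted)."""
        if t_stop is None:
            t_stop = self.t_total
        keep = (self.times >= t_start) & (self.times < t_stop)
        return SpikeRaster(
            self.times[keep],
            self.ids[keep],
            self.n_neurons,
            self.t_total,
            self.t_transient,
            dict(self.meta),
        )

    def analyzed(self) -> "SpikeRaster":
        """The post-transient portion of the raster."""
        return self.window(self.t_transient)

    def mean_rate(self, t_start: float | None = None, t_stop: float | None = None) -> float:
        """Mean rate in Hz per neuron over the given window (default: post-transient)."""
        if t_start is None:
            t_start = self.t_transient
        if t_stop is None:
            t_stop = self.t_total
        duration_s = (t_stop - t_start) * 1e-3
        if duration_s <= 0:
            raise ValueError("empty analysis window")
        n_spk = np.count_nonzero((self.times >= t_start) & (self.times < t_stop))
        return n_spk / (self.n_neurons * duration_s)


@njit(cache=True)
def _lif_core(
    indptr,
    indices,
    data,
    sigma,
    n,
    dt,
    n_steps,
    dm,
    ds,
    g,
    theta,
    rho,
    stsd_on,
    er,
    f_stsd,
    transient_step,
    max_analyzed,
    seed,
    spike_times,
    spike_ids,
    ext_step,
    ext_id,
    ext_amp,
    record_v,
    v_out,
):  # pragma: no cover - exercised via simulate()
    np.random.seed(seed)
    v = np.zeros(n)
    s = np.zeros(n)
    x = np.ones(n)
    prev = np.empty(n, dtype=np.int64)
    cur = np.empty(n, dtype=np.int64)
    n_prev = 0
    n_spk = 0
    n_analyzed = 0
    cap = spike_times.shape[0]
    n_ext = ext_step.shape[0]
    ptr = 0
    lam = n * rho * dt
    end_step = n_steps
    for step in range(n_steps):
        # recurrent input from spikes of the previous step
        for m in range(n_prev):
            j = prev[m]
            w = x[j] if stsd_on else 1.0
            for q in range(indptr[j], indptr[j + 1]):
                s[indices[q]] += data[q] * w
        # externally scheduled impulses
        while ptr < n_ext and ext_step[ptr] == step:
            s[ext_id[ptr]] += ext_amp[ptr]
            ptr += 1
        # noise events: total count over the network, then uniform assignment
        if lam > 0.0:
            k_tot = np.random.poisson(lam)
            for _ in range(k_tot):
                i = np.random.randint(0, n)
                if sigma[i] > 0.0:
                    s[i] += sigma[i] * np.random.standard_normal()
        # exact propagation over one step
        for i in range(n):
            v[i] = dm * v[i] + g * s[i]
            s[i] *= ds
        if stsd_on:
            for i in range(n):
                x[i] = 1.0 + (x[i] - 1.0) * er
        if record_v:
            for i in range(n):
                v_out[step + 1, i] = v[i]
        # threshold crossings; resets discard all prior input
        n_cur = 0
        t_now = (step + 1) * dt
        for i in range(n):
            if v[i] >= theta:
                if n_spk < cap:
                    spike_times[n_spk] = t_now
                    spike_ids[n_spk] = i
                    n_spk += 1
                if step >= transient_step:
                    n_analyzed += 1
                v[i] = 0.0
                s[i] = 0.0
                if stsd_on:
                    x[i] *= f_stsd
                cur[n_cur] = i
                n_cur += 1
        prev, cur = cur, prev
        n_prev = n_cur
        if n_analyzed >= max_analyzed or n_spk >= cap:
            end_step = step + 1
            break
    ok = True
    for i in range(n):
        if not np.isfinite(v[i]):
            ok = False
    return n_spk, end_step, ok


def simulate(
    w: WeightMatrix | np.ndarray,
    config: SimConfig,
    stsd: STSDConfig | None = None,
    external_events: np.ndarray | None = None,
    record_v: bool = False,
) -> SpikeRaster:
    """Run the network and return its spike raster.

    ``external_events`` is an optional ``(k, 3)`` array of
    ``(time_ms, neuron_id, amplitude)`` impulses injected into the
    synaptic trace, used for controlled single-neuron protocols.  With
    ``record_v`` the per-step membrane potentials are kept on the raster
    (``v_trace[k, i]`` is ``V_i`` at time ``k dt``) — only sensible for
    small, short runs.

    The run stops at ``t_total`` or once ``max_spikes`` post-transient
    spikes have been emitted, whichever comes first.
    """
    if stsd is None:
        stsd = STSDConfig()
    values = w.values if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)
    n = values.shape[0]
    csc = scipy.sparse.csc_matrix(values)
    row_energy = np.einsum("ij,ij->i", values, values)
    model = NoiseModel.from_row_energy(config, row_energy)

    n_steps = int(round(config.t_total / config.dt))
    transient_step = int(round(config.t_transient / config.dt))
    dm = float(np.exp(-config.dt / config.tau_m))
    ds = float(np.exp(-config.dt / config.tau_s))
    g = dm - ds

    if external_events is None or len(external_events) == 0:
        ext = np.zeros((0, 3), dtype=float)
    else:
        ext = np.asarray(external_events, dtype=float)
        ext = ext[np.argsort(ext[:, 0], kind="stable")]
    ext_step = np.floor(ext[:, 0] / config.dt + 0.5).astype(np.int64)
    ext_id = ext[:, 1].astype(np.int64)
    ext_amp = np.ascontiguousarray(ext[:, 2])

    cap = config.spike_capacity
    if cap is None:
        # headroom for a sustained 20 Hz per neuron, well above any regime
        # of this model; a capped run is flagged in the raster metadata
        cap = int(min(config.max_spikes * 1.5, n * config.t_total * 0.02) + 10_000)
    spike_times = np.empty(cap, dtype=np.float64)
    spike_ids = np.empty(cap, dtype=np.int64)
    v_out = np.zeros((n_steps + 1 if record_v else 1, n), dtype=np.float64)

    n_spk, end_step, ok = _lif_core(
        csc.indptr.astype(np.int64),
        csc.indices.astype(np.int64),
        csc.data.astype(np.float64),
        model.sigma,
        n,
        float(config.dt),
        n_steps,
        dm,
        ds,
        g,
        float(config.theta),
        float(config.rho),
        stsd.enabled,
        float(np.exp(-config.dt / stsd.tau_r)),
        float(stsd.f_stsd),
        transient_step,
        int(config.max_spikes),
        int(config.seed) % (2**31 - 1),
        spike_times,
        spike_ids,
        ext_step,
        ext_id,
        ext_amp,
        record_v,
        v_out,
    )
    if not ok:
        raise RuntimeError("membrane potential diverged (non-finite state)")
    t_end = end_step * config.dt
    raster = SpikeRaster(
        spike_times[:n_spk].copy(),
        spike_ids[:n_spk].copy(),
        n,
        t_end,
        min(config.t_transient, t_end),
        meta={
            "seed": config.seed,
            "alpha": config.alpha,
            "dt": config.dt,
            "noise_convention": config.noise_convention,
            "stsd": stsd.enabled,
            "truncated": bool(n_spk >= cap),
        },
    )
    if record_v:
        raster.v_trace = v_out[: end_step + 1]
    if n_spk >= cap:
        logger.warning("spike capacity %d reached at t=%.1f ms", cap, t_end)
    return raster
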