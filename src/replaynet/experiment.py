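"""Reproducible experiment orchestration: learn -> simulate -> analyze -> sweep.

An :class:`ExperimentConfig` bundles the learning, simulation, depression
and analysis parameters and round-trips losslessly through YAML (unknown
keys are rejected).  ``run_experiment`` executes the full pipeline for
one parameter point, ``sweep_phase_diagram`` scans a grid of connection
strengths and noise levels (restartable: completed cells are skipped),
and ``make_fixture`` builds the small deterministic planted fixtures the
test suite uses so that no unit test needs a full network simulation.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .analysis import (
    Avalanche,
    RateSeries,
    bin_rates,
    classify_regime,
    detect_avalanches,
    fit_exponential,
    fit_power_law,
    segment_up_down,
    waiting_times,
)
from .learning import (
    LearningConfig,
    PhaseCodedPattern,
    STDPKernelParams,
    WeightMatrix,
    learn_weights,
    make_patterns,
    prune,
)
from .simulate import SimConfig, SpikeRaster, STSDConfig, simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the statistics stack (times in ms, rates in Hz)."""

    bin_ms: float = 1.0
    r_min_hz: float = 7.0
    t_max_ms: float = 50.0
    size_x_min: float = 10.0
    duration_x_min: float = 2.0
    wt_fit_min_ms: float = 10.0
    wt_fit_max_ms: float = 50.0
    min_bins_classify: int = 10_000


@dataclass(frozen=True)
class SweepConfig:
    """Grid of (H0/Theta, alpha) points and realizations per point."""

    h0_values: tuple = ()
    alpha_values: tuple = ()
    realizations: int = 1


@dataclass(frozen=True)
class ExperimentConfig:
    learning: LearningConfig = field(default_factory=LearningConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    stsd: STSDConfig = field(default_factory=STSDConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    seed: int = 0

    # -- config round-trips ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sections = {
            "learning": LearningConfig,
            "sim": SimConfig,
            "stsd": STSDConfig,
            "analysis": AnalysisConfig,
            "sweep": SweepConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            if name in d:
                kwargs[name] = _dataclass_from_dict(typ, d.pop(name))
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _dataclass_from_dict(typ, d: dict):
    if not isinstance(d, dict):
        raise ValueError(f"config section for {typ.__name__} must be a mapping")
    d = dict(d)
    kwargs = {}
    for f in fields(typ):
        if f.name in d:
            v = d.pop(f.name)
            if f.name == "kernel" and isinstance(v, dict):
                v = _dataclass_from_dict(STDPKernelParams, v)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    if d:
        raise ValueError(f"unknown keys in {typ.__name__} section: {sorted(d)}")
    return typ(**kwargs)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# single experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    weights: WeightMatrix
    patterns: list[PhaseCodedPattern]
    raster: SpikeRaster
    rates: RateSeries
    stats: dict


def run_experiment(
    config: ExperimentConfig,
    out_dir=None,
    keep_raster: bool = True,
) -> ExperimentResult:
    """Execute learn -> prune -> simulate -> analyze for one parameter point.

    All potentials start at zero; the transient is discarded before any
    statistic is computed; the run stops at ``sim.t_total`` or at
    ``sim.max_spikes`` analyzed spikes, whichever comes first.  The
    pattern phases and the simulation noise derive from independent
    streams spawned from ``config.seed``, so results are deterministic.
    """
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    s_pat, s_sim = ss.spawn(2)
    lc = config.learning
    patterns = make_patterns(lc.n, lc.p, lc.period, s_pat)
    w = prune(learn_weights(patterns, lc), lc.f_plus_prune)
    t_learn = time.perf_counter() - t0
    logger.info("learning done in %.1f s (N=%d, P=%d)", t_learn, lc.n, lc.p)

    sim_cfg = replace(config.sim, seed=int(s_sim.generate_state(1)[0] % (2**31 - 1)))
    raster = simulate(w, sim_cfg, config.stsd)
    t_sim = time.perf_counter() - t0 - t_learn
    logger.info("simulation done in %.1f s (%d spikes)", t_sim, raster.n_spikes)

    stats = analyze_raster(raster, config.analysis)
    stats["pruning"] = {
        "positive_fraction": w.survivor_fractions()[0],
        "negative_fraction": w.survivor_fractions()[1],
    }

    result = ExperimentResult(config, w, patterns, raster, stats.pop("_rates"), stats)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        rio.save_weights(w, out / "weights.h5")
        if keep_raster:
            rio.save_raster(raster, out / "raster.h5")
        rio.avalanches_frame(result.stats["_avalanches"]).to_csv(
            out / "avalanches.csv", index=False
        )
        pd.DataFrame({"waiting_time_ms": result.stats["_waiting_times"]}).to_csv(
            out / "waiting_times.csv", index=False
        )
        rio.segments_frame(result.stats["_segments"]).to_csv(
            out / "segments.csv", index=False
        )
        rio.write_json(
            {k: v for k, v in result.stats.items() if not k.startswith("_")},
            out / "stats.json",
        )
    return result


def analyze_raster(raster: SpikeRaster, acfg: AnalysisConfig) -> dict:
    """The full statistics stack on the post-transient part of a raster."""
    rates = bin_rates(raster, acfg.bin_ms)
    avalanches = detect_avalanches(rates, acfg.r_min_hz)
    stats: dict = {
        "_rates": rates,
        "_avalanches": avalanches,
        "mean_rate_hz": raster.mean_rate(),
        "n_spikes_analyzed": int(rates.counts.sum()),
        "n_avalanches": len(avalanches),
    }

    try:
        regime = classify_regime(rates, min_bins=acfg.min_bins_classify)
        stats["regime"] = {
            "label": regime.label,
            "modes_hz": list(regime.modes_hz),
            "valley_depth": regime.valley_depth,
        }
    except ValueError as e:
        stats["regime"] = {"label": None, "reason": str(e)}

    # sizes are spike counts and durations/waiting times multiples of the
    # 1-ms bin: integer-valued data, fitted with the discrete estimator
    discrete = float(acfg.bin_ms).is_integer()
    sizes = np.array([a.size for a in avalanches], dtype=float)
    durations = np.array([a.duration_ms for a in avalanches], dtype=float)
    stats["size_fit"] = _try_power_law(sizes, acfg.size_x_min, None, discrete=True)
    stats["duration_fit"] = _try_power_law(
        durations, acfg.duration_x_min, None, discrete=discrete
    )

    if len(avalanches) >= 2:
        dts = waiting_times(avalanches)
        stats["_waiting_times"] = dts
        stats["wt_fit_linear"] = _try_power_law(
            dts, acfg.wt_fit_min_ms, acfg.wt_fit_max_ms, discrete=discrete
        )
        if stats["wt_fit_linear"]["exponent"] is not None:
            wt = dict(stats["wt_fit_linear"])
            # per-log-interval density P~(dt) = P(dt) dt: exponent shifts by 1
            for key in ("exponent", "exponent_lsq"):
                if wt.get(key) is not None:
                    wt[key] = wt[key] - 1.0
            stats["wt_fit_log_measure"] = wt
    else:
        stats["_waiting_times"] = np.empty(0)

    segments = segment_up_down(
        avalanches, acfg.t_max_ms, t_start=rates.t_start, t_stop=rates.t_stop
    )
    stats["_segments"] = segments
    down = np.array([s.duration_ms for s in segments if s.kind == "down"])
    up = np.array([s.duration_ms for s in segments if s.kind == "up"])
    stats["n_up_states"] = int(up.size)
    stats["n_down_states"] = int(down.size)
    stats["up_time_fraction"] = (
        float(up.sum() / (up.sum() + down.sum())) if up.size + down.size else None
    )
    try:
        ef = fit_exponential(down)
        stats["down_duration_fit"] = {
            "rate_per_ms": ef.rate_per_ms,
            "mean_ms": ef.mean_ms,
            "ks_statistic": ef.ks_statistic,
            "ks_pvalue": ef.ks_pvalue,
            "n": ef.n_samples,
        }
    except ValueError as e:
        stats["down_duration_fit"] = {"rate_per_ms": None, "reason": str(e)}
    return stats


def _try_power_law(
    samples: np.ndarray, x_min: float, x_max: float | None, discrete: bool = False
) -> dict:
    if x_max is None:
        x_max = float(samples.max()) if samples.size else 0.0
    out: dict = {"x_min": x_min, "x_max": x_max}
    try:
        mle = fit_power_law(samples, x_min, x_max, method="mle", discrete=discrete)
        lsq = fit_power_law(samples, x_min, x_max, method="lsq", discrete=discrete)
        out.update(
            exponent=mle.exponent,
            exponent_lsq=lsq.exponent,
            n=mle.n_samples,
            ks_distance=mle.ks_distance,
        )
    except ValueError as e:
        out.update(exponent=None, exponent_lsq=None, reason=str(e))
    return out


# ---------------------------------------------------------------------------
# phase-diagram sweep
# ---------------------------------------------------------------------------


@dataclass
class PhaseDiagramResult:
    """Per-cell mean rates and regime labels over the (H0, alpha) grid."""

    frame: pd.DataFrame

    def aggregated(self) -> pd.DataFrame:
        """Mean rate over realizations and the most frequent label per cell."""
        def _mode(s):
            m = s.mode()
            return m.iloc[0] if len(m) else None

        return (
            self.frame.groupby(["h0", "alpha"])
            .agg(mean_rate_hz=("mean_rate_hz", "mean"), label=("label", _mode))
            .reset_index()
        )


def sweep_phase_diagram(config: ExperimentConfig, out_dir=None) -> PhaseDiagramResult:
    """Run the pipeline over the configured (H0/Theta, alpha) grid.

    One cell per grid point per realization.  With ``out_dir`` the sweep
    is restartable: cells whose ``stats.json`` already exists are loaded
    instead of re-run, and the aggregate table is written as CSV + JSON.
    """
    sw = config.sweep
    if not sw.h0_values or not sw.alpha_values:
        raise ValueError("sweep grid is empty")
    rows = []
    for h0 in sw.h0_values:
        for alpha in sw.alpha_values:
            for k in range(sw.realizations):
                cell = f"h0_{h0:g}_alpha_{alpha:g}_r{k}"
                cell_dir = None if out_dir is None else Path(out_dir) / cell
                if cell_dir is not None and (cell_dir / "stats.json").exists():
                    import json

                    stats = json.loads((cell_dir / "stats.json").read_text())
                    rows.append(
                        {
                            "h0": h0,
                            "alpha": alpha,
                            "realization": k,
                            "mean_rate_hz": stats["mean_rate_hz"],
                            "label": stats["regime"]["label"],
                        }
                    )
                    logger.info("cell %s already done; skipped", cell)
                    continue
                cell_seed = int(
                    np.random.SeedSequence(
                        [config.seed, int(round(h0 * 1e6)), int(round(alpha * 1e6)), k]
                    ).generate_state(1)[0]
                    % (2**31 - 1)
                )
                cfg = replace(
                    config,
                    learning=replace(config.learning, h0=h0),
                    sim=replace(config.sim, alpha=alpha),
                    seed=cell_seed,
                )
                res = run_experiment(cfg, out_dir=cell_dir, keep_raster=False)
                rows.append(
                    {
                        "h0": h0,
                        "alpha": alpha,
                        "realization": k,
                        "mean_rate_hz": res.stats["mean_rate_hz"],
                        "label": res.stats["regime"]["label"],
                    }
                )
    frame = pd.DataFrame(rows)
    result = PhaseDiagramResult(frame)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "phase_diagram.csv", index=False)
        rio.write_json(frame.to_dict(orient="records"), out / "phase_diagram.json")
    return result


# ---------------------------------------------------------------------------
# planted fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, params: dict | None = None, seed: int = 0, path=None) -> dict:
    """Small deterministic fixtures for testing the analysis stack.

    ``"toy-rates"``: a rate series with planted avalanches on a
    sub-threshold background — ``detect_avalanches`` must return exactly
    the planted runs.  ``"toy-raster"``: cyclic replay of a phase-coded
    pattern plus Poisson background spikes.  ``"toy-weights"``: a small
    random weight matrix with zero diagonal and mixed-sign rows.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "toy-rates":
        n_bins = int(params.pop("n_bins", 2000))
        n_neurons = int(params.pop("n_neurons", 1000))
        bin_ms = float(params.pop("bin_ms", 1.0))
        r_min = float(params.pop("r_min_hz", 7.0))
        planted = params.pop(
            "planted", [(100, 5, 20.0), (400, 12, 15.0), (900, 1, 30.0)]
        )
        _reject_unknown(kind, params)
        max_bg = int(np.floor(r_min * n_neurons * bin_ms * 1e-3))
        counts = rng.integers(0, max_bg + 1, size=n_bins)
        avalanches = []
        for start_bin, dur_bins, rate_hz in planted:
            c = int(round(rate_hz * n_neurons * bin_ms * 1e-3))
            counts[start_bin : start_bin + dur_bins] = c
            # planted avalanches must be isolated from the background runs
            counts[start_bin - 1] = 0
            counts[start_bin + dur_bins] = 0
            avalanches.append(
                Avalanche(start_bin * bin_ms, dur_bins * bin_ms, c * dur_bins)
            )
        rates = RateSeries(
            bin_ms, counts / (n_neurons * bin_ms * 1e-3), counts, n_neurons
        )
        if path is not None:
            pd.DataFrame({"count": counts, "rate_hz": rates.rates}).to_csv(
                path, index=False
            )
        return {"rates": rates, "planted": avalanches}

    if kind == "toy-raster":
        n = int(params.pop("n", 120))
        period = float(params.pop("period", 100.0))
        n_cycles = int(params.pop("n_cycles", 5))
        bg_hz = float(params.pop("background_hz", 0.5))
        jitter_ms = float(params.pop("jitter_ms", 0.0))
        _reject_unknown(kind, params)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
        pattern = PhaseCodedPattern(phases, period, 0)
        t_total = n_cycles * period
        times = []
        ids = []
        base = pattern.spike_times
        for c in range(n_cycles):
            t = base + c * period
            if jitter_ms > 0:
                t = np.clip(t + rng.normal(0.0, jitter_ms, size=n), 0, t_total - 1e-9)
            times.append(t)
            ids.append(np.arange(n))
        n_bg = rng.poisson(bg_hz * 1e-3 * n * t_total)
        times.append(rng.uniform(0.0, t_total, size=n_bg))
        ids.append(rng.integers(0, n, size=n_bg))
        times = np.concatenate(times)
        ids = np.concatenate(ids)
        order = np.argsort(times, kind="stable")
        raster = SpikeRaster(times[order], ids[order], n, t_total, 0.0, {"seed": seed})
        if path is not None:
            rio.save_raster_text(raster, path)
        return {"raster": raster, "pattern": pattern}

    if kind == "toy-weights":
        n = int(params.pop("n", 20))
        scale = float(params.pop("scale", 0.1))
        _reject_unknown(kind, params)
        values = rng.normal(0.0, scale, size=(n, n))
        np.fill_diagonal(values, 0.0)
        w = WeightMatrix(values, meta={"seed": seed})
        if path is not None:
            rio.save_weights(w, path)
        return {"weights": w}

    raise ValueError(f"unknown fixture kind: {kind}")


def _reject_unknown(kind: str, params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameters for {kind}: {sorted(params)}")
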