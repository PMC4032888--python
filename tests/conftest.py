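"""Shared fixtures.

The heavy network runs used by the acceptance tests are session-scoped so
that the three study points (quiescent A, transition B, sustained-replay
C) are each simulated once and shared across criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from replaynet.analysis import (
    RateSeries,
    bin_rates,
    detect_avalanches,
    segment_up_down,
    waiting_times,
)
from replaynet.learning import LearningConfig, learn_weights, make_patterns, prune
from replaynet.simulate import SimConfig, simulate

N_FULL = 3000
PERIOD_MS = 333.0

#: study points of the phase diagram, (H0/Theta, alpha in 1/ms)
POINT_A = (0.207, 0.04)
POINT_B = (0.221, 0.06)
POINT_C = (0.250, 0.08)


def learned_weights(n, h0, seed, p=2):
    pats = make_patterns(n, p, PERIOD_MS, seed)
    cfg = LearningConfig(n=n, p=p, period=PERIOD_MS, h0=h0, seed=seed)
    return pats, prune(learn_weights(pats, cfg), cfg.f_plus_prune)


def run_point(n, h0, alpha, pattern_seed, sim_seed, t_total, t_transient=10_000.0):
    pats, w = learned_weights(n, h0, pattern_seed)
    sc = SimConfig(
        alpha=alpha, t_total=t_total, t_transient=t_transient, seed=sim_seed
    )
    return simulate(w, sc), pats


@pytest.fixture(scope="session")
def point_a():
    """>=30 s of point-A activity after a 10-s transient (quiescent regime)."""
    h0, alpha = POINT_A
    raster, pats = run_point(N_FULL, h0, alpha, 21, 121, t_total=45_000.0)
    return {"raster": raster, "patterns": pats}


@pytest.fixture(scope="session")
def point_c():
    """>=30 s of point-C activity after a 10-s transient (sustained replay)."""
    h0, alpha = POINT_C
    raster, pats = run_point(N_FULL, h0, alpha, 21, 321, t_total=45_000.0)
    return {"raster": raster, "patterns": pats}


@dataclass
class PooledPointB:
    """Avalanche statistics pooled over pattern realizations at point B."""

    rates_list: list[RateSeries]
    sizes: np.ndarray
    durations: np.ndarray
    dts: np.ndarray
    down_durations: np.ndarray
    up_durations: np.ndarray
    mean_rate_hz: float
    analyzed_s: float


@pytest.fixture(scope="session")
def point_b_pooled():
    """Three pattern realizations at point B, 150 s analyzed each.

    Statistics are pooled over realizations, following the protocol of
    averaging over independent quenched pattern phases.
    """
    h0, alpha = POINT_B
    rates_list, sizes, durs, dts = [], [], [], []
    downs, ups, rates_mean = [], [], []
    for sp, ss in [(21, 221), (22, 222), (23, 223)]:
        raster, _ = run_point(N_FULL, h0, alpha, sp, ss, t_total=160_000.0)
        rates = bin_rates(raster)
        avs = detect_avalanches(rates)
        rates_list.append(rates)
        sizes.extend(a.size for a in avs)
        durs.extend(a.duration_ms for a in avs)
        if len(avs) >= 2:
            dts.extend(waiting_times(avs))
        segs = segment_up_down(avs, 50.0, t_start=rates.t_start, t_stop=rates.t_stop)
        downs.extend(s.duration_ms for s in segs if s.kind == "down")
        ups.extend(s.duration_ms for s in segs if s.kind == "up")
        rates_mean.append(raster.mean_rate())
    return PooledPointB(
        rates_list=rates_list,
        sizes=np.array(sizes, dtype=float),
        durations=np.array(durs, dtype=float),
        dts=np.array(dts, dtype=float),
        down_durations=np.array(downs, dtype=float),
        up_durations=np.array(ups, dtype=float),
        mean_rate_hz=float(np.mean(rates_mean)),
        analyzed_s=3 * 150.0,
    )
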