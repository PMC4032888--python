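"""Statistics of spontaneous network activity.

Implements the analysis chain applied to a spike raster: 1-ms population
rate binning; classification of the dynamical regime from the shape of
the rate histogram (exponential / bimodal / Gaussian); neuronal-avalanche
detection as maximal runs of bins above a rate threshold; waiting times
between avalanches under both the per-linear-interval and
per-logarithmic-interval density conventions; segmentation of the run
into up and down states by concatenating avalanches against a maximum
waiting time; truncated power-law and exponential fits; and a circular
rank-correlation score quantifying replay of a stored pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal
import scipy.stats
from scipy.ndimage import gaussian_filter1d

from .learning import PhaseCodedPattern
from .simulate import SpikeRaster

# rate bands of the regime classifier (Hz): below LOW_BAND_HZ the activity
# is noise-driven, above HIGH_BAND_HZ it reflects collective replay
LOW_BAND_HZ = 2.0
HIGH_BAND_HZ = 10.0

DEFAULT_R_MIN_HZ = 7.0
DEFAULT_T_MAX_MS = 50.0


# ---------------------------------------------------------------------------
# rate binning
# ---------------------------------------------------------------------------


@dataclass
class RateSeries:
    """Per-bin population rate in Hz per neuron, plus raw spike counts."""

    bin_ms: float
    rates: np.ndarray
    counts: np.ndarray
    n_neurons: int
    t_start: float = 0.0

    @property
    def n_bins(self) -> int:
        return int(self.rates.size)

    @property
    def t_stop(self) -> float:
        return self.t_start + self.n_bins * self.bin_ms

    def bin_time(self, b: int) -> float:
        """Start time (ms) of bin ``b``."""
        return self.t_start + b * self.bin_ms


def bin_rates(
    raster: SpikeRaster,
    bin_ms: float = 1.0,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> RateSeries:
    """Bin a raster into per-interval rates, Hz per neuron.

    The default window is the post-transient part of the raster.  The
    rate of a bin is ``count / (N * bin_ms * 1e-3)``; the counts sum to
    the number of spikes in the window.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if t_start is None:
        t_start = raster.t_transient
    if t_stop is None:
        t_stop = raster.t_total
    if not t_stop > t_start:
        raise ValueError("empty analysis window")
    n_bins = int(np.ceil((t_stop - t_start) / bin_ms))
    keep = (raster.times >= t_start) & (raster.times < t_stop)
    idx = np.floor((raster.times[keep] - t_start) / bin_ms).astype(np.int64)
    idx = np.minimum(idx, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    rates = counts / (raster.n_neurons * bin_ms * 1e-3)
    return RateSeries(bin_ms, rates, counts, raster.n_neurons, t_start)


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimeLabel:
    """Shape class of the rate histogram with its diagnostics."""

    label: str  # "exponential" | "bimodal" | "gaussian"
    modes_hz: tuple
    valley_depth: float | None
    mean_rate_hz: float


def classify_regime(
    rates: RateSeries,
    min_bins: int = 10_000,
    hist_res_hz: float = 1.0,
    smooth_sd_bins: float = 2.0,
    prominence_frac: float = 0.05,
) -> RegimeLabel:
    """Classify the dynamical regime from the per-bin rate distribution.

    The histogram of per-bin rates (1-Hz resolution, lightly smoothed) is
    reduced to its modes; a single mode in the low band (< 2 Hz) marks
    the noise-driven exponential regime, a single mode in the high band
    (>= 10 Hz) the sustained-replay Gaussian regime, and modes in both
    bands separated by a local minimum mark the bimodal up/down regime.
    """
    if rates.n_bins < min_bins:
        raise ValueError(f"need at least {min_bins} rate bins for a stable histogram")
    r = rates.rates
    edges = np.arange(0.0, r.max() + 2 * hist_res_hz, hist_res_hz)
    hist, _ = np.histogram(r, bins=edges)
    h = gaussian_filter1d(hist.astype(float), smooth_sd_bins, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])

    prom = prominence_frac * h.max()
    peaks, _ = scipy.signal.find_peaks(h, prominence=prom)
    modes = list(peaks)
    # the zero bin can be a mode of a monotonically decaying histogram but
    # is never an interior peak; include it if the histogram falls away
    if h.size >= 2 and h[0] >= h[1] and (not modes or h[0] >= prom):
        modes = [0] + modes
    modes_hz = tuple(float(centers[m]) for m in modes)

    mean_rate = float(r.mean())
    low = [m for m in modes if centers[m] <= LOW_BAND_HZ]
    high = [m for m in modes if centers[m] >= HIGH_BAND_HZ]

    valley = None
    if low and high:
        lo, hi = low[0], high[-1]
        interior = h[lo : hi + 1]
        valley_val = interior.min()
        valley = float(min(h[lo], h[hi]) - valley_val)
        if valley > 0:
            return RegimeLabel("bimodal", modes_hz, valley, mean_rate)
    if high and not low:
        return RegimeLabel("gaussian", modes_hz, valley, mean_rate)
    if low and not high:
        return RegimeLabel("exponential", modes_hz, valley, mean_rate)
    # no clear band structure: fall back on the mean rate
    label = "exponential" if mean_rate <= LOW_BAND_HZ else "gaussian"
    return RegimeLabel(label, modes_hz, valley, mean_rate)


# ---------------------------------------------------------------------------
# avalanches and waiting times
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Avalanche:
    """Maximal run of bins with rate above the detection threshold."""

    start_ms: float
    duration_ms: float
    size: int

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


def detect_avalanches(
    rates: RateSeries, r_min_hz: float = DEFAULT_R_MIN_HZ
) -> list[Avalanche]:
    """Maximal runs of consecutive bins with rate strictly above ``r_min_hz``.

    A bin at or below the threshold terminates the run.  The size of an
    avalanche is its total spike count; its duration is the run length
    times the bin width.
    """
    if r_min_hz <= 0:
        raise ValueError("r_min_hz must be positive")
    active = rates.rates > r_min_hz
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    out = []
    for b0, b1 in zip(starts, stops):
        out.append(
            Avalanche(
                start_ms=rates.bin_time(int(b0)),
                duration_ms=(b1 - b0) * rates.bin_ms,
                size=int(rates.counts[b0:b1].sum()),
            )
        )
    return out


def waiting_times(avalanches: list[Avalanche]) -> np.ndarray:
    """Quiescent gaps (ms) from the end of each avalanche to the start of the next."""
    if len(avalanches) < 2:
        raise ValueError("need at least two avalanches")
    starts = np.array([a.start_ms for a in avalanches])
    ends = np.array([a.end_ms for a in avalanches])
    return starts[1:] - ends[:-1]


def waiting_time_density(
    dts: np.ndarray,
    convention: str = "per-linear-bin",
    n_bins: int = 40,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Histogram density of waiting times on logarithmically spaced bins.

    ``"per-linear-bin"`` returns P(dt), probability per ms, normalized so
    that ``sum(P * width) = 1``.  ``"per-log-bin"`` returns the density
    per logarithmic interval, i.e. the probability of a waiting time in
    ``[dt, dt (1 + dlambda)]`` divided by ``dlambda``; it is constructed
    bin-wise as ``P(dt) * dt``, so a power law of exponent ``-g`` in one
    convention appears with exponent ``-(g - 1)`` in the other.
    """
    if convention not in ("per-linear-bin", "per-log-bin"):
        raise ValueError("unknown density convention")
    dts = np.asarray(dts, dtype=float)
    if dts.size == 0:
        raise ValueError("no waiting times")
    if bins is None:
        lo, hi = dts.min(), dts.max()
        if lo == hi:
            bins = np.array([lo * 0.9, hi * 1.1]) if lo > 0 else np.array([-0.5, 0.5])
        else:
            bins = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    counts, edges = np.histogram(dts, bins=bins)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:]) if edges[0] > 0 else 0.5 * (edges[:-1] + edges[1:])
    p_linear = counts / (counts.sum() * widths)
    density = p_linear if convention == "per-linear-bin" else p_linear * centers
    return pd.DataFrame(
        {
            "center_ms": centers,
            "width_ms": widths,
            "count": counts,
            "density": density,
        }
    )


# ---------------------------------------------------------------------------
# up / down state segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSegment:
    """One up or down interval of the segmented run."""

    kind: str  # "up" | "down"
    start_ms: float
    duration_ms: float

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


def segment_up_down(
    avalanches: list[Avalanche],
    t_max_ms: float = DEFAULT_T_MAX_MS,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> list[StateSegment]:
    """Segment the run into up and down states.

    An up state is a maximal concatenation of at least two avalanches
    whose internal waiting times are all below ``t_max_ms``; it spans
    from the first avalanche's start to the last one's end.  An isolated
    avalanche — preceded and followed by waiting times of ``t_max_ms`` or
    more — does not interrupt the surrounding down state.  Down states
    cover the remainder of the ``[t_start, t_stop)`` window, so up and
    down durations add up to the window length.
    """
    if t_start is None:
        t_start = avalanches[0].start_ms if avalanches else 0.0
    if t_stop is None:
        t_stop = avalanches[-1].end_ms if avalanches else t_start
    ups: list[tuple[float, float]] = []
    group: list[Avalanche] = []
    for av in avalanches:
        if group and av.start_ms - group[-1].end_ms < t_max_ms:
            group.append(av)
        else:
            if len(group) >= 2:
                ups.append((group[0].start_ms, group[-1].end_ms))
            group = [av]
    if len(group) >= 2:
        ups.append((group[0].start_ms, group[-1].end_ms))

    segments: list[StateSegment] = []
    cursor = t_start
    for a, b in ups:
        if a > cursor:
            segments.append(StateSegment("down", cursor, a - cursor))
        segments.append(StateSegment("up", a, b - a))
        cursor = b
    if t_stop > cursor:
        segments.append(StateSegment("down", cursor, t_stop - cursor))
    return segments


# ---------------------------------------------------------------------------
# distribution fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    """Truncated power-law fit, density convention ``P(x) ~ x**(-exponent)``."""

    exponent: float
    x_min: float
    x_max: float
    method: str
    n_samples: int
    ks_distance: float


def _truncated_pareto_logz(gamma: float, a: float, b: float) -> float:
    """log of the normalizing integral of x^-gamma on [a, b]."""
    if abs(gamma - 1.0) < 1e-9:
        return float(np.log(np.log(b / a)))
    u = (a ** (1.0 - gamma) - b ** (1.0 - gamma)) / (gamma - 1.0)
    return float(np.log(u))


def _truncated_pareto_cdf(x: np.ndarray, gamma: float, a: float, b: float) -> np.ndarray:
    if abs(gamma - 1.0) < 1e-9:
        return np.log(x / a) / np.log(b / a)
    return (a ** (1.0 - gamma) - x ** (1.0 - gamma)) / (
        a ** (1.0 - gamma) - b ** (1.0 - gamma)
    )


def _truncated_zeta_weights(gamma: float, a: int, b: int) -> np.ndarray:
    k = np.arange(a, b + 1, dtype=float)
    return k**-gamma


def fit_power_law(
    samples: np.ndarray,
    x_min: float,
    x_max: float,
    method: str = "mle",
    discrete: bool = False,
    min_samples: int = 100,
    n_bins: int = 25,
) -> PowerLawFit:
    """Fit a truncated power law on ``[x_min, x_max]``.

    ``method="mle"``: maximum likelihood under the doubly truncated
    Pareto density ``C x^-gamma`` (the standard estimator for bounded
    scaling ranges); with ``discrete=True`` the exact truncated-zeta
    likelihood over the integers in range is used instead, which matters
    for integer-valued data with a narrow support (avalanche durations
    in 1-ms bins, spike counts).  ``method="lsq"``: least squares on the
    log-binned empirical density (bin edges snapped to half-integers in
    the discrete case).  Returns the density exponent in the positive
    convention together with a Kolmogorov-Smirnov distance between the
    in-range sample and the fitted law.
    """
    if not 0 < x_min < x_max:
        raise ValueError("need 0 < x_min < x_max")
    samples = np.asarray(samples, dtype=float)
    x = samples[(samples >= x_min) & (samples <= x_max)]
    if x.size < min_samples:
        raise ValueError(
            f"only {x.size} samples in [{x_min}, {x_max}]; need {min_samples}"
        )
    if np.unique(x).size < 3:
        raise ValueError("degenerate support: fewer than 3 distinct values in range")

    if method == "mle":
        if discrete:
            a, b = int(round(x_min)), int(round(x_max))
            counts = np.bincount((x - a).astype(np.int64), minlength=b - a + 1)
            mean_log = float(np.mean(np.log(x)))

            def nll(gamma: float) -> float:
                return gamma * mean_log + np.log(
                    _truncated_zeta_weights(gamma, a, b).sum()
                )

        else:
            mean_log = float(np.mean(np.log(x)))

            def nll(gamma: float) -> float:
                return gamma * mean_log + _truncated_pareto_logz(gamma, x_min, x_max)

        res = scipy.optimize.minimize_scalar(nll, bounds=(0.01, 20.0), method="bounded")
        gamma = float(res.x)
    elif method == "lsq":
        edges = np.geomspace(x_min, x_max, n_bins + 1)
        if discrete:
            edges = np.unique(np.round(edges - 0.5)) + 0.5
            edges = edges[(edges >= x_min - 0.5) & (edges <= x_max + 0.5)]
        counts, edges = np.histogram(x, bins=edges)
        widths = np.diff(edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = counts / (counts.sum() * widths)
        good = counts > 0
        if good.sum() < 3:
            raise ValueError("too few occupied bins for a least-squares fit")
        slope, _ = np.polyfit(np.log(centers[good]), np.log(dens[good]), 1)
        gamma = float(-slope)
    else:
        raise ValueError("method must be 'mle' or 'lsq'")

    xs = np.sort(x)
    ecdf = np.arange(1, xs.size + 1) / xs.size
    if discrete:
        a, b = int(round(x_min)), int(round(x_max))
        w = _truncated_zeta_weights(gamma, a, b)
        cdf_tab = np.cumsum(w) / w.sum()
        model_cdf = cdf_tab[np.clip(xs.astype(np.int64) - a, 0, b - a)]
    else:
        model_cdf = _truncated_pareto_cdf(xs, gamma, x_min, x_max)
    ks = float(np.max(np.abs(ecdf - model_cdf)))
    return PowerLawFit(gamma, x_min, x_max, method, int(x.size), ks)


@dataclass(frozen=True)
class ExponentialFit:
    """Left-truncated exponential fit of durations."""

    rate_per_ms: float
    mean_ms: float
    x0_ms: float
    ks_statistic: float
    ks_pvalue: float
    n_samples: int


def fit_exponential(durations: np.ndarray, min_samples: int = 50) -> ExponentialFit:
    """MLE exponential fit with left truncation at the smallest duration.

    The rate is ``1 / mean(d - d_min)`` — the maximum-likelihood estimate
    for an exponential observed only above the minimum observable
    duration — with a Kolmogorov-Smirnov test of the shifted sample
    against the fitted law.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < min_samples:
        raise ValueError(f"need at least {min_samples} durations")
    x0 = float(d.min())
    shifted = d - x0
    mean_excess = float(shifted.mean())
    if mean_excess <= 0:
        # all durations identical: the exponential hypothesis fails flat
        return ExponentialFit(np.inf, x0, x0, 1.0, 0.0, int(d.size))
    rate = 1.0 / mean_excess
    ks = scipy.stats.kstest(shifted, "expon", args=(0.0, mean_excess))
    return ExponentialFit(
        rate, float(d.mean()), x0, float(ks.statistic), float(ks.pvalue), int(d.size)
    )


# ---------------------------------------------------------------------------
# replay similarity
# ---------------------------------------------------------------------------


def replay_similarity(
    raster: SpikeRaster,
    pattern: PhaseCodedPattern,
    t_start: float | None = None,
    t_stop: float | None = None,
    min_spikers: int = 10,
) -> float:
    """Circular rank correlation between firing order and pattern phases.

    For each neuron that spikes in the window, take its first spike time;
    convert first-spike times and pattern phases to circular ranks and
    compute the circular correlation coefficient.  Scores near +1
    indicate replay of the pattern in its stored order (near -1 for
    time-reversed replay); unrelated activity scores near 0.
    """
    if t_start is None:
        t_start = raster.t_transient
    if t_stop is None:
        t_stop = raster.t_total
    keep = (raster.times >= t_start) & (raster.times < t_stop)
    times, ids = raster.times[keep], raster.ids[keep]
    if times.size == 0:
        raise ValueError("no spikes in window")
    order = np.argsort(times, kind="stable")
    first: dict[int, float] = {}
    for k in order:
        i = int(ids[k])
        if i not in first:
            first[i] = float(times[k])
    if len(first) < min_spikers:
        raise ValueError(f"need at least {min_spikers} distinct spiking neurons")
    neurons = np.array(sorted(first))
    t_first = np.array([first[i] for i in neurons])
    phases = pattern.phases[neurons]

    m = neurons.size
    a = 2.0 * np.pi * scipy.stats.rankdata(t_first, method="average") / m
    b = 2.0 * np.pi * scipy.stats.rankdata(phases, method="average") / m
    sa = np.sin(a - _circular_mean(a))
    sb = np.sin(b - _circular_mean(b))
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))
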