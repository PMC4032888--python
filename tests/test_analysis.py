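"""Rate binning, regime classification, avalanches, waiting times,
up/down segmentation, distribution fits and replay similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replaynet.analysis import (
    Avalanche,
    RateSeries,
    bin_rates,
    classify_regime,
    detect_avalanches,
    fit_exponential,
    fit_power_law,
    replay_similarity,
    segment_up_down,
    waiting_time_density,
    waiting_times,
)
from replaynet.experiment import make_fixture
from replaynet.simulate import SpikeRaster


def rates_from_counts(counts, n_neurons=1000, bin_ms=1.0):
    counts = np.asarray(counts, dtype=np.int64)
    return RateSeries(
        bin_ms, counts / (n_neurons * bin_ms * 1e-3), counts, n_neurons
    )


# ---------------------------------------------------------------------------
# naive reference implementations (oracles)
# ---------------------------------------------------------------------------


def naive_avalanches(rates: RateSeries, r_min: float):
    out = []
    run = None
    for b in range(rates.n_bins):
        if rates.rates[b] > r_min:
            if run is None:
                run = [b, b]
            else:
                run[1] = b
        else:
            if run is not None:
                out.append(run)
                run = None
    if run is not None:
        out.append(run)
    return [
        Avalanche(
            rates.bin_time(b0),
            (b1 - b0 + 1) * rates.bin_ms,
            int(rates.counts[b0 : b1 + 1].sum()),
        )
        for b0, b1 in out
    ]


def naive_segments(avalanches, t_max, t_start, t_stop):
    """Direct application of the concatenation rule: group avalanches
    whose gaps are < t_max; groups of one are absorbed into down."""
    groups = []
    for av in avalanches:
        if groups and av.start_ms - groups[-1][-1].end_ms < t_max:
            groups[-1].append(av)
        else:
            groups.append([av])
    ups = [(g[0].start_ms, g[-1].end_ms) for g in groups if len(g) >= 2]
    segs = []
    cur = t_start
    for a, b in ups:
        if a > cur:
            segs.append(("down", cur, a - cur))
        segs.append(("up", a, b - a))
        cur = b
    if t_stop > cur:
        segs.append(("down", cur, t_stop - cur))
    return segs


# ---------------------------------------------------------------------------
# rate binning
# ---------------------------------------------------------------------------


class TestBinRates:
    def test_single_bin_rate_value(self):
        # 3 spikes among 3000 neurons in one 1-ms bin -> 1 Hz per neuron
        r = SpikeRaster(np.array([0.5, 0.6, 0.7]), np.array([0, 1, 2]), 3000, 1.0)
        rs = bin_rates(r, 1.0)
        assert rs.rates[0] == pytest.approx(1.0)

    def test_empty_raster_all_zero(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 10, 50.0)
        rs = bin_rates(r, 1.0)
        assert rs.n_bins == 50
        assert np.all(rs.rates == 0.0)

    @pytest.mark.parametrize("bin_ms", [0.5, 1.0, 2.0, 7.0])
    def test_count_conservation(self, bin_ms):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1000.0, 5000))
        ids = rng.integers(0, 100, 5000)
        r = SpikeRaster(times, ids, 100, 1000.0)
        rs = bin_rates(r, bin_ms)
        assert rs.counts.sum() == 5000

    def test_invalid_bin(self):
        r = SpikeRaster(np.array([1.0]), np.array([0]), 10, 10.0)
        with pytest.raises(ValueError):
            bin_rates(r, 0.0)


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------


class TestClassifyRegime:
    def _classify(self, rates_hz, n_neurons=1000):
        counts = np.round(np.asarray(rates_hz) * n_neurons * 1e-3).astype(int)
        return classify_regime(rates_from_counts(counts, n_neurons))

    def test_exponential_mixture(self):
        rng = np.random.default_rng(0)
        lab = self._classify(rng.exponential(1.0, 20_000))
        assert lab.label == "exponential"

    def test_gaussian_mixture(self):
        rng = np.random.default_rng(1)
        lab = self._classify(np.clip(rng.normal(20.0, 3.0, 20_000), 0, None))
        assert lab.label == "gaussian"
        assert lab.modes_hz[-1] == pytest.approx(20.0, abs=2.0)

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(2)
        low = rng.exponential(1.0, 12_000)
        high = np.clip(rng.normal(20.0, 3.0, 8_000), 0, None)
        lab = self._classify(np.concatenate([low, high]))
        assert lab.label == "bimodal"
        assert lab.valley_depth is not None and lab.valley_depth > 0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            self._classify(np.ones(100))


# ---------------------------------------------------------------------------
# avalanches
# ---------------------------------------------------------------------------


class TestDetectAvalanches:
    def test_manual_enumeration(self):
        # rates [0, 10, 20, 0, 8, 0] Hz at N=1000: counts [0,10,20,0,8,0]
        rs = rates_from_counts([0, 10, 20, 0, 8, 0])
        avs = detect_avalanches(rs, 7.0)
        assert len(avs) == 2
        assert (avs[0].duration_ms, avs[0].size) == (2.0, 30)
        assert (avs[1].duration_ms, avs[1].size) == (1.0, 8)
        assert avs[0].start_ms == 1.0 and avs[1].start_ms == 4.0

    def test_all_subthreshold_empty(self):
        rs = rates_from_counts([3, 7, 5, 0])
        assert detect_avalanches(rs, 7.0) == []  # rate == R_min terminates

    def test_planted_fixture_recovered_exactly(self):
        fx = make_fixture("toy-rates", seed=3)
        avs = detect_avalanches(fx["rates"], 7.0)
        planted = {(a.start_ms, a.duration_ms, a.size) for a in fx["planted"]}
        detected = {(a.start_ms, a.duration_ms, a.size) for a in avs}
        assert planted <= detected
        # every extra detection comes from background runs strictly above
        # threshold, which the generator forbids
        assert planted == detected

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 25, size=rng.integers(5, 300))
        rs = rates_from_counts(counts)
        assert detect_avalanches(rs, 7.0) == naive_avalanches(rs, 7.0)

    def test_size_conservation(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, 1000)
        rs = rates_from_counts(counts)
        avs = detect_avalanches(rs, 7.0)
        assert sum(a.size for a in avs) <= counts.sum()


class TestWaitingTimes:
    def test_end_to_start_definition(self):
        avs = [Avalanche(0.0, 10.0, 5), Avalanche(14.0, 2.0, 3)]
        np.testing.assert_allclose(waiting_times(avs), [4.0])

    def test_count_is_k_minus_one(self):
        avs = [Avalanche(10.0 * k, 2.0, 1) for k in range(7)]
        assert waiting_times(avs).size == 6

    def test_toy_single_gap(self):
        rs = rates_from_counts([0, 10, 20, 0, 8, 0])
        avs = detect_avalanches(rs, 7.0)
        np.testing.assert_allclose(waiting_times(avs), [1.0])

    def test_needs_two(self):
        with pytest.raises(ValueError):
            waiting_times([Avalanche(0.0, 1.0, 1)])


class TestWaitingTimeDensity:
    def test_log_measure_is_linear_times_dt(self):
        rng = np.random.default_rng(0)
        dts = rng.uniform(1.0, 100.0, 5000)
        lin = waiting_time_density(dts, "per-linear-bin")
        log = waiting_time_density(dts, "per-log-bin")
        np.testing.assert_allclose(
            log["density"], lin["density"] * lin["center_ms"], rtol=1e-12
        )

    def test_linear_density_normalized(self):
        rng = np.random.default_rng(1)
        dts = rng.exponential(30.0, 10_000) + 1.0
        lin = waiting_time_density(dts, "per-linear-bin")
        assert (lin["density"] * lin["width_ms"]).sum() == pytest.approx(1.0)

    def test_degenerate_single_value(self):
        tab = waiting_time_density(np.full(10, 5.0))
        assert (tab["density"] * tab["width_ms"]).sum() == pytest.approx(1.0)
        assert (tab["count"] > 0).sum() == 1

    def test_power_law_exponent_shift_identity(self):
        """On exact power-law input the two conventions' fitted exponents
        differ by exactly one (P ~ dt^-3 vs P~ ~ dt^-2)."""
        rng = np.random.default_rng(2)
        g, a, b = 3.0, 10.0, 50.0
        u = rng.uniform(size=100_000)
        x = (a ** (1 - g) - u * (a ** (1 - g) - b ** (1 - g))) ** (1 / (1 - g))
        bins = np.geomspace(a, b, 30)
        lin = waiting_time_density(x, "per-linear-bin", bins=bins)
        log = waiting_time_density(x, "per-log-bin", bins=bins)
        good = lin["count"] > 0
        s_lin = np.polyfit(np.log(lin["center_ms"][good]), np.log(lin["density"][good]), 1)[0]
        s_log = np.polyfit(np.log(log["center_ms"][good]), np.log(log["density"][good]), 1)[0]
        assert s_log - s_lin == pytest.approx(1.0, abs=1e-9)
        assert -s_lin == pytest.approx(3.0, abs=0.15)


# ---------------------------------------------------------------------------
# up / down segmentation
# ---------------------------------------------------------------------------


class TestSegmentUpDown:
    def test_manual_example(self):
        """Gaps [20, 60, 30, 10] ms with T_max = 50: avalanches 1-2 form an
        up state, the 60-ms gap a down state, avalanches 3-5 a second up."""
        avs = []
        t = 0.0
        for gap in [0.0, 20.0, 60.0, 30.0, 10.0]:
            t += gap
            avs.append(Avalanche(t, 5.0, 10))
            t += 5.0
        segs = segment_up_down(avs, 50.0)
        kinds = [s.kind for s in segs]
        assert kinds == ["up", "down", "up"]
        assert segs[0].start_ms == avs[0].start_ms
        assert segs[0].end_ms == avs[1].end_ms
        assert segs[2].start_ms == avs[2].start_ms
        assert segs[2].end_ms == avs[4].end_ms

    def test_single_avalanche_is_down(self):
        segs = segment_up_down([Avalanche(100.0, 5.0, 10)], 50.0, 0.0, 1000.0)
        assert [s.kind for s in segs] == ["down"]
        assert segs[0].duration_ms == 1000.0

    def test_isolated_avalanche_does_not_break_down_state(self):
        avs = [
            Avalanche(0.0, 5.0, 10),
            Avalanche(10.0, 5.0, 10),
            Avalanche(200.0, 5.0, 10),  # isolated
            Avalanche(400.0, 5.0, 10),
            Avalanche(410.0, 5.0, 10),
        ]
        segs = segment_up_down(avs, 50.0, 0.0, 500.0)
        assert [s.kind for s in segs] == ["up", "down", "up", "down"]
        assert segs[1].duration_ms == pytest.approx(400.0 - 15.0)

    def test_all_close_gaps_single_up(self):
        avs = [Avalanche(10.0 * k, 5.0, 1) for k in range(10)]
        segs = segment_up_down(avs, 50.0)
        assert [s.kind for s in segs] == ["up"]

    def test_durations_tile_the_window(self):
        rng = np.random.default_rng(7)
        t = 0.0
        avs = []
        for _ in range(200):
            t += rng.exponential(40.0) + 1.0
            d = float(rng.integers(1, 10))
            avs.append(Avalanche(round(t), d, 5))
            t += d
        segs = segment_up_down(avs, 50.0, 0.0, t + 100.0)
        assert sum(s.duration_ms for s in segs) == pytest.approx(t + 100.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = 0.0
        avs = []
        for _ in range(rng.integers(0, 60)):
            t += float(rng.integers(1, 120))
            d = float(rng.integers(1, 20))
            avs.append(Avalanche(t, d, 1))
            t += d
        t_stop = t + 50.0
        got = segment_up_down(avs, 50.0, 0.0, t_stop)
        expected = naive_segments(avs, 50.0, 0.0, t_stop)
        assert [(s.kind, s.start_ms, s.duration_ms) for s in got] == expected


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


class TestFitPowerLaw:
    @pytest.mark.parametrize("gamma", [1.5, 2.0, 3.0])
    def test_continuous_recovery(self, gamma):
        rng = np.random.default_rng(int(gamma * 10))
        a, b = 4.0, 1e4
        u = rng.uniform(size=100_000)
        x = (a ** (1 - gamma) - u * (a ** (1 - gamma) - b ** (1 - gamma))) ** (
            1 / (1 - gamma)
        )
        fit = fit_power_law(x, a, b)
        assert fit.exponent == pytest.approx(gamma, abs=0.05)

    def test_discrete_zipf_recovery(self):
        rng = np.random.default_rng(0)
        k = np.arange(4, 10_001)
        w = k ** -1.5
        x = rng.choice(k, size=100_000, p=w / w.sum()).astype(float)
        fit = fit_power_law(x, 4, 10_000, discrete=True)
        assert fit.exponent == pytest.approx(1.5, abs=0.05)

    def test_mle_lsq_agreement(self):
        rng = np.random.default_rng(5)
        a, b, g = 2.0, 500.0, 2.0
        u = rng.uniform(size=100_000)
        x = (a ** (1 - g) - u * (a ** (1 - g) - b ** (1 - g))) ** (1 / (1 - g))
        mle = fit_power_law(x, a, b, method="mle").exponent
        lsq = fit_power_law(x, a, b, method="lsq").exponent
        assert abs(mle - lsq) < 0.1

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([5.0] * 50 + [7.0] * 50), 1.0, 100.0)
        with pytest.raises(ValueError):
            fit_power_law(np.arange(1, 50, dtype=float), 1.0, 100.0)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            fit_power_law(np.arange(200, dtype=float), 10.0, 5.0)


class TestFitExponential:
    def test_mean_recovery(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(200.0, 10_000)
        fit = fit_exponential(d)
        assert 1.0 / fit.rate_per_ms == pytest.approx(200.0, rel=0.02)
        assert fit.ks_pvalue > 0.01

    def test_left_truncation(self):
        rng = np.random.default_rng(1)
        d = 50.0 + rng.exponential(100.0, 10_000)
        fit = fit_exponential(d)
        assert 1.0 / fit.rate_per_ms == pytest.approx(100.0, rel=0.03)

    def test_constant_durations_rejected_by_ks(self):
        fit = fit_exponential(np.full(100, 7.0))
        assert fit.ks_pvalue == pytest.approx(0.0)

    def test_insufficient(self):
        with pytest.raises(ValueError):
            fit_exponential(np.ones(10))


# ---------------------------------------------------------------------------
# replay similarity
# ---------------------------------------------------------------------------


class TestReplaySimilarity:
    def test_perfect_cycle_scores_high(self):
        fx = make_fixture("toy-raster", {"background_hz": 0.0, "n_cycles": 1}, seed=0)
        score = replay_similarity(fx["raster"], fx["pattern"])
        assert score > 0.95

    def test_planted_replay_with_background(self):
        fx = make_fixture("toy-raster", {"background_hz": 1.0, "n_cycles": 5}, seed=1)
        assert replay_similarity(fx["raster"], fx["pattern"]) > 0.9

    def test_permuted_ids_score_near_zero(self):
        fx = make_fixture("toy-raster", {"background_hz": 0.0, "n_cycles": 1,
                                         "n": 3000}, seed=2)
        raster = fx["raster"]
        rng = np.random.default_rng(3)
        shuffled = SpikeRaster(
            raster.times, rng.permutation(raster.ids), raster.n_neurons,
            raster.t_total,
        )
        assert abs(replay_similarity(shuffled, fx["pattern"])) < 0.1

    def test_too_few_spikers(self):
        r = SpikeRaster(np.arange(5.0), np.arange(5), 100, 10.0)
        fx = make_fixture("toy-raster", seed=0)
        with pytest.raises(ValueError):
            replay_similarity(r, fx["pattern"])
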