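"""PETH selection, rate smoothing, quintile grouping and the latency
shuffle test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from swrkit import io, latency, synth
from swrkit.latency import fwhm_to_sigma
from swrkit.synth import UnitGenConfig


def _events(onsets, dur=0.08):
    onsets = np.asarray(onsets)
    return io.make_event_table(onsets, onsets + dur / 2, onsets + dur)


class TestPETH:
    def test_empty_train_flagged(self):
        peth = latency.compute_peth([], [1.0, 2.0])
        assert (peth.rate_hz == 0).all()
        assert np.isnan(peth.peak_time_ms)

    def test_single_latency_lands_in_one_bin(self):
        onsets = [1.0, 2.0, 3.0]
        spikes = [o - 0.009 for o in onsets]  # mid-bin, away from edges
        peth = latency.compute_peth(spikes, onsets)
        nonzero = np.flatnonzero(peth.rate_hz)
        assert len(nonzero) == 1
        center = peth.bin_centers_ms[nonzero[0]]
        assert abs(center - (-10.0)) <= 1.25  # within one 2.5-ms bin
        assert peth.peak_time_ms == pytest.approx(center)

    def test_homogeneous_poisson_is_flat(self, rng):
        onsets = 1.0 + np.arange(200)
        spikes = np.sort(rng.uniform(0, 201, size=40000))  # ~200 Hz
        peth = latency.compute_peth(spikes, onsets)
        lam = 200.0 * 0.0025 * len(onsets)     # expected count per bin
        se_rate = np.sqrt(lam) / (len(onsets) * 0.0025)
        assert (np.abs(peth.rate_hz - 200.0) < 3.5 * se_rate).mean() > 0.99


class TestSelection:
    def test_zero_spread_selects_none(self):
        peaks = pd.Series({f"i{k}": -10.0 for k in range(20)})
        assert latency.select_pre_swr_interneurons(peaks) == []

    def test_clear_outlier_selected(self, rng):
        peaks = pd.Series(rng.normal(20.0, 5.0, 99),
                          index=[f"i{k}" for k in range(99)])
        peaks["early"] = -30.0
        assert latency.select_pre_swr_interneurons(peaks) == ["early"]

    def test_infinite_criterion_selects_none(self, rng):
        peaks = pd.Series(rng.normal(0.0, 5.0, 50))
        assert latency.select_pre_swr_interneurons(peaks,
                                                   criterion_sd=np.inf) == []

    def test_top_k_intersection(self, rng):
        peaks = pd.Series(rng.normal(20.0, 5.0, 50),
                          index=[f"i{k}" for k in range(50)])
        peaks["a"] = -40.0
        peaks["b"] = -35.0
        sel = latency.select_pre_swr_interneurons(peaks, top_k=1)
        assert sel == ["a"]


class TestSmoothedRate:
    def test_area_conserves_spike_count(self, rng):
        spikes = np.sort(rng.uniform(1.0, 9.0, 150))
        rate = latency.smoothed_rate(spikes)
        area = rate.samples.sum() / rate.rate
        assert area == pytest.approx(150.0, rel=1e-3)

    def test_two_distant_spikes_two_bumps(self):
        rate = latency.smoothed_rate([1.0, 1.1])
        area = rate.samples.sum() / rate.rate
        assert area == pytest.approx(2.0, rel=1e-3)
        mid = rate.samples[rate.index_at(1.05)]
        assert mid < rate.samples.max() * 1e-3


class TestPreSwrRate:
    def test_silence_gives_zero(self):
        rate = latency.smoothed_rate([5.0], t_start=0.0, t_stop=6.0)
        assert latency.pre_swr_rate(rate, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_constant_rate_trace_recovered(self):
        rate = latency.smoothed_rate([], t_start=0.0, t_stop=10.0)
        const = rate.with_samples(np.full(rate.n, 20.0))
        assert latency.pre_swr_rate(const, 5.0) == pytest.approx(20.0)

    def test_matches_gaussian_quadrature_oracle(self):
        """Grid-based estimate equals the closed-form Gaussian-mass value."""
        onset = 2.0
        spike = onset - 0.015   # centered in the 30-ms window
        sigma_s = fwhm_to_sigma(15.0) / 1000.0
        expected = (ndtr((onset - spike) / sigma_s)
                    - ndtr((onset - 0.030 - spike) / sigma_s)) / 0.030
        rate = latency.smoothed_rate([spike], t_start=1.0, t_stop=3.0,
                                     dt_ms=0.2)
        grid_val = latency.pre_swr_rate(rate, onset)
        exact = latency.pre_swr_rates([spike], [onset])[0]
        assert exact == pytest.approx(expected, rel=1e-9)
        assert grid_val == pytest.approx(expected, rel=0.01)


class TestQuintiles:
    def test_ten_distinct_rates(self):
        rates = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
        labels = latency.assign_quintiles(rates)
        assert np.bincount(labels)[1:].tolist() == [2, 2, 2, 2, 2]
        assert labels[0] == 1 and labels[1] == 1
        assert labels[-1] == 5

    def test_all_equal_rates_still_balanced(self):
        labels = latency.assign_quintiles(np.ones(13))
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_uniform_rates_give_monotone_quintile_means(self, rng):
        rates = rng.random(1000)
        labels = latency.assign_quintiles(rates)
        means = [rates[labels == q].mean() for q in range(1, 6)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_too_few_swrs_rejected(self):
        with pytest.raises(ValueError):
            latency.assign_quintiles([1.0, 2.0, 3.0])


class TestLatencyAndRank:
    @staticmethod
    def _spikes(times_by_cell):
        rows = [(cell, "pyr", t) for cell, times in times_by_cell.items()
                for t in times]
        df = pd.DataFrame(rows, columns=["cell_id", "cell_class",
                                         "spike_time_s"])
        return df.sort_values(["cell_id", "spike_time_s"],
                              kind="stable").reset_index(drop=True)

    def test_first_and_last_ranks(self):
        events = _events([1.0])
        spikes = self._spikes({f"c{k}": [1.0 + 0.005 * (k + 1)]
                               for k in range(5)})
        out = latency.spike_latency_and_rank(spikes, events)
        by_cell = out.set_index("cell_id")
        assert by_cell.loc["c0", "rank"] == 0.0
        assert by_cell.loc["c4", "rank"] == 1.0

    def test_middle_cell_rank_and_latency(self):
        events = _events([1.0])
        spikes = self._spikes({"a": [1.005], "b": [1.010], "c": [1.015]})
        out = latency.spike_latency_and_rank(spikes, events).set_index("cell_id")
        assert out.loc["b", "rank"] == pytest.approx(0.5)
        assert out.loc["b", "latency_ms"] == pytest.approx(10.0)

    def test_sole_participant_rank_undefined(self):
        out = latency.spike_latency_and_rank(
            self._spikes({"a": [1.01]}), _events([1.0]))
        assert np.isnan(out["rank"].iloc[0])

    def test_time_shift_equivariance(self, rng):
        events = _events([1.0, 3.0])
        spikes = self._spikes({"a": [1.01, 3.02], "b": [1.02, 3.01]})
        base = latency.spike_latency_and_rank(spikes, events)
        shifted_spikes = spikes.assign(
            spike_time_s=spikes["spike_time_s"] + 0.004)
        shifted = latency.spike_latency_and_rank(shifted_spikes, events)
        np.testing.assert_allclose(shifted["latency_ms"],
                                   base["latency_ms"] + 4.0)
        np.testing.assert_allclose(shifted["rank"], base["rank"])


class TestQuintileLatencyTest:
    def test_equal_latencies_not_significant(self):
        lat = np.full(100, 25.0)
        q = latency.assign_quintiles(np.arange(100, dtype=float))
        res = latency.quintile_latency_test(lat, q, seed=0)
        assert res.delta_ms == 0.0
        assert not res.significant

    def test_injected_gap_detected(self, rng):
        q = latency.assign_quintiles(rng.random(300))
        lat = rng.normal(30.0, 10.0, 300)
        lat[q == 1] += 10.0
        res = latency.quintile_latency_test(lat, q, seed=1)
        assert res.significant and res.delta_ms > 0

    def test_deterministic(self, rng):
        q = latency.assign_quintiles(rng.random(100))
        lat = rng.normal(30.0, 10.0, 100)
        a = latency.quintile_latency_test(lat, q, seed=3)
        b = latency.quintile_latency_test(lat, q, seed=3)
        np.testing.assert_array_equal(a.null, b.null)
        assert a.lo == b.lo and a.hi == b.hi

    def test_empty_quintile_latencies_rejected(self):
        lat = np.full(10, np.nan)
        lat[:2] = 20.0
        q = np.repeat([1, 2, 3, 4, 5], 2)
        lat[q == 1] = np.nan
        with pytest.raises(ValueError):
            latency.quintile_latency_test(lat, q, seed=0)


class TestQuintileSummaries:
    def test_rate_flat_when_equal(self):
        onsets = 2.0 + np.arange(10)
        events = _events(onsets)
        rows = [(f"p", "pyr", o + 0.01) for o in onsets]
        spikes = pd.DataFrame(rows, columns=["cell_id", "cell_class",
                                             "spike_time_s"])
        q = latency.assign_quintiles(np.arange(10.0))
        rates = latency.quintile_firing_rate(spikes, q, events)
        assert rates.nunique() == 1

    def test_zero_spikes_zero_rates(self):
        events = _events(2.0 + np.arange(10))
        spikes = pd.DataFrame(columns=["cell_id", "cell_class",
                                       "spike_time_s"])
        q = latency.assign_quintiles(np.arange(10.0))
        assert (latency.quintile_firing_rate(spikes, q, events) == 0).all()

    def test_duration_flat_and_empty_flagged(self):
        events = _events(2.0 + np.arange(10), dur=0.06)
        q = latency.assign_quintiles(np.arange(10.0))
        durs = latency.swr_duration_by_quintile(q, events)
        np.testing.assert_allclose(durs, 0.06)
        # an artificial grouping that never uses label 5
        q2 = np.where(q == 5, 4, q)
        durs2 = latency.swr_duration_by_quintile(q2, events)
        assert np.isnan(durs2[5])


class TestEndToEndUnits:
    def test_induced_latency_gap_detected_via_full_pipeline(self):
        onsets = 2.0 + 1.0 * np.arange(300)
        events = _events(onsets)
        cfg = UnitGenConfig(n_swr=300, latency_slope_ms_per_hz=0.25, seed=3)
        spikes, _ = synth.gen_unit_spikes(cfg, events)
        t_int = spikes.loc[spikes["cell_id"] == "int000",
                           "spike_time_s"].to_numpy()
        rates = latency.pre_swr_rates(t_int, onsets)
        q = latency.assign_quintiles(rates)
        lat = latency.spike_latency_and_rank(spikes, events)
        per_swr = lat[lat["cell_id"] == "pyr000"].set_index(
            "swr_id")["latency_ms"].reindex(events["event_id"]).to_numpy()
        res = latency.quintile_latency_test(per_swr, q, seed=0)
        assert res.significant and res.delta_ms > 0
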