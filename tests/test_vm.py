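"""Intracellular pipeline: spike handling, dVm_pre, peaks, conductance,
triplet and pairwise statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swrkit import vm
from swrkit.io import ContinuousTrace

from conftest import make_trace

RATE = 20000.0


def _flat(duration_s=5.0, level=-60.0, rate=RATE):
    return make_trace(np.full(int(duration_s * rate), level), rate=rate)


def _add_triangle_spike(trace, t_apex, width_ms=2.0, peak=20.0):
    x = trace.samples.copy()
    half = int(trace.rate * width_ms / 2000.0)
    i = trace.index_at(t_apex)
    x[i - half:i + 1] = np.linspace(x[i - half], peak, half + 1)
    x[i:i + half + 1] = np.linspace(peak, x[i + half], half + 1)
    return trace.with_samples(x)


class TestDetectVmSpikes:
    def test_subthreshold_trace_has_none(self):
        assert len(vm.detect_vm_spikes(_flat())) == 0

    def test_single_transient_single_apex(self):
        trace = _add_triangle_spike(_flat(level=-55.0), 2.0)
        times = vm.detect_vm_spikes(trace)
        assert len(times) == 1
        assert times[0] == pytest.approx(2.0, abs=1e-4)

    def test_burst_of_three_counted(self):
        trace = _flat(level=-55.0)
        for k in range(3):
            trace = _add_triangle_spike(trace, 2.0 + 0.010 * k)
        assert len(vm.detect_vm_spikes(trace)) == 3


class TestTruncateSpikes:
    def test_spike_free_trace_unchanged(self, rng):
        x = -60.0 + 0.5 * rng.standard_normal(int(RATE))
        trace = make_trace(x, rate=RATE)
        out = vm.truncate_spikes(trace)
        np.testing.assert_array_equal(out.samples, x)

    def test_single_spike_flattened(self):
        trace = _add_triangle_spike(_flat(level=-55.0), 2.0)
        out = vm.truncate_spikes(trace)
        assert np.abs(out.samples - (-55.0)).max() < 0.5
        assert out.samples.max() <= vm.SPIKE_THRESHOLD_MV

    def test_complex_spike_doublet_removed(self):
        trace = _flat(level=-55.0)
        trace = _add_triangle_spike(trace, 2.0)
        trace = _add_triangle_spike(trace, 2.010)
        out = vm.truncate_spikes(trace)
        assert out.samples.max() <= vm.SPIKE_THRESHOLD_MV

    def test_idempotent(self, rng):
        x = -60.0 + 0.3 * rng.standard_normal(int(2 * RATE))
        trace = _add_triangle_spike(make_trace(x, rate=RATE), 1.0)
        once = vm.truncate_spikes(trace)
        twice = vm.truncate_spikes(once)
        np.testing.assert_allclose(twice.samples, once.samples)

    def test_unreturned_edge_truncates_to_end(self):
        x = np.full(int(RATE), -55.0)
        x[-200:] = np.linspace(-55.0, 10.0, 200)  # rises and never returns
        with pytest.warns(UserWarning, match="no return"):
            out = vm.truncate_spikes(make_trace(x, rate=RATE))
        assert out.samples.max() <= vm.SPIKE_THRESHOLD_MV


class TestDeltaVmPre:
    def test_constant_trace_gives_zero(self):
        assert vm.compute_delta_vm_pre(_flat(), 3.0) == pytest.approx(0.0)

    def test_shift_invariance(self, rng):
        x = -60.0 + rng.standard_normal(int(5 * RATE))
        trace = make_trace(x, rate=RATE)
        a = vm.compute_delta_vm_pre(trace, 3.0)
        b = vm.compute_delta_vm_pre(trace.with_samples(x + 11.3), 3.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_rectangular_dip_measured_exactly(self):
        trace = _flat()
        x = trace.samples.copy()
        onset = 3.0
        i0, i1 = trace.index_at(onset - 0.075), trace.index_at(onset + 0.025)
        x[i0:i1] -= 3.0
        assert vm.compute_delta_vm_pre(trace.with_samples(x), onset) == \
            pytest.approx(-3.0, rel=1e-3)

    def test_insufficient_coverage_raises(self):
        with pytest.raises(vm.InsufficientCoverage):
            vm.compute_delta_vm_pre(_flat(duration_s=1.0), 0.5)


class TestDepolPeak:
    def test_gaussian_bump_at_40ms(self):
        trace = _flat()
        onset = 3.0
        t = trace.times()
        x = trace.samples + 5.0 * np.exp(
            -0.5 * ((t - onset - 0.040) / 0.010) ** 2)
        assert vm.compute_depol_peak(trace.with_samples(x), onset) == \
            pytest.approx(40.0, abs=0.2)

    def test_rising_ramp_peaks_at_window_edge(self):
        trace = _flat()
        x = trace.samples + np.linspace(0, 10, trace.n)
        assert vm.compute_depol_peak(trace.with_samples(x), 3.0) == \
            pytest.approx(120.0, abs=0.1)

    def test_ties_broken_to_earliest(self):
        trace = _flat()
        x = trace.samples.copy()
        onset = 3.0
        for t_peak in (0.020, 0.060):
            x[trace.index_at(onset + t_peak)] += 5.0
        assert vm.compute_depol_peak(trace.with_samples(x), onset) == \
            pytest.approx(20.0, abs=0.1)


class TestTriggeredAverage:
    def test_single_event_is_identity(self):
        trace = _flat()
        out = vm.swr_triggered_average(trace, [2.0], window_s=(-0.1, 0.1))
        np.testing.assert_allclose(out.samples, -60.0)
        assert out.t0 == pytest.approx(-0.1)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        n_ev = 400
        rate = 1000.0
        x = rng.standard_normal(int(n_ev * 0.25 * rate))
        trace = make_trace(x, rate=rate)
        onsets = 0.1 + 0.25 * np.arange(n_ev - 1)
        out = vm.swr_triggered_average(trace, onsets, window_s=(-0.05, 0.05))
        # SD of the mean of ~400 standard normals is 1/20
        assert out.samples.std() == pytest.approx(1 / np.sqrt(n_ev), rel=0.3)


class TestConductance:
    def test_epsg_closed_form(self):
        current = make_trace(np.full(int(5 * RATE), -100.0), rate=RATE)
        x = current.samples.copy()
        x[current.index_at(3.0):] -= 700.0   # -700 pA above baseline
        rec = vm.compute_conductance(current.with_samples(x), -70.0, 0.0, 3.0)
        assert rec.g_ns.samples[-1] == pytest.approx(10.0)
        assert rec.g_ns.units == "nS"

    def test_ipsg_closed_form(self):
        current = make_trace(np.zeros(int(5 * RATE)), rate=RATE)
        x = current.samples.copy()
        x[current.index_at(3.0):] += 800.0
        rec = vm.compute_conductance(current.with_samples(x), 10.0, -90.0,
                                     3.0, kind="IPSG")
        assert rec.g_ns.samples[-1] == pytest.approx(8.0)

    def test_baseline_current_gives_zero(self):
        current = make_trace(np.full(int(5 * RATE), -55.0), rate=RATE)
        rec = vm.compute_conductance(current, -70.0, 0.0, 3.0)
        np.testing.assert_allclose(rec.g_ns.samples, 0.0, atol=1e-12)

    def test_equal_potentials_rejected(self):
        current = make_trace(np.zeros(int(5 * RATE)), rate=RATE)
        with pytest.raises(ValueError):
            vm.compute_conductance(current, -70.0, -70.0, 3.0)

    def test_linear_in_current(self):
        current = make_trace(np.zeros(int(5 * RATE)), rate=RATE)
        x = current.samples.copy()
        x[current.index_at(3.0):] = 350.0
        a = vm.compute_conductance(current.with_samples(x), -70.0, 0.0, 3.0)
        b = vm.compute_conductance(current.with_samples(2 * x), -70.0, 0.0, 3.0)
        np.testing.assert_allclose(b.g_ns.samples, 2 * a.g_ns.samples)


def _triplet_records(rng, n_swr=60, coupling=0.0):
    rows = []
    for s in range(n_swr):
        dvm = rng.normal(0.0, 2.0, 3)
        peak = 40.0 - coupling * dvm + rng.normal(0.0, 6.0, 3)
        for c in range(3):
            rows.append({"cell_id": f"c{c}", "swr_id": s,
                         "delta_vm_pre_mv": dvm[c],
                         "depol_peak_time_ms": peak[c]})
    return pd.DataFrame(rows)


class TestTripletOrderTest:
    def test_frequencies_sum_to_one(self, rng):
        res = vm.triplet_order_test(_triplet_records(rng), seed=0,
                                    n_perm=2000)
        assert res.table["freq"].sum() == pytest.approx(1.0)
        assert list(res.table["order"]) == ["123", "132", "213", "231",
                                            "312", "321"]

    def test_deterministic_band(self, rng):
        records = _triplet_records(rng)
        a = vm.triplet_order_test(records, seed=42, n_perm=2000)
        b = vm.triplet_order_test(records, seed=42, n_perm=2000)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_coupling_overrepresents_concordant_order(self, rng):
        """Deeper hyperpolarization -> later depolarization inflates the
        1-2-3 order above the permutation band."""
        records = _triplet_records(rng, coupling=8.0)
        res = vm.triplet_order_test(records, seed=1, n_perm=4000)
        t = res.table.set_index("order")
        assert t.loc["123", "flag"] == "high"

    def test_too_few_swrs_rejected(self, rng):
        with pytest.raises(ValueError):
            vm.triplet_order_test(_triplet_records(rng, n_swr=10), seed=0)


class TestPairwiseCorrelations:
    @staticmethod
    def _records(dvm_by_cell, peak_by_cell=None):
        rows = []
        for cell, series in dvm_by_cell.items():
            peaks = (peak_by_cell or {}).get(
                cell, np.full(len(series), 40.0) + np.arange(len(series)))
            for s, (d, p) in enumerate(zip(series, peaks)):
                rows.append({"cell_id": cell, "swr_id": s,
                             "delta_vm_pre_mv": d,
                             "depol_peak_time_ms": p})
        return pd.DataFrame(rows)

    def test_identical_series_give_unit_correlation(self, rng):
        x = rng.normal(0, 2, 50)
        res = vm.pairwise_vm_correlations(self._records({"a": x, "b": x}))
        assert res.pairs["r_dvm"].iloc[0] == pytest.approx(1.0)

    def test_independent_series_give_small_r(self, rng):
        res = vm.pairwise_vm_correlations(self._records(
            {"a": rng.normal(0, 2, 100), "b": rng.normal(0, 2, 100)}))
        assert abs(res.pairs["r_dvm"].iloc[0]) < 0.3

    def test_shared_source_recovered(self, rng):
        shared = rng.normal(0, 2, 100)
        records = self._records({
            "a": shared + rng.normal(0, 0.5, 100),
            "b": shared + rng.normal(0, 0.5, 100),
            "c": rng.normal(0, 2, 100)})
        res = vm.pairwise_vm_correlations(records)
        pair_ab = res.pairs.set_index(["cell_a", "cell_b"]).loc[("a", "b")]
        assert pair_ab["r_dvm"] > 0.8 and pair_ab["p_dvm"] < 1e-6

    def test_distance_correlation_reported(self, rng):
        shared = rng.normal(0, 2, 80)
        peaks = {c: rng.normal(40, 15, 80) for c in "abcd"}
        records = self._records({
            "a": shared + rng.normal(0, 0.5, 80),
            "b": shared + rng.normal(0, 0.5, 80),
            "c": rng.normal(0, 2, 80),
            "d": rng.normal(0, 2, 80)}, peak_by_cell=peaks)
        distances = {("a", "b"): 30.0, ("a", "c"): 300.0, ("a", "d"): 320.0,
                     ("b", "c"): 310.0, ("b", "d"): 330.0, ("c", "d"): 40.0}
        res = vm.pairwise_vm_correlations(records, distances_um=distances)
        assert res.dvm_vs_distance is not None
        assert np.isfinite(res.dvm_vs_peak[0])
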