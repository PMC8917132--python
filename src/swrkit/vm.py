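"""Intracellular membrane-potential (Vm) analysis around SWRs.

The pipeline for one patched pyramidal cell is:

1. detect spikes (peaks of supra-threshold excursions above -20 mV),
2. truncate spikes from the raw trace so subthreshold Vm can be averaged:
   a 1-ms moving average is taken, leading edges are detected where the
   rate of change exceeds 4 V/s, and each edge is linearly interpolated
   until the trace first falls back below the edge value,
3. per SWR, measure the pre-onset hyperpolarization dVm_pre (mean Vm in a
   +/-25 ms window around the Vm minimum within [-50, 0) ms, minus the
   baseline Vm averaged over [-2000, -1000) ms) and the depolarization
   peak time (Vm maximum within [-20, +120] ms),
4. summarize across cells: SWR-triggered averages, pairwise correlations
   of dVm_pre and of depolarization peak times, and a within-SWR rank
   permutation test on simultaneously recorded cell triplets.

Voltage-clamp currents are converted to synaptic conductances as
``g = (I - I_baseline) / (V_hold - E_rev)`` (pA / mV = nS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import ContinuousTrace

__all__ = [
    "SPIKE_THRESHOLD_MV",
    "detect_vm_spikes",
    "truncate_spikes",
    "compute_delta_vm_pre",
    "compute_depol_peak",
    "delta_vm_records",
    "swr_triggered_average",
    "ConductanceRecord",
    "compute_conductance",
    "TripletOrderResult",
    "triplet_order_test",
    "PairwiseVmResult",
    "pairwise_vm_correlations",
    "InsufficientCoverage",
]

SPIKE_THRESHOLD_MV = -20.0
EDGE_RATE_V_PER_S = 4.0

BASELINE_WINDOW_S = (-2.0, -1.0)      # baseline Vm relative to SWR onset
PRE_MIN_WINDOW_S = (-0.050, 0.0)      # search window for the pre-SWR minimum
PRE_AVG_HALF_S = 0.025                # +/- averaging half-window around it
DEPOL_WINDOW_S = (-0.020, 0.120)      # depolarization-peak search window


class InsufficientCoverage(ValueError):
    """The trace does not cover the analysis windows for this event."""


def detect_vm_spikes(vm: ContinuousTrace,
                     threshold_mv: float = SPIKE_THRESHOLD_MV) -> np.ndarray:
    """Spike times: one per local maximum of each supra-threshold excursion."""
    x = vm.samples
    mask = x > threshold_mv
    if not mask.any():
        return np.empty(0)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    apex = [s + int(np.argmax(x[s:e])) for s, e in zip(starts, stops)]
    return vm.t0 + np.asarray(apex) / vm.rate


def _smooth_1ms(vm: ContinuousTrace) -> np.ndarray:
    n = max(int(round(vm.rate * 0.001)), 1)
    return ndimage.uniform_filter1d(vm.samples, size=n, mode="nearest")


def truncate_spikes(vm: ContinuousTrace) -> ContinuousTrace:
    """Remove action potentials by linear interpolation from spike edges.

    Edges are the first samples at which the rate of change of the 1-ms
    smoothed trace exceeds 4 V/s; each edge is interpolated until the trace
    first drops back below the edge value.  Edges falling inside an already
    interpolated span (complex spikes) are absorbed by that span.  A final
    guard interpolates any residual excursion above -20 mV, so the output
    is guaranteed subthreshold.  The operation is idempotent: a spike-free
    trace passes through unchanged.
    """
    smoothed = _smooth_1ms(vm)
    dvdt = np.gradient(smoothed) * vm.rate / 1000.0  # mV/sample -> V/s
    edge_mask = dvdt > EDGE_RATE_V_PER_S
    if not edge_mask.any() and not (vm.samples > SPIKE_THRESHOLD_MV).any():
        return vm

    edges = np.flatnonzero(np.diff(np.r_[False, edge_mask].astype(np.int8)) == 1)
    work = vm.samples.copy()
    last_end = -1
    for e in edges:
        if e <= last_end:
            continue  # inside a span already interpolated (complex spike)
        last_end = _interpolate_from(work, int(e))

    # guard: any excursion above threshold that escaped edge detection
    for s, e in _suprathreshold_regions(work):
        anchor = max(s - 1, 0)
        _interpolate_from(work, anchor)
    return vm.with_samples(work)


def _interpolate_from(work: np.ndarray, e: int) -> int:
    """Interpolate from index ``e`` to the first later sample below work[e].

    Returns the end index of the interpolated span.  If the trace never
    returns below the edge value, holds the edge value to the end and
    warns.
    """
    v_edge = work[e]
    below = np.flatnonzero(work[e + 1:] < v_edge)
    if below.size == 0:
        warnings.warn("spike edge with no return below edge value; "
                      "truncated to trace end", stacklevel=2)
        work[e:] = v_edge
        return work.size - 1
    j = e + 1 + int(below[0])
    work[e:j + 1] = np.linspace(v_edge, work[j], j - e + 1)
    return j


def _suprathreshold_regions(x: np.ndarray):
    mask = x > SPIKE_THRESHOLD_MV
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _window_mean(vm: ContinuousTrace, t_lo: float, t_hi: float) -> float:
    i0, i1 = vm.index_at(t_lo), vm.index_at(t_hi)
    if i0 < 0 or i1 > vm.n or i1 <= i0:
        raise InsufficientCoverage(
            f"trace does not cover [{t_lo:.3f}, {t_hi:.3f}] s")
    return float(vm.samples[i0:i1].mean())


def compute_delta_vm_pre(vm_sub: ContinuousTrace, onset_s: float) -> float:
    """Pre-SWR Vm change for one event, in mV.

    ``vm_sub`` must be spike-truncated.  Finds the Vm minimum within
    [-50, 0) ms before onset, averages Vm over +/-25 ms around it (the
    window may extend past onset), and subtracts the baseline Vm averaged
    over [-2000, -1000) ms.  Negative values indicate hyperpolarization.
    Shift-invariant: adding a constant to the trace leaves it unchanged.
    """
    baseline = _window_mean(vm_sub, onset_s + BASELINE_WINDOW_S[0],
                            onset_s + BASELINE_WINDOW_S[1])
    i0 = vm_sub.index_at(onset_s + PRE_MIN_WINDOW_S[0])
    i1 = vm_sub.index_at(onset_s + PRE_MIN_WINDOW_S[1])
    if i0 < 0 or i1 > vm_sub.n or i1 <= i0:
        raise InsufficientCoverage("pre-onset window not covered")
    i_min = i0 + int(np.argmin(vm_sub.samples[i0:i1]))  # earliest on ties
    t_min = vm_sub.t0 + i_min / vm_sub.rate
    pre = _window_mean(vm_sub, t_min - PRE_AVG_HALF_S, t_min + PRE_AVG_HALF_S)
    return pre - baseline


def compute_depol_peak(vm_sub: ContinuousTrace, onset_s: float) -> float:
    """Time (ms, relative to onset) of the Vm maximum in [-20, +120] ms.

    Ties are broken toward the earliest time.  Invariant to adding a
    constant to the trace.
    """
    i0 = vm_sub.index_at(onset_s + DEPOL_WINDOW_S[0])
    i1 = vm_sub.index_at(onset_s + DEPOL_WINDOW_S[1]) + 1  # inclusive edge
    if i0 < 0 or i1 > vm_sub.n or i1 <= i0:
        raise InsufficientCoverage("depolarization window not covered")
    i_max = i0 + int(np.argmax(vm_sub.samples[i0:i1]))
    return (vm_sub.t0 + i_max / vm_sub.rate - onset_s) * 1000.0


def delta_vm_records(vm: ContinuousTrace, events: pd.DataFrame,
                     cell_id="cell0", truncate: bool = True
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(cell, SWR) records: baseline, dVm_pre, depolarization peak,
    first-spike time and within-SWR spike count.

    Events without full window coverage are skipped and reported in the
    second return value with a reason code.
    """
    spike_times = detect_vm_spikes(vm)
    vm_sub = truncate_spikes(vm) if truncate else vm

    rows, skipped = [], []
    for _, ev in events.iterrows():
        onset, offset = float(ev["onset_s"]), float(ev["offset_s"])
        try:
            baseline = _window_mean(vm_sub, onset + BASELINE_WINDOW_S[0],
                                    onset + BASELINE_WINDOW_S[1])
            dvm = compute_delta_vm_pre(vm_sub, onset)
            peak_ms = compute_depol_peak(vm_sub, onset)
        except InsufficientCoverage as exc:
            skipped.append({"event_id": ev["event_id"], "reason": str(exc)})
            continue
        in_swr = spike_times[(spike_times >= onset) & (spike_times <= offset)]
        rows.append({
            "cell_id": cell_id,
            "swr_id": ev["event_id"],
            "baseline_mv": baseline,
            "delta_vm_pre_mv": dvm,
            "depol_peak_time_ms": peak_ms,
            "first_spike_time_ms": (in_swr[0] - onset) * 1000.0
                                   if len(in_swr) else np.nan,
            "n_spikes_in_swr": len(in_swr),
        })
    return pd.DataFrame(rows), pd.DataFrame(skipped)


def swr_triggered_average(vm: ContinuousTrace, onsets,
                          window_s: tuple = (-0.5, 0.5)) -> ContinuousTrace:
    """Mean trace across events, aligned to onsets (t0 = window start).

    Events whose window is not fully covered are dropped; use
    :func:`swr_triggered_segments` when the contributing-event count is
    needed.
    """
    segs, _ = swr_triggered_segments(vm, onsets, window_s)
    if not len(segs):
        raise ValueError("no events with full window coverage")
    return ContinuousTrace(samples=segs.mean(axis=0), rate=vm.rate,
                           t0=window_s[0], units=vm.units)


def swr_triggered_segments(vm: ContinuousTrace, onsets,
                           window_s: tuple = (-0.5, 0.5)
                           ) -> tuple[np.ndarray, int]:
    """Stack of per-event segments (n_events x n_samples) and the count."""
    n_win = int(round((window_s[1] - window_s[0]) * vm.rate))
    rows = []
    for onset in np.atleast_1d(onsets):
        i0 = vm.index_at(onset + window_s[0])
        if i0 < 0 or i0 + n_win > vm.n:
            continue
        rows.append(vm.samples[i0:i0 + n_win])
    segs = np.asarray(rows) if rows else np.empty((0, n_win))
    return segs, len(rows)


@dataclass(frozen=True)
class ConductanceRecord:
    """Synaptic conductance time course for one SWR."""

    swr_id: object
    kind: str                  # "EPSG" or "IPSG"
    g_ns: ContinuousTrace
    hold_mv: float
    e_rev_mv: float


# default clamp configurations: EPSG at -70 mV vs E_rev 0 mV,
# IPSG at +10 mV vs E_rev -90 mV
CLAMP_DEFAULTS = {"EPSG": (-70.0, 0.0), "IPSG": (10.0, -90.0)}
CONDUCTANCE_WINDOW_S = (-2.0, 0.4)


def compute_conductance(current: ContinuousTrace, hold_mv: float,
                        e_rev_mv: float, onset_s: float,
                        swr_id=0, kind: str = "EPSG") -> ConductanceRecord:
    """Baseline-subtracted conductance g(t) = (I - I_base)/(V_h - E_rev).

    ``current`` is in pA, potentials in mV, so g comes out in nS.  The
    baseline current is the mean over [-2000, -1000) ms before onset; the
    returned trace covers [-2000, +400] ms.
    """
    if hold_mv == e_rev_mv:
        raise ValueError("holding potential must differ from reversal")
    baseline = _window_mean(current, onset_s + BASELINE_WINDOW_S[0],
                            onset_s + BASELINE_WINDOW_S[1])
    seg = current.slice(onset_s + CONDUCTANCE_WINDOW_S[0],
                        onset_s + CONDUCTANCE_WINDOW_S[1])
    g = (seg.samples - baseline) / (hold_mv - e_rev_mv)
    trace = ContinuousTrace(samples=g, rate=seg.rate,
                            t0=seg.t0 - onset_s, units="nS")
    return ConductanceRecord(swr_id=swr_id, kind=kind, g_ns=trace,
                             hold_mv=hold_mv, e_rev_mv=e_rev_mv)


# ---------------------------------------------------------------------------
# triplet rank-order permutation test

_PERMS3 = list(permutations(range(3)))  # 6 permutations of 3 cells

ORDER_LABELS = ["".join(str(i + 1) for i in p) for p in _PERMS3]


@dataclass(frozen=True)
class TripletOrderResult:
    """Observed order frequencies vs a within-SWR permutation null."""

    table: pd.DataFrame   # order, freq, lo, hi, flag
    n_swr: int
    n_perm: int


def _order_label_index(dvm_triplet: np.ndarray, pos: np.ndarray) -> int:
    """Label of the dVm order given peak-time positions ``pos`` (0=earliest).

    Cells are listed from largest (least hyperpolarized) to smallest
    dVm_pre, named by their depolarization-order position.  Stable argsort
    breaks dVm ties deterministically toward the earlier-depolarizing cell.
    """
    order = np.argsort(-dvm_triplet, kind="stable")
    return _PERMS3.index(tuple(pos[order]))


def triplet_order_test(records: pd.DataFrame, n_perm: int = 10_000,
                       seed=None, min_swr: int = 30) -> TripletOrderResult:
    """Within-SWR permutation test on a simultaneously recorded cell triplet.

    ``records`` is the long-format output of :func:`delta_vm_records` for
    exactly three cells.  For every SWR where all three cells were
    measured, cells are ranked by depolarization peak time (position
    1 = earliest); the order of their dVm_pre values (largest first) is one
    of six permutations.  Observed order frequencies are compared with a
    null in which dVm_pre values are randomly exchanged across cells within
    each SWR (``n_perm`` draws).

    Because six correlated frequencies are examined at once, the ``flag``
    column controls the familywise error: it marks frequencies outside a
    simultaneous (Bonferroni-adjusted, 0.05/6 per order, two-sided) band
    of the null.  The per-order 95% band — the gray zone one would draw in
    a figure — is also returned as ``lo95``/``hi95``.  All percentile
    bands use conservative discrete quantiles and equality counts as
    inside.
    """
    cells = sorted(records["cell_id"].unique())
    if len(cells) != 3:
        raise ValueError("triplet test needs records from exactly 3 cells")
    wide_dvm = records.pivot(index="swr_id", columns="cell_id",
                             values="delta_vm_pre_mv")[cells].dropna()
    wide_peak = records.pivot(index="swr_id", columns="cell_id",
                              values="depol_peak_time_ms")[cells]
    wide_peak = wide_peak.loc[wide_dvm.index]
    n_swr = len(wide_dvm)
    if n_swr < min_swr:
        raise ValueError(f"need >= {min_swr} SWRs with all 3 cells, "
                         f"got {n_swr}")

    dvm = wide_dvm.to_numpy()
    peak = wide_peak.to_numpy()
    # position of each cell in the depolarization order (0 = earliest)
    pos = np.empty_like(peak, dtype=int)
    for s in range(n_swr):
        pos[s, np.argsort(peak[s], kind="stable")] = np.arange(3)

    observed = np.array([_order_label_index(dvm[s], pos[s])
                         for s in range(n_swr)])
    # per-SWR label reached under each of the 6 within-SWR exchanges
    label_table = np.empty((n_swr, 6), dtype=int)
    for s in range(n_swr):
        for k, perm in enumerate(_PERMS3):
            label_table[s, k] = _order_label_index(dvm[s, list(perm)], pos[s])

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 6, size=(n_perm, n_swr))
    null_labels = label_table[np.arange(n_swr)[None, :], draws]
    null_freq = np.stack([(null_labels == k).mean(axis=1) for k in range(6)],
                         axis=1)  # n_perm x 6

    obs_freq = np.array([(observed == k).mean() for k in range(6)])
    alpha_sim = 100.0 * 0.025 / 6.0
    lo = np.percentile(null_freq, alpha_sim, axis=0, method="lower")
    hi = np.percentile(null_freq, 100.0 - alpha_sim, axis=0, method="higher")
    lo95 = np.percentile(null_freq, 2.5, axis=0, method="lower")
    hi95 = np.percentile(null_freq, 97.5, axis=0, method="higher")
    flag = np.where(obs_freq > hi, "high",
                    np.where(obs_freq < lo, "low", ""))
    table = pd.DataFrame({"order": ORDER_LABELS, "freq": obs_freq,
                          "lo": lo, "hi": hi, "lo95": lo95, "hi95": hi95,
                          "flag": flag})
    return TripletOrderResult(table=table, n_swr=n_swr, n_perm=n_perm)


# ---------------------------------------------------------------------------
# pairwise correlations across cells

@dataclass(frozen=True)
class PairwiseVmResult:
    pairs: pd.DataFrame                      # per-pair correlations
    dvm_vs_peak: tuple[float, float]         # (r, p) across pairs
    dvm_vs_distance: tuple[float, float] | None


def pairwise_vm_correlations(records: pd.DataFrame,
                             distances_um: dict | None = None,
                             min_shared: int = 10) -> PairwiseVmResult:
    """Pearson correlations of dVm_pre and depolarization peak times for
    every cell pair over shared SWRs, plus second-level correlations across
    pairs (r of dVm_pre vs r of peak time; r of dVm_pre vs pair distance).

    Significance is a two-sided t-test of the correlation coefficient, as
    returned by :func:`scipy.stats.pearsonr`.
    """
    cells = sorted(records["cell_id"].unique())
    wide_dvm = records.pivot(index="swr_id", columns="cell_id",
                             values="delta_vm_pre_mv")
    wide_peak = records.pivot(index="swr_id", columns="cell_id",
                              values="depol_peak_time_ms")
    rows = []
    for a, b in combinations(cells, 2):
        shared = wide_dvm[[a, b]].dropna()
        if len(shared) < min_shared:
            continue
        r_dvm, p_dvm = stats.pearsonr(shared[a], shared[b])
        peaks = wide_peak.loc[shared.index, [a, b]].dropna()
        r_peak, p_peak = stats.pearsonr(peaks[a], peaks[b])
        dist = np.nan
        if distances_um is not None:
            dist = distances_um.get((a, b), distances_um.get((b, a), np.nan))
        rows.append({"cell_a": a, "cell_b": b, "n_swr": len(shared),
                     "r_dvm": r_dvm, "p_dvm": p_dvm,
                     "r_peak": r_peak, "p_peak": p_peak,
                     "distance_um": dist})
    pairs = pd.DataFrame(rows)

    def _corr(x, y):
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return (np.nan, np.nan)
        return tuple(stats.pearsonr(x, y))

    dvm_vs_peak = (np.nan, np.nan)
    dvm_vs_dist = None
    if len(pairs) >= 3:
        dvm_vs_peak = _corr(pairs["r_dvm"], pairs["r_peak"])
        with_dist = pairs.dropna(subset=["distance_um"])
        if len(with_dist) >= 3:
            dvm_vs_dist = _corr(with_dist["r_dvm"], with_dist["distance_um"])
    return PairwiseVmResult(pairs=pairs, dvm_vs_peak=dvm_vs_peak,
                            dvm_vs_distance=dvm_vs_dist)
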