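"""Extracellular quintile/latency pipeline.

Identifies interneurons that fire before SWR onset (peri-event time
histograms, 2.5-ms bins), estimates each interneuron's pre-SWR rate from a
Gaussian-smoothed spike train (15 ms FWHM, averaged over the 30 ms before
onset), groups SWRs into quintiles of that rate (Q1 = highest), and tests
whether a paired pyramidal cell's first-spike latency differs between Q1
and Q5 against a null distribution built by shuffling latencies across
quintiles (500 shuffles, 95% band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .io import ContinuousTrace

__all__ = [
    "PETH",
    "compute_peth",
    "select_pre_swr_interneurons",
    "smoothed_rate",
    "pre_swr_rate",
    "pre_swr_rates",
    "assign_quintiles",
    "spike_latency_and_rank",
    "QuintileTestResult",
    "quintile_latency_test",
    "quintile_firing_rate",
    "swr_duration_by_quintile",
    "fwhm_to_sigma",
]

N_QUINTILES = 5
PRE_WINDOW_S = 0.030
FWHM_MS = 15.0
MIN_SPIKES_PER_CELL = 10


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PETH:
    """Peri-event time histogram for one cell around SWR onsets."""

    cell_id: object
    bin_edges_ms: np.ndarray
    rate_hz: np.ndarray
    peak_time_ms: float          # NaN when the histogram is empty
    n_events: int

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def compute_peth(spike_times, onsets, window_ms=(-200.0, 200.0),
                 bin_ms: float = 2.5, cell_id=None) -> PETH:
    """Event-aligned histogram, normalized to Hz by n_events * bin width."""
    spike_times = np.asarray(spike_times, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    for onset in onsets:
        rel_ms = (spike_times - onset) * 1000.0
        counts += np.histogram(rel_ms, bins=edges)[0]
    rate = counts / (len(onsets) * bin_ms / 1000.0)
    if counts.sum() == 0:
        peak = np.nan
    else:
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = float(centers[np.argmax(rate)])
    return PETH(cell_id=cell_id, bin_edges_ms=edges, rate_hz=rate,
                peak_time_ms=peak, n_events=len(onsets))


def select_pre_swr_interneurons(peak_times_ms: pd.Series,
                                criterion_sd: float = 1.5,
                                top_k: int | None = None) -> list:
    """Interneurons whose PETH peak precedes the population mean peak time
    by more than ``criterion_sd`` standard deviations.

    ``peak_times_ms`` maps interneuron id -> PETH peak time (ms).  With
    ``top_k``, the result is intersected with the k most negative peaks.
    A zero spread across cells selects nothing.
    """
    s = pd.Series(peak_times_ms).dropna()
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return []
    cutoff = s.mean() - criterion_sd * sd
    selected = s[s < cutoff]
    if top_k is not None:
        most_negative = set(s.nsmallest(top_k).index)
        selected = selected[selected.index.isin(most_negative)]
    return list(selected.index)


def smoothed_rate(spike_times, fwhm_ms: float = FWHM_MS, dt_ms: float = 1.0,
                  t_start: float | None = None,
                  t_stop: float | None = None) -> ContinuousTrace:
    """Gaussian-kernel firing-rate estimate on a regular grid, in Hz.

    The kernel integrates to one spike, so the integral of the rate over
    time equals the spike count (up to edge truncation).
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    sigma_ms = fwhm_to_sigma(fwhm_ms)
    pad_s = 5.0 * sigma_ms / 1000.0
    if t_start is None:
        t_start = (spike_times[0] if spike_times.size else 0.0) - pad_s
    if t_stop is None:
        t_stop = (spike_times[-1] if spike_times.size else 1.0) + pad_s
    dt_s = dt_ms / 1000.0
    n = int(np.ceil((t_stop - t_start) / dt_s))
    counts = np.histogram(spike_times, bins=n, range=(t_start, t_start + n * dt_s))[0]
    smoothed = ndimage.gaussian_filter1d(counts.astype(float),
                                         sigma=sigma_ms / dt_ms,
                                         mode="constant")
    return ContinuousTrace(samples=smoothed / dt_s, rate=1.0 / dt_s,
                           t0=t_start, units="Hz")


def pre_swr_rate(rate_trace: ContinuousTrace, onset_s: float,
                 window_ms: float = 30.0) -> float:
    """Mean of a smoothed rate trace over [onset - window, onset)."""
    i1 = rate_trace.index_at(onset_s)
    i0 = rate_trace.index_at(onset_s - window_ms / 1000.0)
    if i0 < 0 or i1 > rate_trace.n or i1 <= i0:
        raise ValueError("pre-SWR window not covered by the rate trace")
    return float(rate_trace.samples[i0:i1].mean())


def pre_swr_rates(spike_times, onsets, fwhm_ms: float = FWHM_MS,
                  window_ms: float = 30.0) -> np.ndarray:
    """Exact pre-SWR rates from the Gaussian-kernel estimate.

    Closed form: the window mean of a sum of unit-mass Gaussians is the
    summed Gaussian probability mass in the window divided by the window
    length.  Matches the grid-based :func:`pre_swr_rate` up to
    discretization.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    sigma_s = fwhm_to_sigma(fwhm_ms) / 1000.0
    w_s = window_ms / 1000.0
    out = np.empty(onsets.size)
    for k, onset in enumerate(onsets):
        a, b = onset - w_s, onset
        mass = ndtr((b - spike_times) / sigma_s) - ndtr((a - spike_times) / sigma_s)
        out[k] = mass.sum() / w_s
    return out


def assign_quintiles(pre_rates) -> np.ndarray:
    """Quintile label per SWR: 1 = highest pre-SWR rate, 5 = lowest.

    Ties are broken by a stable sort on (rate, SWR index), group sizes
    differ by at most one, and every SWR receives exactly one label.
    """
    rates = np.asarray(pre_rates, dtype=float)
    if rates.size < N_QUINTILES:
        raise ValueError(f"need >= {N_QUINTILES} SWRs to form quintiles")
    order = np.argsort(-rates, kind="stable")
    labels = np.empty(rates.size, dtype=int)
    for q, chunk in enumerate(np.array_split(order, N_QUINTILES), start=1):
        labels[chunk] = q
    return labels


def spike_latency_and_rank(pyr_spikes: pd.DataFrame,
                           swr_events: pd.DataFrame) -> pd.DataFrame:
    """First-spike latency and rank order per (pyramidal cell, SWR).

    Latency is the time from SWR onset to the cell's first spike inside
    [onset, offset], in ms.  Rank is the cell's normalized position among
    all pyramidal cells participating in that SWR: (position - 1)/(n - 1),
    NaN when the cell is the only participant.  Rows exist only for SWRs
    in which the cell fired.
    """
    pyr = pyr_spikes[pyr_spikes["cell_class"] == "pyr"]
    rows = []
    for _, ev in swr_events.iterrows():
        onset, offset = float(ev["onset_s"]), float(ev["offset_s"])
        in_ev = pyr[(pyr["spike_time_s"] >= onset) &
                    (pyr["spike_time_s"] <= offset)]
        if not len(in_ev):
            continue
        first = in_ev.groupby("cell_id")["spike_time_s"].min().sort_values(
            kind="stable")
        n_part = len(first)
        for position, (cell, t_first) in enumerate(first.items()):
            rank = position / (n_part - 1) if n_part > 1 else np.nan
            rows.append({"cell_id": cell, "swr_id": ev["event_id"],
                         "latency_ms": (t_first - onset) * 1000.0,
                         "rank": rank, "n_participants": n_part})
    return pd.DataFrame(rows,
                        columns=["cell_id", "swr_id", "latency_ms",
                                 "rank", "n_participants"])


@dataclass(frozen=True)
class QuintileTestResult:
    delta_ms: float              # observed mean(Q1) - mean(Q5) latency
    null: np.ndarray             # shuffled deltas
    lo: float
    hi: float
    significant: bool
    p_two_sided: float


def quintile_latency_test(latencies_ms, quintiles, n_shuffle: int = 500,
                          seed=None) -> QuintileTestResult:
    """Shuffle test for a Q1-vs-Q5 first-spike latency difference.

    ``latencies_ms`` holds one value per SWR (NaN where the cell did not
    fire); ``quintiles`` the matching labels from
    :func:`assign_quintiles`.  The observed statistic is
    mean(Q1) - mean(Q5); the null shuffles latencies across quintile
    labels (group sizes preserved) ``n_shuffle`` times.  Significant when
    the observed value falls outside the conservative 2.5-97.5 percentile
    band of the null.
    """
    lat = np.asarray(latencies_ms, dtype=float)
    q = np.asarray(quintiles, dtype=int)
    if lat.shape != q.shape:
        raise ValueError("latencies and quintile labels must align")
    m1, m5 = q == 1, q == N_QUINTILES
    if not (np.isfinite(lat[m1]).any() and np.isfinite(lat[m5]).any()):
        raise ValueError("both Q1 and Q5 need at least one latency")
    delta = float(np.nanmean(lat[m1]) - np.nanmean(lat[m5]))

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_shuffle, lat.size)), axis=1)
    shuffled = lat[idx]                       # n_shuffle x n_swr
    with np.errstate(invalid="ignore"):
        null = (np.nanmean(shuffled[:, m1], axis=1) -
                np.nanmean(shuffled[:, m5], axis=1))
    null = null[np.isfinite(null)]
    lo = float(np.percentile(null, 2.5, method="lower"))
    hi = float(np.percentile(null, 97.5, method="higher"))
    n = null.size
    p = 2.0 * min((1 + np.sum(null <= delta)) / (n + 1),
                  (1 + np.sum(null >= delta)) / (n + 1))
    return QuintileTestResult(delta_ms=delta, null=null, lo=lo, hi=hi,
                              significant=bool(delta < lo or delta > hi),
                              p_two_sided=float(min(p, 1.0)))


def quintile_firing_rate(pyr_spikes: pd.DataFrame, quintiles,
                         swr_events: pd.DataFrame,
                         cell_id=None) -> pd.Series:
    """Mean within-SWR firing rate (Hz) per quintile for one cell."""
    pyr = pyr_spikes[pyr_spikes["cell_class"] == "pyr"]
    if cell_id is not None:
        pyr = pyr[pyr["cell_id"] == cell_id]
    t = pyr["spike_time_s"].to_numpy()
    q = np.asarray(quintiles, dtype=int)
    rates = {lab: [] for lab in range(1, N_QUINTILES + 1)}
    for (_, ev), lab in zip(swr_events.iterrows(), q):
        onset, offset = float(ev["onset_s"]), float(ev["offset_s"])
        dur = offset - onset
        n = int(np.sum((t >= onset) & (t <= offset)))
        rates[lab].append(n / dur if dur > 0 else 0.0)
    return pd.Series({lab: (np.mean(v) if v else 0.0)
                      for lab, v in rates.items()}, name="rate_hz")


def swr_duration_by_quintile(quintiles, swr_events: pd.DataFrame) -> pd.Series:
    """Mean SWR duration (s) per quintile; NaN flags an empty quintile."""
    dur = (swr_events["offset_s"] - swr_events["onset_s"]).to_numpy()
    q = np.asarray(quintiles, dtype=int)
    out = {}
    for lab in range(1, N_QUINTILES + 1):
        sel = dur[q == lab]
        out[lab] = float(sel.mean()) if sel.size else np.nan
    return pd.Series(out, name="duration_s")
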