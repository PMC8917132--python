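"""Seeded synthetic-data generators for every pipeline input.

The in vivo recordings these analyses were designed for are not bundled
with the package, so each stage is exercised on generated data whose
ground truth is known by construction:

* ``gen_lfp`` — noise with Hanning-enveloped ripple-band bursts at known
  times (substrate for the detectors),
* ``gen_vm`` — membrane potential with a controlled pre-onset
  hyperpolarizing dip per SWR and a depolarization whose peak time is
  linearly coupled to the dip (the hyperpolarization/timing structure the
  intracellular analyses measure), plus threshold spikes,
* ``gen_unit_spikes`` — interneuron trains with variable pre-SWR rate
  bursts and pyramidal trains whose first-spike latency depends on the
  paired interneuron's pre-rate (the quintile analysis structure),
* ``gen_hmm_counts`` / ``gen_mixture_counts`` — exact generative twins of
  the Poisson HMM and Poisson mixture models.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import PoissonHMMParams
from .io import ContinuousTrace, make_event_table, validate_spikes
from .mixture import PoissonMixtureParams

__all__ = [
    "gen_lfp",
    "VmGenConfig",
    "gen_vm",
    "UnitGenConfig",
    "gen_unit_spikes",
    "gen_hmm_counts",
    "gen_mixture_counts",
]


def gen_lfp(n_swr: int, burst_freq_hz: float = 150.0,
            burst_dur_ms=(60.0, 120.0), burst_snr: float = 10.0,
            noise_sd: float = 1.0, rate_hz: float = 1250.0, seed=None,
            min_gap_s: float = 0.5, pad_s: float = 1.0
            ) -> tuple[ContinuousTrace, pd.DataFrame]:
    """White-noise LFP with ripple-band bursts at known ground-truth times.

    Bursts are Hanning-enveloped sinusoids at ``burst_freq_hz`` (must lie
    in the 100-250 Hz ripple band) with durations drawn uniformly from
    ``burst_dur_ms`` (scalar or (lo, hi), within 20-200 ms) and peak
    amplitude ``burst_snr`` times the noise SD.  Inter-burst gaps are at
    least ``min_gap_s``.  Returns the trace and the ground-truth event
    table (onset = envelope start, peak = envelope center).
    """
    if not (100.0 <= burst_freq_hz <= 250.0):
        raise ValueError("burst_freq_hz must lie in the 100-250 Hz band")
    durs = np.atleast_1d(np.asarray(burst_dur_ms, dtype=float))
    if durs.min() < 20.0 or durs.max() > 200.0:
        raise ValueError("burst durations must lie within 20-200 ms")
    rng = np.random.default_rng(seed)

    if n_swr > 0:
        dur_s = (rng.uniform(durs[0], durs[-1], size=n_swr)
                 if durs.size > 1 else np.full(n_swr, durs[0])) / 1000.0
        gaps = min_gap_s + rng.exponential(0.25, size=n_swr)
        onsets = pad_s + np.cumsum(gaps) + np.r_[0.0, np.cumsum(dur_s[:-1])]
        total_s = onsets[-1] + dur_s[-1] + pad_s
    else:
        dur_s = np.empty(0)
        onsets = np.empty(0)
        total_s = 10.0

    n = int(np.ceil(total_s * rate_hz))
    samples = rng.normal(0.0, noise_sd, size=n)
    amp = burst_snr * noise_sd
    for onset, dur in zip(onsets, dur_s):
        i0 = int(round(onset * rate_hz))
        nb = int(round(dur * rate_hz))
        t = np.arange(nb) / rate_hz
        phase = rng.uniform(0, 2 * np.pi)
        samples[i0:i0 + nb] += (amp * np.hanning(nb) *
                                np.sin(2 * np.pi * burst_freq_hz * t + phase))
    trace = ContinuousTrace(samples=samples, rate=rate_hz, units="au")
    events = make_event_table(onsets, onsets + dur_s / 2, onsets + dur_s)
    return trace, events


@dataclass(frozen=True)
class VmGenConfig:
    """Membrane-potential generator settings.

    Per SWR, a hyperpolarizing dip of depth ~ N(hyper_depth_mean,
    hyper_depth_sd^2) mV is placed just before onset, and a depolarizing
    transient peaks at ``depol_base_ms + coupling_ms_per_mv * dVm_pre``
    (so a negative coupling makes deeper hyperpolarizations produce later
    peaks, the sign convention of the measured correlations).  "Depth" is
    defined as the mean of the dip over the +/-25 ms averaging window, so
    the expected measured dVm_pre is exactly -depth for both dip shapes.
    """

    n_swr: int = 200
    baseline_mv: float = -60.0
    hyper_depth_mean_mv: float = 2.0
    hyper_depth_sd_mv: float = 0.7
    coupling_ms_per_mv: float = -10.0
    depol_amp_mv: float = 8.0
    depol_base_ms: float = 40.0
    depol_sigma_ms: float = 12.0
    peak_jitter_ms: float = 4.0
    noise_sd_mv: float = 0.2
    spike_threshold_mv: float = -50.0
    dip_shape: str = "raised_cosine"      # or "rect"
    dip_center_ms: float = -25.0
    rate_hz: float = 20_000.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_swr < 1:
            raise ValueError("n_swr must be >= 1")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if self.dip_shape not in ("raised_cosine", "rect"):
            raise ValueError("dip_shape must be 'raised_cosine' or 'rect'")


SPIKE_PEAK_MV = 20.0
SPIKE_WIDTH_MS = 2.0
DIP_HALF_MS = 25.0
MIN_ONSET_SPACING_S = 4.0


def gen_vm(cfg: VmGenConfig, swr_onsets) -> tuple[ContinuousTrace, pd.DataFrame]:
    """Vm trace with per-SWR dips, coupled depolarizations and spikes.

    ``swr_onsets`` must be spaced >= 4 s apart so every event has a clean
    [-2000, -1000) ms baseline window.  Returns the trace and a
    ground-truth table (per SWR: dip depth, expected dVm_pre, true
    depolarization peak time).
    """
    onsets = np.sort(np.atleast_1d(np.asarray(swr_onsets, dtype=float)))
    if onsets.size < 1:
        raise ValueError("need at least one SWR onset")
    if onsets.size > 1 and np.diff(onsets).min() < MIN_ONSET_SPACING_S:
        raise ValueError("SWR onsets must be >= 4 s apart")
    if onsets[0] < 2.5:
        raise ValueError("first onset needs >= 2.5 s of pre-onset baseline")
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate_hz
    n = int(np.ceil((onsets[-1] + 1.0) * rate))
    vm = np.full(n, cfg.baseline_mv)
    if cfg.noise_sd_mv > 0:
        vm += rng.normal(0.0, cfg.noise_sd_mv, size=n)
    t = np.arange(n) / rate

    depths = cfg.hyper_depth_mean_mv + \
        cfg.hyper_depth_sd_mv * rng.standard_normal(onsets.size)
    depths = np.maximum(depths, 0.0)
    jitter = cfg.peak_jitter_ms * rng.standard_normal(onsets.size)

    rows = []
    half_s = DIP_HALF_MS / 1000.0
    for k, onset in enumerate(onsets):
        depth = depths[k]
        center = onset + cfg.dip_center_ms / 1000.0
        if cfg.dip_shape == "raised_cosine":
            # trough 2*depth so the +/-25 ms window mean equals depth
            sel = (t >= center - half_s) & (t < center + half_s)
            vm[sel] -= depth * (1.0 + np.cos(np.pi * (t[sel] - center) / half_s))
        else:
            # flat dip spanning [-75, +25] ms: covers any +/-25 ms window
            sel = (t >= onset - 0.075) & (t < onset + 0.025)
            vm[sel] -= depth

        dvm_pre = -depth
        peak_ms = cfg.depol_base_ms + cfg.coupling_ms_per_mv * dvm_pre \
            + jitter[k]
        peak_ms = float(np.clip(peak_ms, -15.0, 115.0))
        sigma_s = cfg.depol_sigma_ms / 1000.0
        t_peak = onset + peak_ms / 1000.0
        sel = (t >= t_peak - 5 * sigma_s) & (t < t_peak + 5 * sigma_s)
        vm[sel] += cfg.depol_amp_mv * np.exp(
            -0.5 * ((t[sel] - t_peak) / sigma_s) ** 2)
        rows.append({"swr_id": k, "onset_s": onset, "dip_depth_mv": depth,
                     "expected_dvm_pre_mv": dvm_pre,
                     "true_peak_time_ms": peak_ms})

    _emit_spikes(vm, rate, cfg.spike_threshold_mv)
    trace = ContinuousTrace(samples=vm, rate=rate, units="mV")
    return trace, pd.DataFrame(rows)


def _emit_spikes(vm: np.ndarray, rate: float, threshold_mv: float) -> None:
    """Replace each threshold crossing with a 2-ms triangular spike to
    +20 mV (exercises the -20 mV detector and 4 V/s edge logic)."""
    above = vm > threshold_mv
    if not above.any():
        return
    starts = np.flatnonzero(np.diff(np.r_[False, above].astype(np.int8)) == 1)
    half = max(int(round(rate * SPIKE_WIDTH_MS / 2000.0)), 1)
    for s in starts:
        apex = min(s + half, vm.size - 1)
        end = min(s + 2 * half, vm.size - 1)
        vm[s:apex + 1] = np.linspace(vm[s], SPIKE_PEAK_MV, apex - s + 1)
        if end > apex:
            vm[apex:end + 1] = np.linspace(SPIKE_PEAK_MV, vm[end], end - apex + 1)


@dataclass(frozen=True)
class UnitGenConfig:
    """Extracellular spike-train generator settings.

    Each interneuron fires a Poisson burst in the 30 ms before each SWR
    with a per-SWR rate drawn from a Gamma distribution (mean
    ``int_pre_rate_mean_hz``, coefficient of variation
    ``int_pre_rate_cv``); pyramidal cell ``j`` is paired with interneuron
    ``j % n_int`` and fires its first within-SWR spike at
    ``base_latency_ms + latency_slope_ms_per_hz * pre_rate + jitter``.
    """

    n_int: int = 1
    n_pyr: int = 5
    n_swr: int = 300
    int_pre_rate_mean_hz: float = 60.0
    int_pre_rate_cv: float = 0.5
    latency_slope_ms_per_hz: float = 0.0
    base_latency_ms: float = 25.0
    latency_jitter_sd_ms: float = 10.0
    within_swr_rate_hz: float = 60.0
    int_baseline_rate_hz: float = 3.0
    pyr_baseline_rate_hz: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        for name in ("int_pre_rate_mean_hz", "within_swr_rate_hz",
                     "int_baseline_rate_hz", "pyr_baseline_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_swr < 5:
            raise ValueError("n_swr must be >= 5 (quintiles need >= 5 events)")


def gen_unit_spikes(cfg: UnitGenConfig, swr_events: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike table for interneurons and pyramidal cells around SWRs.

    Returns ``(spikes, truth)`` where ``truth`` holds the per-(interneuron,
    SWR) ground-truth pre-SWR burst rate.  Deterministic per (cfg, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    onsets = swr_events["onset_s"].to_numpy()
    offsets = swr_events["offset_s"].to_numpy()
    t_end = float(offsets[-1] + 1.0)
    rows = []
    truth = []

    shape = 1.0 / max(cfg.int_pre_rate_cv, 1e-6) ** 2
    scale = cfg.int_pre_rate_mean_hz / shape
    pre_rates = rng.gamma(shape, scale, size=(cfg.n_int, len(onsets)))

    for i in range(cfg.n_int):
        cell = f"int{i:03d}"
        times = list(_poisson_times(rng, cfg.int_baseline_rate_hz, 0.0, t_end))
        for k, onset in enumerate(onsets):
            r = pre_rates[i, k]
            n_burst = rng.poisson(r * 0.030)
            times.extend(onset - 0.030 + 0.030 * rng.random(n_burst))
            truth.append({"cell_id": cell, "swr_id":
                          swr_events["event_id"].iloc[k],
                          "pre_rate_hz": r})
        for tt in sorted(times):
            rows.append((cell, "int", tt))

    for j in range(cfg.n_pyr):
        cell = f"pyr{j:03d}"
        paired = pre_rates[j % cfg.n_int]
        times = list(_poisson_times(rng, cfg.pyr_baseline_rate_hz, 0.0, t_end))
        for k, (onset, offset) in enumerate(zip(onsets, offsets)):
            lat_ms = (cfg.base_latency_ms +
                      cfg.latency_slope_ms_per_hz * paired[k] +
                      cfg.latency_jitter_sd_ms * rng.standard_normal())
            first = onset + max(lat_ms, 0.5) / 1000.0
            if first <= offset:
                times.append(first)
                remaining = offset - first
                n_extra = rng.poisson(cfg.within_swr_rate_hz * remaining)
                times.extend(first + remaining * rng.random(n_extra))
        for tt in sorted(times):
            rows.append((cell, "pyr", tt))

    spikes = pd.DataFrame(rows, columns=["cell_id", "cell_class",
                                         "spike_time_s"])
    spikes = spikes.sort_values(["cell_id", "spike_time_s"],
                                kind="stable").reset_index(drop=True)
    validate_spikes(spikes)
    return spikes, pd.DataFrame(truth)


def _poisson_times(rng, rate_hz, t0, t1):
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(t0 + (t1 - t0) * rng.random(n))


def gen_hmm_counts(n_cells: int, M: int, T_per_seq, n_seq: int,
                   param_ranges: dict | None = None, seed=None
                   ) -> tuple[list, PoissonHMMParams, list]:
    """Count sequences sampled exactly from the Poisson HMM.

    ``T_per_seq`` is an int or an inclusive (lo, hi) range of sequence
    lengths.  ``param_ranges`` may override ``lam_range`` (uniform sampling
    range for expected counts) and ``self_bias`` (extra probability mass
    on self-transitions).  Returns (sequences, true params, state paths).
    """
    ranges = {"lam_range": (0.2, 8.0), "self_bias": 0.3}
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)
    lam = rng.uniform(*ranges["lam_range"], size=(n_cells, M))
    A = rng.dirichlet(np.ones(M), size=M)
    A = (1 - ranges["self_bias"]) * A + ranges["self_bias"] * np.eye(M)
    A = A / A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(M))
    params = PoissonHMMParams(pi=pi, A=A, lam=lam)

    if np.isscalar(T_per_seq):
        lengths = np.full(n_seq, int(T_per_seq))
    else:
        lengths = rng.integers(T_per_seq[0], T_per_seq[1] + 1, size=n_seq)
    sequences, paths = [], []
    for T in lengths:
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(M, p=pi)
        for tt in range(1, T):
            states[tt] = rng.choice(M, p=A[states[tt - 1]])
        counts = rng.poisson(lam[:, states].T)
        sequences.append(counts)
        paths.append(states)
    return sequences, params, paths


def gen_mixture_counts(n_int: int, M: int, n_swr: int, pi=None, lam=None,
                       seed=None
                       ) -> tuple[np.ndarray, np.ndarray, PoissonMixtureParams]:
    """SWR x interneuron count matrix from the Poisson mixture.

    By default, ensemble ``j`` drives interneurons with index ``n % M == j``
    at a high rate (8 counts/SWR) and the rest at a low rate (0.75), giving
    well-separated ensembles (rate ratio > 10).  Returns (counts, labels,
    true params).
    """
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = np.full(M, 1.0 / M)
    pi = np.asarray(pi, dtype=float)
    if lam is None:
        lam = np.full((n_int, M), 0.75)
        for j in range(M):
            lam[np.arange(n_int) % M == j, j] = 8.0
    lam = np.asarray(lam, dtype=float)
    params = PoissonMixtureParams(pi=pi, lam=lam)
    labels = rng.choice(M, size=n_swr, p=pi)
    counts = rng.poisson(lam[:, labels].T)
    return counts, labels, params
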