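"""Sharp-wave-ripple (SWR) detection from LFP traces.

Two detectors are provided, matching the two recording pathways they are
used on:

``detect_swr_patch``
    For tungsten-electrode LFP recorded alongside patch clamp.  The trace is
    band-passed 100-250 Hz, the rectified envelope is smoothed, and events
    are taken where the envelope exceeds ``threshold_sd`` robust standard
    deviations of the baseline noise.  The noise SD is estimated robustly
    (MAD * 1.4826) and re-estimated once with detected events excluded, so
    the threshold is insensitive to the events themselves.

``detect_swr_probe``
    For silicon-probe LFP.  The signal is brought to 1250 Hz, band-passed
    130-200 Hz with a fourth-order Chebyshev filter, squared, smoothed and
    z-scored; peaks are thresholded at ``peak_sd`` SDs above the mean and
    event boundaries at ``edge_sd`` crossings; durations outside
    [20, 200] ms are discarded, and events co-detected on an optional noise
    channel are treated as artifacts and removed.

Both detectors threshold in SD units, so detection is invariant to overall
amplitude scaling of the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ContinuousTrace, make_event_table, validate_events
from .signal import bandpass, downsample

__all__ = [
    "detect_swr_patch",
    "detect_swr_probe",
    "QCRules",
    "swr_qc",
    "require_min_events",
]

log = logging.getLogger(__name__)

MERGE_GAP_S = 0.030          # events closer than this are merged
MIN_TRACE_DURATION_S = 5.0   # needed for a stable noise estimate


def _smooth(x: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    n = max(int(round(window_s * rate)), 1)
    return ndimage.uniform_filter1d(x, size=n, mode="nearest")


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _regions_above(mask: np.ndarray):
    """Start/stop index pairs (half-open) of True runs in a boolean mask."""
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


def _merge_regions(regions, rate: float, gap_s: float = MERGE_GAP_S):
    if not regions:
        return []
    gap_n = int(round(gap_s * rate))
    merged = [list(regions[0])]
    for start, stop in regions[1:]:
        if start - merged[-1][1] < gap_n:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [tuple(r) for r in merged]


def detect_swr_patch(lfp: ContinuousTrace, threshold_sd: float = 3.0,
                     band: tuple = (100.0, 250.0),
                     smooth_s: float = 0.008) -> pd.DataFrame:
    """Envelope-threshold SWR detector for patch-session LFP.

    Returns an event table with onset/peak/offset in seconds and
    ``peak_s`` at the envelope maximum.  ``peak_power`` is not part of the
    event schema; the detection statistic is available via the probe
    detector when needed.
    """
    if lfp.duration < MIN_TRACE_DURATION_S:
        raise ValueError(
            f"trace of {lfp.duration:.2f} s is too short; "
            f"need >= {MIN_TRACE_DURATION_S} s for noise estimation")
    filtered = bandpass(lfp, band[0], band[1]).samples
    env = _smooth(np.abs(filtered), lfp.rate, smooth_s)

    sd = _robust_sd(filtered)
    regions = _find_patch_events(env, sd, threshold_sd, lfp.rate)
    # one re-estimation of the noise SD with detected events excluded
    if regions:
        keep = np.ones(filtered.size, dtype=bool)
        for start, stop in regions:
            keep[start:stop] = False
        if keep.sum() > int(lfp.rate):
            sd = _robust_sd(filtered[keep])
            regions = _find_patch_events(env, sd, threshold_sd, lfp.rate)

    return _regions_to_events(regions, env, lfp)


def _find_patch_events(env, sd, threshold_sd, rate):
    thr = threshold_sd * sd
    regions = _regions_above(env > thr)
    return _merge_regions(regions, rate)


def _regions_to_events(regions, stat, lfp: ContinuousTrace) -> pd.DataFrame:
    onsets, peaks, offsets = [], [], []
    for start, stop in regions:
        onsets.append(lfp.t0 + start / lfp.rate)
        offsets.append(lfp.t0 + stop / lfp.rate)
        peaks.append(lfp.t0 + (start + int(np.argmax(stat[start:stop]))) / lfp.rate)
    return make_event_table(onsets, peaks, offsets)


PROBE_RATE_HZ = 1250.0
PROBE_BAND = (130.0, 200.0)


def _probe_zscore(lfp: ContinuousTrace, smooth_s: float, peak_sd: float,
                  edge_sd: float) -> ContinuousTrace:
    """Smoothed squared ripple-band signal, z-scored against baseline.

    The mean/SD are re-estimated with detected events (edge-to-edge spans
    around peaks reaching ``peak_sd``) excluded, iterated to a fixed
    point, so the normalization reflects baseline noise rather than the
    events themselves — the same rationale as the patch detector's noise
    estimate.  Sub-peak noise excursions stay in the baseline, keeping the
    SD estimate unbiased.
    """
    if lfp.rate > PROBE_RATE_HZ:
        lfp = downsample(lfp, PROBE_RATE_HZ)
    filtered = bandpass(lfp, PROBE_BAND[0], PROBE_BAND[1], order=4).samples
    sq = _smooth(filtered ** 2, lfp.rate, smooth_s)
    keep = np.ones(sq.size, dtype=bool)
    z = (sq - sq.mean()) / sq.std()
    for _ in range(5):
        new_keep = np.ones(sq.size, dtype=bool)
        for start, stop in _regions_above(z > edge_sd):
            if z[start:stop].max() >= peak_sd:
                new_keep[start:stop] = False
        if new_keep.sum() <= int(lfp.rate) or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        z = (sq - sq[keep].mean()) / sq[keep].std()
    return lfp.with_samples(z)


def detect_swr_probe(lfp: ContinuousTrace, peak_sd: float = 5.0,
                     edge_sd: float = 2.0,
                     dur_s: tuple = (0.020, 0.200),
                     noise_channel: ContinuousTrace | None = None,
                     smooth_s: float = 0.008) -> pd.DataFrame:
    """Normalized-squared-signal SWR detector for silicon-probe LFP.

    Peaks are required to reach ``peak_sd`` SDs above the mean of the
    smoothed squared 130-200 Hz signal; event boundaries are the
    surrounding ``edge_sd`` crossings.  Events with durations outside
    ``dur_s`` are discarded, as are events co-detected on ``noise_channel``.
    """
    if lfp.duration < MIN_TRACE_DURATION_S:
        raise ValueError("trace too short for noise estimation")
    z = _probe_zscore(lfp, smooth_s, peak_sd, edge_sd)
    # boundaries are the edge_sd crossings around each peak; no merge step —
    # sub-threshold-duration noise excursions fall to the 20-ms floor
    regions = _regions_above(z.samples > edge_sd)
    regions = [r for r in regions if z.samples[r[0]:r[1]].max() >= peak_sd]
    regions = [r for r in regions
               if dur_s[0] <= (r[1] - r[0]) / z.rate <= dur_s[1]]
    events = _regions_to_events(regions, z.samples, z)

    if noise_channel is not None:
        if not isinstance(noise_channel, ContinuousTrace):
            raise TypeError("noise_channel must be a ContinuousTrace")
        noise_events = detect_swr_probe(noise_channel, peak_sd=peak_sd,
                                        edge_sd=edge_sd, dur_s=dur_s,
                                        smooth_s=smooth_s)
        keep = [not _overlaps_any(row, noise_events)
                for _, row in events.iterrows()]
        events = events[keep].reset_index(drop=True)
    return events


def _overlaps_any(event_row, others: pd.DataFrame) -> bool:
    return bool(((others["onset_s"] < event_row["offset_s"]) &
                 (others["offset_s"] > event_row["onset_s"])).any())


@dataclass(frozen=True)
class QCRules:
    """Programmatic event QC replacing manual curation.

    ``min_band_power_sd``: minimum within-event ripple-band RMS, in units of
    the whole-trace band SD.  ``max_line_noise_ratio``: maximum allowed
    ratio of line-frequency band power to ripple-band power inside the
    event.
    """

    min_band_power_sd: float | None = None
    max_line_noise_ratio: float | None = None
    line_hz: float = 50.0
    ripple_band: tuple = (100.0, 250.0)


def swr_qc(events: pd.DataFrame, lfp: ContinuousTrace | None = None,
           rules: QCRules = QCRules()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply QC rules; returns ``(kept, rejected)`` with reason codes.

    With an empty rule set this is the identity (all events kept).
    """
    validate_events(events)
    active = (rules.min_band_power_sd is not None or
              rules.max_line_noise_ratio is not None)
    if not active or not len(events):
        return events.reset_index(drop=True), events.iloc[0:0].assign(reason="")

    if lfp is None:
        raise ValueError("QC rules require the LFP trace")
    band = bandpass(lfp, *rules.ripple_band).samples
    band_sd = band.std()
    lo, hi = rules.line_hz * 0.8, rules.line_hz * 1.2
    line = bandpass(lfp, lo, hi).samples

    reasons = []
    for _, row in events.iterrows():
        i0 = max(lfp.index_at(row["onset_s"]), 0)
        i1 = min(lfp.index_at(row["offset_s"]), lfp.n)
        seg_band = band[i0:i1]
        seg_line = line[i0:i1]
        reason = ""
        band_rms = np.sqrt(np.mean(seg_band ** 2)) if len(seg_band) else 0.0
        if rules.min_band_power_sd is not None and \
                band_rms < rules.min_band_power_sd * band_sd:
            reason = "low_band_power"
        elif rules.max_line_noise_ratio is not None:
            line_pow = np.mean(seg_line ** 2) if len(seg_line) else 0.0
            band_pow = np.mean(seg_band ** 2) if len(seg_band) else np.inf
            if band_pow == 0 or line_pow / band_pow > rules.max_line_noise_ratio:
                reason = "line_noise"
        reasons.append(reason)

    reasons = np.array(reasons)
    kept = events[reasons == ""].reset_index(drop=True)
    rejected = events[reasons != ""].assign(reason=reasons[reasons != ""])
    for _, row in rejected.iterrows():
        log.info("QC rejected event %s: %s", row["event_id"], row["reason"])
    return kept, rejected.reset_index(drop=True)


def require_min_events(events: pd.DataFrame, min_events: int = 30) -> bool:
    """Downstream-session filter: need at least ``min_events`` SWRs."""
    ok = len(events) >= min_events
    if not ok:
        warnings.warn(
            f"session has only {len(events)} SWRs "
            f"(< {min_events}); excluded from downstream analysis",
            stacklevel=2)
    return ok
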