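"""Filtering and resampling primitives for continuous traces.

Both operations are zero-phase and pure: they return new traces and never
modify their input.  The ripple band-pass follows common ripple-detection
practice — a Chebyshev type-I IIR design applied forward-backward so that
event timing is not biased by filter delay.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import ContinuousTrace

__all__ = ["bandpass", "downsample"]


def bandpass(trace: ContinuousTrace, lo_hz: float, hi_hz: float,
             order: int = 4, ripple_db: float = 1.0) -> ContinuousTrace:
    """Zero-phase Chebyshev type-I band-pass filter.

    Parameters
    ----------
    lo_hz, hi_hz
        Pass-band edges in Hz; require ``0 < lo_hz < hi_hz < rate/2``.
    order
        Filter order (applied twice by filtfilt).
    ripple_db
        Pass-band ripple of the Chebyshev design, dB.
    """
    nyq = trace.rate / 2.0
    if not (0 < lo_hz < hi_hz):
        raise ValueError("need 0 < lo_hz < hi_hz")
    if hi_hz >= nyq:
        raise ValueError(f"hi_hz={hi_hz} must be below Nyquist ({nyq} Hz)")
    sos = sps.cheby1(order, ripple_db, [lo_hz, hi_hz], btype="bandpass",
                     fs=trace.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(filtered)


def downsample(trace: ContinuousTrace, target_hz: float) -> ContinuousTrace:
    """Anti-aliased resampling to ``target_hz`` (< current rate).

    Integer and rational rate ratios are handled by polyphase resampling.
    """
    if target_hz >= trace.rate:
        raise ValueError("target_hz must be below the current rate")
    frac = Fraction(target_hz / trace.rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    if abs(up / down - target_hz / trace.rate) > 1e-9:
        raise ValueError("resampling ratio is not rational within tolerance")
    out = sps.resample_poly(trace.samples, up, down)
    return ContinuousTrace(samples=out, rate=float(target_hz),
                           t0=trace.t0, units=trace.units)
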