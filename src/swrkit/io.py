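"""Core containers and file formats.

Continuous signals (LFP, membrane potential, clamp current) live in
:class:`ContinuousTrace`; event and spike tables are plain pandas DataFrames
validated against fixed schemas.  On disk, traces are flat little-endian
float32 arrays (``<name>.f32``) with a JSON sidecar holding the sampling
rate, sample count, start time and units; tables are headered CSV.

Conventions used throughout the package:

* time is in seconds (float64) internally; milliseconds appear only at the
  CLI/config surface,
* sample indices are 0-based and event intervals are half-open
  ``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ContinuousTrace",
    "EVENT_COLUMNS",
    "SPIKE_COLUMNS",
    "CELL_CLASSES",
    "make_event_table",
    "validate_events",
    "validate_spikes",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_spikes",
    "write_spikes",
]


class FormatError(ValueError):
    """Raised when a file does not match the declared on-disk format."""


@dataclass(frozen=True)
class ContinuousTrace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Signal values (mV for Vm, pA for clamp current, arbitrary for LFP).
    rate
        Sampling rate in Hz; must be positive.
    t0
        Time of the first sample in seconds.
    units
        Physical unit label, e.g. ``"mV"``.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.rate > 0):
            raise ValueError("rate must be > 0")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n / rate)."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample covering time ``t`` (floor convention)."""
        return int(np.floor((t - self.t0) * self.rate))

    def slice(self, t_start: float, t_stop: float) -> "ContinuousTrace":
        """Half-open time slice ``[t_start, t_stop)`` as a new trace."""
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_stop), self.n)
        if i1 <= i0:
            raise ValueError("empty slice")
        return replace(self, samples=self.samples[i0:i1],
                       t0=self.t0 + i0 / self.rate)

    def with_samples(self, samples: np.ndarray) -> "ContinuousTrace":
        return replace(self, samples=samples)


EVENT_COLUMNS = ["event_id", "onset_s", "peak_s", "offset_s", "channel_id"]
SPIKE_COLUMNS = ["cell_id", "cell_class", "spike_time_s"]
CELL_CLASSES = ("pyr", "int")


def make_event_table(onsets, peaks=None, offsets=None, channel_id=0,
                     event_ids=None) -> pd.DataFrame:
    """Assemble a validated event table from arrays of times."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if offsets is None:
        offsets = onsets
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if peaks is None:
        peaks = 0.5 * (onsets + offsets)
    peaks = np.atleast_1d(np.asarray(peaks, dtype=float))
    if event_ids is None:
        event_ids = np.arange(len(onsets))
    df = pd.DataFrame({
        "event_id": event_ids,
        "onset_s": onsets,
        "peak_s": peaks,
        "offset_s": offsets,
        "channel_id": channel_id,
    })
    df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    validate_events(df)
    return df


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != EVENT_COLUMNS:
        raise FormatError(f"event table columns must be {EVENT_COLUMNS}")
    if len(df):
        if df["event_id"].duplicated().any():
            raise FormatError("event_id values must be unique")
        if not ((df["onset_s"] <= df["peak_s"]) &
                (df["peak_s"] <= df["offset_s"])).all():
            raise FormatError("need onset_s <= peak_s <= offset_s")
        if not df["onset_s"].is_monotonic_increasing:
            raise FormatError("events must be sorted by onset_s")
    return df


def validate_spikes(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != SPIKE_COLUMNS:
        raise FormatError(f"spike table columns must be {SPIKE_COLUMNS}")
    if len(df):
        if not np.isfinite(df["spike_time_s"].to_numpy()).all():
            raise FormatError("spike times must be finite")
        bad = set(df["cell_class"]) - set(CELL_CLASSES)
        if bad:
            raise FormatError(f"unknown cell_class values: {sorted(bad)}")
        for _, grp in df.groupby("cell_id"):
            if not grp["spike_time_s"].is_monotonic_increasing:
                raise FormatError("spike times must be sorted within cell")
    return df


def _sidecar_path(path_binary: Path) -> Path:
    return path_binary.with_suffix(".json")


def write_trace(trace: ContinuousTrace, path_binary) -> Path:
    """Write ``<name>.f32`` (little-endian float32) plus JSON sidecar."""
    path_binary = Path(path_binary)
    trace.samples.astype("<f4").tofile(path_binary)
    sidecar = {
        "rate_hz": float(trace.rate),
        "n_samples": int(trace.n),
        "t0_s": float(trace.t0),
        "units": trace.units,
    }
    _sidecar_path(path_binary).write_text(json.dumps(sidecar, indent=1))
    return path_binary


def read_trace(path_binary, path_sidecar=None) -> ContinuousTrace:
    """Read a flat float32 trace and its JSON sidecar."""
    path_binary = Path(path_binary)
    path_sidecar = Path(path_sidecar) if path_sidecar else _sidecar_path(path_binary)
    try:
        meta = json.loads(path_sidecar.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read sidecar {path_sidecar}: {exc}") from exc
    for key in ("rate_hz", "n_samples"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field '{key}'")
    if not meta["rate_hz"] > 0:
        raise FormatError("sidecar rate_hz must be > 0")
    n_expected = int(meta["n_samples"])
    n_bytes = path_binary.stat().st_size
    if n_bytes != 4 * n_expected:
        raise FormatError(
            f"{path_binary}: file holds {n_bytes // 4} float32 samples, "
            f"sidecar declares {n_expected}")
    samples = np.fromfile(path_binary, dtype="<f4").astype(np.float64)
    return ContinuousTrace(samples=samples, rate=float(meta["rate_hz"]),
                           t0=float(meta.get("t0_s", 0.0)),
                           units=str(meta.get("units", "")))


def write_events(df: pd.DataFrame, path) -> Path:
    validate_events(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_events(df)


def write_spikes(df: pd.DataFrame, path) -> Path:
    validate_spikes(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_spikes(df)
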