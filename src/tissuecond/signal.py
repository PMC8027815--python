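"""Conditioning and segmentation of voltage/current pulse recordings.

The raw instrument export is a pair of uniformly sampled channels, voltage
and current, containing either a single low-voltage diagnostic pulse or a
high-voltage train (typically 100 pulses).  Before any conductivity is
computed the recording is conditioned — DC offsets estimated on a quiet
window and subtracted, then a zero-phase low-pass Butterworth filter — and
segmented into individual pulses by amplitude thresholding.  Each pulse's
flat top ("plateau") is summarized by the median of its central portion,
which is robust to charging transients at the pulse edges and to isolated
corrupted samples, and the per-pulse resistance is the ratio of the two
plateau values.

Index convention: 0-based, half-open ``[start, end)`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import (
    ConditioningError,
    DomainError,
    FilterDesignError,
    InvalidRecordingError,
    ParseError,
    SegmentationError,
)
from .geometry import FieldStrength

__all__ = [
    "PulseRecording",
    "PulseProtocol",
    "PulseSegment",
    "remove_dc_offset",
    "smooth",
    "detect_pulses",
    "plateau_stats",
    "characterize_segments",
    "pulse_table",
]

#: Relative tolerance on sample-interval uniformity.
_DT_RTOL = 1e-9

#: Named CSV schema for waveform files.
RECORDING_COLUMNS = ("time_s", "voltage_V", "current_A")


@dataclass(frozen=True)
class PulseProtocol:
    """Declared pulse-delivery protocol for one recording.

    ``nominal_field`` is the prescribed field strength (the protocol variable
    of the study); the realized plate voltage is ``E * L`` for the sample the
    protocol is applied to.
    """

    n_pulses: int
    pulse_width_s: float
    repetition_period_s: float
    nominal_field: FieldStrength

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise DomainError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if not (0 < self.pulse_width_s < self.repetition_period_s):
            raise DomainError(
                "need 0 < pulse_width < repetition_period, got "
                f"{self.pulse_width_s} / {self.repetition_period_s}"
            )


@dataclass(frozen=True)
class PulseRecording:
    """Uniformly sampled voltage/current time series.

    Invariants (checked on construction): the three arrays have equal length
    of at least 2, time is strictly increasing, and the sample interval is
    uniform and equal to ``1 / sampling_rate_hz`` to within 1e-9 relative.
    """

    time_s: np.ndarray
    voltage_v: np.ndarray
    current_a: np.ndarray
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.voltage_v, dtype=float)
        i = np.asarray(self.current_a, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "voltage_v", v)
        object.__setattr__(self, "current_a", i)
        if not (len(t) == len(v) == len(i)):
            raise InvalidRecordingError("time, voltage and current must have equal length")
        if len(t) < 2:
            raise InvalidRecordingError("a recording needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidRecordingError("time must be strictly increasing")
        nominal = 1.0 / self.sampling_rate_hz
        if np.any(np.abs(dt - nominal) > _DT_RTOL * nominal + 1e-15):
            raise InvalidRecordingError(
                "non-uniform time base or sample interval inconsistent with sampling_rate_hz"
            )

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "voltage_V": self.voltage_v,
                "current_A": self.current_a,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: Optional[dict] = None) -> "PulseRecording":
        """Read a waveform CSV with named columns time_s, voltage_V, current_A."""
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path}: not readable as CSV ({exc})") from exc
        missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        for col in RECORDING_COLUMNS:
            numeric = pd.to_numeric(df[col], errors="coerce")
            if numeric.isna().any():
                row = int(numeric.isna().idxmax())
                raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
            df[col] = numeric
        t = df["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else float("nan")
        return cls(
            time_s=t,
            voltage_v=df["voltage_V"].to_numpy(),
            current_a=df["current_A"].to_numpy(),
            sampling_rate_hz=fs,
            metadata=dict(metadata or {}),
        )


@dataclass(frozen=True)
class PulseSegment:
    """One detected pulse: sample extent, plateau window and plateau values.

    ``start``/``end`` and ``plateau_start``/``plateau_end`` are 0-based,
    half-open sample indices into the parent recording.
    """

    pulse_index: int
    start: int
    end: int
    plateau_start: Optional[int] = None
    plateau_end: Optional[int] = None
    v_plateau: Optional[float] = None
    i_plateau: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SegmentationError(f"empty segment [{self.start}, {self.end})")
        if self.plateau_start is not None and self.plateau_end is not None:
            if not (self.start <= self.plateau_start < self.plateau_end <= self.end):
                raise SegmentationError("plateau window must lie within the segment")

    @property
    def resistance_ohm(self) -> float:
        if self.v_plateau is None or self.i_plateau is None:
            raise SegmentationError("plateau not characterized yet")
        if self.i_plateau <= 0:
            raise SegmentationError(
                f"non-positive plateau current {self.i_plateau}; resistance undefined"
            )
        return self.v_plateau / self.i_plateau


def remove_dc_offset(
    rec: PulseRecording,
    quiet_window: tuple[int, int],
    threshold_fraction: float = 0.5,
) -> PulseRecording:
    """Subtract per-channel DC offsets estimated over a quiet window.

    The window (half-open sample range) must lie outside every detected
    pulse; this is validated post hoc by thresholding the voltage channel at
    ``threshold_fraction`` of its absolute maximum.

    Returns a new recording whose channel means over the quiet window are
    zero to round-off; pulse amplitudes are shifted by exactly the estimated
    offsets.
    """
    lo, hi = quiet_window
    if not (0 <= lo < hi <= len(rec)):
        raise ConditioningError(f"quiet window [{lo}, {hi}) outside recording of length {len(rec)}")
    for seg in detect_pulses(rec, threshold_fraction):
        if lo < seg.end and seg.start < hi:
            raise ConditioningError(
                f"quiet window [{lo}, {hi}) overlaps detected pulse "
                f"[{seg.start}, {seg.end})"
            )
    v_off = float(np.mean(rec.voltage_v[lo:hi]))
    i_off = float(np.mean(rec.current_a[lo:hi]))
    return replace(
        rec,
        voltage_v=rec.voltage_v - v_off,
        current_a=rec.current_a - i_off,
        metadata={**rec.metadata, "dc_offset_v": v_off, "dc_offset_a": i_off},
    )


def smooth(rec: PulseRecording, cutoff_hz: float, order: int = 4) -> PulseRecording:
    """Zero-phase low-pass Butterworth filter on both channels.

    Applied forward and backward (``filtfilt``) so pulse edges are not
    delayed; DC gain is exactly 1 so plateau levels are preserved.
    """
    nyquist = rec.sampling_rate_hz / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise FilterDesignError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    b, a = butter(order, cutoff_hz, btype="low", fs=rec.sampling_rate_hz)
    return replace(
        rec,
        voltage_v=filtfilt(b, a, rec.voltage_v),
        current_a=filtfilt(b, a, rec.current_a),
        metadata={**rec.metadata, "filter": {"order": order, "cutoff_hz": cutoff_hz}},
    )


def detect_pulses(
    rec: PulseRecording,
    threshold_fraction: float = 0.5,
    min_width_samples: int = 5,
) -> list[PulseSegment]:
    """Segment a recording into pulses by voltage-amplitude thresholding.

    Segments are the maximal runs of samples where ``|V| >= f * max|V|``
    (samples exactly at threshold are included); runs shorter than
    ``min_width_samples`` are discarded as glitches.  An all-zero voltage
    trace yields an empty list.
    """
    if not (0 < threshold_fraction < 1):
        raise DomainError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    v = np.abs(rec.voltage_v)
    vmax = v.max()
    if vmax == 0:
        return []
    above = v >= threshold_fraction * vmax
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    segments = []
    for start, end in zip(starts, ends):
        if end - start >= min_width_samples:
            segments.append(PulseSegment(pulse_index=len(segments), start=start, end=end))
    return segments


def plateau_stats(
    seg: PulseSegment, rec: PulseRecording, central_fraction: float = 0.5
) -> tuple[float, float]:
    """Median voltage and current over the central portion of a pulse.

    The window keeps the central ``central_fraction`` of the segment,
    trimming the edges symmetrically, which excludes charging transients and
    filter edge response; the median tolerates up to ~10% outlier samples.
    """
    if not (0 < central_fraction <= 1):
        raise DomainError(f"central_fraction must be in (0, 1], got {central_fraction}")
    width = seg.end - seg.start
    trim = int(round(width * (1.0 - central_fraction) / 2.0))
    lo, hi = seg.start + trim, seg.end - trim
    if hi <= lo:
        raise SegmentationError(
            f"plateau window empty after trimming segment [{seg.start}, {seg.end})"
        )
    return (
        float(np.median(rec.voltage_v[lo:hi])),
        float(np.median(rec.current_a[lo:hi])),
    )


def characterize_segments(
    rec: PulseRecording,
    segments: Sequence[PulseSegment],
    central_fraction: float = 0.5,
) -> list[PulseSegment]:
    """Fill plateau window and plateau values for each detected segment."""
    out = []
    for seg in segments:
        width = seg.end - seg.start
        trim = int(round(width * (1.0 - central_fraction) / 2.0))
        v_plat, i_plat = plateau_stats(seg, rec, central_fraction)
        out.append(
            replace(
                seg,
                plateau_start=seg.start + trim,
                plateau_end=seg.end - trim,
                v_plateau=v_plat,
                i_plateau=i_plat,
            )
        )
    return out


def pulse_table(segments: Sequence[PulseSegment]) -> pd.DataFrame:
    """Per-pulse summary table (pulse_index, plateau V/I, resistance)."""
    return pd.DataFrame(
        {
            "pulse_index": [s.pulse_index for s in segments],
            "v_plateau_V": [s.v_plateau for s in segments],
            "i_plateau_A": [s.i_plateau for s in segments],
            "resistance_ohm": [s.resistance_ohm for s in segments],
        }
    )
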