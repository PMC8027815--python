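"""Conductivity statistics from conditioned pulse recordings.

This is the analytical core of the package.  Each sample contributes

* a *baseline* (initial) conductivity from a single low-voltage diagnostic
  pulse (~20 V, non-electroporating, purely diagnostic), and
* an *intra-pulse* conductivity during a high-voltage pulse train, one value
  per delivered pulse, summarized by the mean over pulses.

Both come from Ohm's law on the pulse plateau and the geometric cell
constant: ``sigma = K / R`` with ``R = V_plateau / I_plateau``.

Group-level results are assembled into a conductivity-vs-field curve: the
per-field mean/SD of intra-pulse conductivity, the mean percent increase
over each sample's own baseline, and the *adjusted* conductivity — the group
baseline mean scaled by the mean percent increase, which normalizes curves
from groups with different starting conductivities onto a comparable scale.

The high-level entry point is :class:`PulsedFieldStudy` (a model object
built from per-sample recordings) whose :meth:`~PulsedFieldStudy.fit`
returns a :class:`PulsedFieldResults` carrying the per-sample estimates, the
assembled curve and a text ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    ConditioningError,
    DomainError,
    InvalidRecordingError,
    MeasurementError,
    ParseError,
    ProtocolMismatchError,
)
from .geometry import CylindricalSample, FieldStrength, cell_constant, field_from_voltage
from .signal import (
    PulseProtocol,
    PulseRecording,
    PulseSegment,
    characterize_segments,
    detect_pulses,
    remove_dc_offset,
    smooth,
)

__all__ = [
    "ConductivityMeasurement",
    "ConductivityCurve",
    "TemperatureTrace",
    "QCResult",
    "baseline_conductivity",
    "intra_pulse_conductivity",
    "percent_increase",
    "adjusted_conductivity",
    "assemble_curve",
    "joule_heating_qc",
    "SampleRun",
    "PulsedFieldStudy",
    "PulsedFieldResults",
]


@dataclass(frozen=True)
class ConductivityMeasurement:
    """One conductivity value with its provenance.

    ``source`` is ``"baseline"`` for the diagnostic pulse (the field then is
    the realized diagnostic field, ~36 V/cm for 20 V across 0.56 cm) or
    ``"intra_pulse"`` for one pulse of the high-voltage train (the field is
    the nominal protocol field).
    """

    sample_id: str
    sigma_s_per_m: float
    field: FieldStrength
    source: Literal["baseline", "intra_pulse"]
    pulse_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sigma_s_per_m > 0:
            raise MeasurementError(f"conductivity must be > 0, got {self.sigma_s_per_m}")
        if self.source not in ("baseline", "intra_pulse"):
            raise DomainError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class TemperatureTrace:
    """Sampled tissue temperature during pulse delivery (default 2 Hz)."""

    time_s: np.ndarray
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        temp = np.asarray(self.temp_c, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "temp_c", temp)
        if len(t) != len(temp) or len(t) < 1:
            raise InvalidRecordingError("time and temperature must have equal, nonzero length")
        if not np.all(np.isfinite(temp)):
            raise InvalidRecordingError("temperature trace contains non-finite values")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]:
                raise InvalidRecordingError("temperature time base must be uniform, increasing")

    @property
    def sample_rate_hz(self) -> float:
        if len(self.time_s) < 2:
            return float("nan")
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "temp_C": self.temp_c}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemperatureTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "temp_C"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing column {col!r}")
        return cls(time_s=df["time_s"].to_numpy(), temp_c=df["temp_C"].to_numpy())


@dataclass(frozen=True)
class QCResult:
    passed: bool
    max_rise_c: float


@dataclass(frozen=True)
class ConductivityCurve:
    """Assembled sigma(E) curve for one tissue group.

    ``table`` columns: field_V_per_cm, sigma_mean_S_per_m, sigma_sd, n,
    pct_increase_mean, sigma_adjusted, degenerate (n == 1 flag).  Fields are
    sorted ascending.
    """

    group: str
    baseline_mean_s_per_m: float
    baseline_sd_s_per_m: float
    baseline_n: int
    table: pd.DataFrame
    percent_increase_mode: str = "per_sample"

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "group", self.group)
        out.to_csv(path, index=False)


def _conditioned_segments(
    rec: PulseRecording,
    threshold_fraction: float,
    plateau_fraction: float,
    min_width_samples: int,
) -> list[PulseSegment]:
    segs = detect_pulses(rec, threshold_fraction, min_width_samples)
    return characterize_segments(rec, segs, plateau_fraction)


def baseline_conductivity(
    diagnostic_rec: PulseRecording,
    sample: CylindricalSample,
    threshold_fraction: float = 0.5,
    plateau_fraction: float = 0.5,
    min_width_samples: int = 5,
) -> ConductivityMeasurement:
    """Initial conductivity from a single low-voltage diagnostic pulse.

    The recording must contain exactly one detectable pulse; the measurement
    is tagged with the realized diagnostic field ``V_plateau / L``.
    """
    segs = _conditioned_segments(
        diagnostic_rec, threshold_fraction, plateau_fraction, min_width_samples
    )
    if len(segs) != 1:
        raise ProtocolMismatchError(
            f"diagnostic recording must contain exactly 1 pulse, found {len(segs)}"
        )
    seg = segs[0]
    if seg.i_plateau is None or seg.i_plateau <= 0:
        raise MeasurementError(f"non-positive plateau current {seg.i_plateau}")
    sigma = cell_constant(sample) / seg.resistance_ohm
    return ConductivityMeasurement(
        sample_id=sample.sample_id,
        sigma_s_per_m=sigma,
        field=field_from_voltage(abs(seg.v_plateau), sample),
        source="baseline",
    )


def intra_pulse_conductivity(
    ire_rec: PulseRecording,
    sample: CylindricalSample,
    protocol: PulseProtocol,
    threshold_fraction: float = 0.5,
    plateau_fraction: float = 0.5,
    min_width_samples: int = 5,
    count_policy: Literal["error", "warn"] = "error",
) -> tuple[list[ConductivityMeasurement], float]:
    """Per-pulse conductivity during a high-voltage train, plus train summary.

    Returns one measurement per detected pulse (``sigma = K / R`` at the
    nominal protocol field) and the train summary, the mean over pulses.
    A pulse count differing from ``protocol.n_pulses`` raises by default;
    ``count_policy="warn"`` downgrades the mismatch to a warning.
    """
    segs = _conditioned_segments(ire_rec, threshold_fraction, plateau_fraction, min_width_samples)
    if len(segs) != protocol.n_pulses:
        msg = f"detected {len(segs)} pulses but protocol declares {protocol.n_pulses}"
        if count_policy == "error":
            raise ProtocolMismatchError(msg)
        warnings.warn(msg, stacklevel=2)
    if not segs:
        raise MeasurementError("no pulses detected in IRE recording")
    k = cell_constant(sample)
    measurements = [
        ConductivityMeasurement(
            sample_id=sample.sample_id,
            sigma_s_per_m=k / seg.resistance_ohm,
            field=protocol.nominal_field,
            source="intra_pulse",
            pulse_index=seg.pulse_index,
        )
        for seg in segs
    ]
    summary = float(np.mean([m.sigma_s_per_m for m in measurements]))
    return measurements, summary


def percent_increase(sigma_e: float, sigma_0: float) -> float:
    """Percent change of ``sigma_e`` relative to a baseline ``sigma_0``."""
    if not sigma_0 > 0:
        raise DomainError(f"baseline conductivity must be > 0, got {sigma_0}")
    return 100.0 * (sigma_e - sigma_0) / sigma_0


def adjusted_conductivity(group_baseline_mean: float, mean_percent_increase: float) -> float:
    """Group baseline mean scaled by a mean percent increase.

    Exact algebraic inverse of :func:`percent_increase`:
    ``adjusted_conductivity(s0, percent_increase(s, s0)) == s``.
    """
    if not group_baseline_mean > 0:
        raise DomainError(f"group baseline mean must be > 0, got {group_baseline_mean}")
    return group_baseline_mean * (1.0 + mean_percent_increase / 100.0)


def assemble_curve(
    measurements: Sequence[ConductivityMeasurement],
    group: str,
    percent_increase_mode: Literal["per_sample", "ratio_of_means"] = "per_sample",
) -> ConductivityCurve:
    """Aggregate per-sample measurements into a sigma(E) curve for one group.

    The group baseline is the mean (and sample SD) over all baseline
    measurements, pooled across samples.  At each field, intra-pulse
    measurements are first reduced to one train value per sample (mean over
    pulses), then summarized across samples (mean, SD with ``n - 1``
    denominator, n; SD is reported as 0 and flagged degenerate when n = 1).

    Percent increase per field is computed per-sample against that sample's
    own baseline then averaged (``per_sample``, the default), or from the
    ratio of the per-field mean to the group baseline mean
    (``ratio_of_means`` — the reading supported by printed group means).
    Adjusted conductivity is the group baseline mean scaled by the mean
    percent increase.
    """
    baselines = [m for m in measurements if m.source == "baseline"]
    intra = [m for m in measurements if m.source == "intra_pulse"]
    if not baselines or not intra:
        raise AggregationError("need at least one baseline and one intra-pulse measurement")
    baseline_by_sample: dict[str, float] = {}
    for m in baselines:
        baseline_by_sample.setdefault(m.sample_id, m.sigma_s_per_m)
    b_values = np.array(list(baseline_by_sample.values()))
    b_mean = float(b_values.mean())
    b_sd = float(b_values.std(ddof=1)) if len(b_values) > 1 else 0.0

    # one train value per (field, sample)
    per_sample: dict[tuple[float, str], list[float]] = {}
    for m in intra:
        per_sample.setdefault((m.field.v_per_m, m.sample_id), []).append(m.sigma_s_per_m)

    rows = []
    for field_v_per_m in sorted({f for f, _ in per_sample}):
        sample_ids = sorted(s for f, s in per_sample if f == field_v_per_m)
        train_means = {s: float(np.mean(per_sample[(field_v_per_m, s)])) for s in sample_ids}
        values = np.array([train_means[s] for s in sample_ids])
        n = len(values)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        if percent_increase_mode == "per_sample":
            pcts = []
            for s in sample_ids:
                if s not in baseline_by_sample:
                    raise AggregationError(
                        f"sample {s!r} has intra-pulse data at "
                        f"{field_v_per_m / 100:.0f} V/cm but no baseline"
                    )
                pcts.append(percent_increase(train_means[s], baseline_by_sample[s]))
            pct = float(np.mean(pcts))
        elif percent_increase_mode == "ratio_of_means":
            pct = percent_increase(mean, b_mean)
        else:
            raise DomainError(f"unknown percent_increase_mode {percent_increase_mode!r}")
        rows.append(
            {
                "field_V_per_cm": field_v_per_m / 100.0,
                "sigma_mean_S_per_m": mean,
                "sigma_sd": sd,
                "n": n,
                "pct_increase_mean": pct,
                "sigma_adjusted": adjusted_conductivity(b_mean, pct),
                "degenerate": n == 1,
            }
        )
    return ConductivityCurve(
        group=group,
        baseline_mean_s_per_m=b_mean,
        baseline_sd_s_per_m=b_sd,
        baseline_n=len(b_values),
        table=pd.DataFrame(rows),
        percent_increase_mode=percent_increase_mode,
    )


def joule_heating_qc(trace: TemperatureTrace, max_rise_c: float) -> QCResult:
    """Check the Joule-heating excursion against a temperature-rise budget.

    Fails iff ``max(T) - T(0)`` strictly exceeds ``max_rise_c`` (a rise
    exactly at the budget passes).
    """
    rise = float(np.max(trace.temp_c) - trace.temp_c[0])
    return QCResult(passed=rise <= max_rise_c, max_rise_c=rise)


# ---------------------------------------------------------------------------
# Model / Results objects for the full pulsed-field workflow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRun:
    """All raw data for one physical sample: diagnostic + IRE recordings."""

    sample: CylindricalSample
    diagnostic: PulseRecording
    ire: PulseRecording
    protocol: PulseProtocol
    temperature: Optional[TemperatureTrace] = None


class PulsedFieldStudy:
    """Pulsed-field conductivity analysis of a cohort of tissue samples.

    Parameters
    ----------
    runs : sequence of SampleRun
        One entry per sample, each carrying the diagnostic recording, the
        high-voltage train and its declared protocol.
    group : str
        Tissue-group label for the assembled curve.
    filter_order, cutoff_fraction : int, float
        Butterworth conditioning: order (default 4) and cutoff as a fraction
        of the sampling rate (default 1/20).  ``apply_filter=False`` skips
        smoothing (useful on clean synthetic data).
    threshold_fraction, plateau_fraction, min_width_samples :
        Segmentation and plateau-estimation controls; see
        :mod:`tissuecond.signal`.
    percent_increase_mode : {"per_sample", "ratio_of_means"}
        How the per-field percent increase is aggregated.
    count_policy : {"error", "warn"}
        What to do when the detected pulse count disagrees with the
        declared protocol.
    max_temp_rise_c : float
        Joule-heating QC budget applied to any attached temperature traces.
    """

    def __init__(
        self,
        runs: Sequence[SampleRun],
        group: str = "group",
        *,
        filter_order: int = 4,
        cutoff_fraction: float = 0.05,
        apply_filter: bool = True,
        threshold_fraction: float = 0.5,
        plateau_fraction: float = 0.5,
        min_width_samples: int = 5,
        percent_increase_mode: Literal["per_sample", "ratio_of_means"] = "per_sample",
        count_policy: Literal["error", "warn"] = "error",
        max_temp_rise_c: float = 10.0,
    ) -> None:
        if not runs:
            raise DomainError("need at least one SampleRun")
        self.runs = list(runs)
        self.group = group
        self.filter_order = filter_order
        self.cutoff_fraction = cutoff_fraction
        self.apply_filter = apply_filter
        self.threshold_fraction = threshold_fraction
        self.plateau_fraction = plateau_fraction
        self.min_width_samples = min_width_samples
        self.percent_increase_mode = percent_increase_mode
        self.count_policy = count_policy
        self.max_temp_rise_c = max_temp_rise_c

    # -- conditioning ------------------------------------------------------

    def _condition(self, rec: PulseRecording) -> PulseRecording:
        """DC-offset removal on the pre-pulse quiet window, then smoothing."""
        segs = detect_pulses(rec, self.threshold_fraction, self.min_width_samples)
        if segs and segs[0].start >= 8:
            # keep a small guard before the first rising edge
            quiet_end = max(2, segs[0].start - 4)
            try:
                rec = remove_dc_offset(rec, (0, quiet_end), self.threshold_fraction)
            except ConditioningError:
                pass  # no usable quiet window; proceed without offset removal
        if self.apply_filter:
            rec = smooth(
                rec,
                cutoff_hz=self.cutoff_fraction * rec.sampling_rate_hz,
                order=self.filter_order,
            )
        return rec

    def fit(self) -> "PulsedFieldResults":
        """Run conditioning, segmentation and aggregation over all samples."""
        seg_kwargs = dict(
            threshold_fraction=self.threshold_fraction,
            plateau_fraction=self.plateau_fraction,
            min_width_samples=self.min_width_samples,
        )
        measurements: list[ConductivityMeasurement] = []
        baseline_rows = []
        pulse_rows = []
        qc_rows = []
        for run in self.runs:
            diag = self._condition(run.diagnostic)
            ire = self._condition(run.ire)
            base = baseline_conductivity(diag, run.sample, **seg_kwargs)
            per_pulse, train_mean = intra_pulse_conductivity(
                ire, run.sample, run.protocol, count_policy=self.count_policy, **seg_kwargs
            )
            measurements.append(base)
            measurements.extend(per_pulse)
            baseline_rows.append(
                {
                    "sample_id": run.sample.sample_id,
                    "tissue_label": run.sample.tissue_label,
                    "sigma0_S_per_m": base.sigma_s_per_m,
                    "diagnostic_field_V_per_cm": base.field.v_per_cm,
                }
            )
            for m in per_pulse:
                pulse_rows.append(
                    {
                        "sample_id": m.sample_id,
                        "field_V_per_cm": m.field.v_per_cm,
                        "pulse_index": m.pulse_index,
                        "sigma_S_per_m": m.sigma_s_per_m,
                    }
                )
            if run.temperature is not None:
                qc = joule_heating_qc(run.temperature, self.max_temp_rise_c)
                qc_rows.append(
                    {
                        "sample_id": run.sample.sample_id,
                        "max_rise_C": qc.max_rise_c,
                        "passed": qc.passed,
                    }
                )
        curve = assemble_curve(measurements, self.group, self.percent_increase_mode)
        return PulsedFieldResults(
            model=self,
            curve=curve,
            baseline_table=pd.DataFrame(baseline_rows),
            pulse_table=pd.DataFrame(pulse_rows),
            qc_table=pd.DataFrame(qc_rows),
            measurements=measurements,
        )


@dataclass
class PulsedFieldResults:
    """Fitted pulsed-field characterization of one tissue group."""

    model: PulsedFieldStudy
    curve: ConductivityCurve
    baseline_table: pd.DataFrame
    pulse_table: pd.DataFrame
    qc_table: pd.DataFrame
    measurements: list = dc_field(default_factory=list, repr=False)

    @property
    def baseline_mean(self) -> float:
        return self.curve.baseline_mean_s_per_m

    @property
    def baseline_sd(self) -> float:
        return self.curve.baseline_sd_s_per_m

    def sigma_at(self, field_v_per_cm: float) -> float:
        """Mean intra-pulse conductivity at a measured field strength."""
        t = self.curve.table
        match = t[np.isclose(t["field_V_per_cm"], field_v_per_cm)]
        if match.empty:
            raise DomainError(f"no measurements at {field_v_per_cm} V/cm")
        return float(match["sigma_mean_S_per_m"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Pulsed-field conductivity characterization: {self.curve.group}",
            f"  samples: {len(self.baseline_table)}   "
            f"percent-increase mode: {self.curve.percent_increase_mode}",
            f"  baseline sigma0: {self.baseline_mean:.3f} "
            f"± {self.baseline_sd:.3f} S/m (n={self.curve.baseline_n})",
            "",
            self.curve.table.to_string(
                index=False,
                formatters={
                    "field_V_per_cm": "{:8.0f}".format,
                    "sigma_mean_S_per_m": "{:10.4f}".format,
                    "sigma_sd": "{:8.4f}".format,
                    "pct_increase_mean": "{:8.1f}".format,
                    "sigma_adjusted": "{:10.4f}".format,
                },
            ),
        ]
        if not self.qc_table.empty:
            n_fail = int((~self.qc_table["passed"]).sum())
            lines.append("")
            lines.append(
                f"  Joule-heating QC: {len(self.qc_table)} traces, {n_fail} failed "
                f"(budget {self.model.max_temp_rise_c} °C)"
            )
        return "\n".join(lines)

    def plot(self, **kwargs):
        """Four-panel figure: baseline, sigma(E), % increase, adjusted sigma."""
        from .plotting import plot_conductivity_panels

        return plot_conductivity_panels(self, **kwargs)
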