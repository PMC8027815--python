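"""Synthetic-data generation for pulsed-field and impedance workflows.

Emulates the study design the analysis pipeline expects, so that every
downstream stage is testable without instrument data:

* a cylindrical tissue sample (default 3 mm radius, 0.56 cm thickness)
  between parallel plates,
* a ~20 V single-pulse diagnostic recording per sample,
* a 100-pulse high-voltage train per sample at one of the seven protocol
  field strengths {500, 750, 1000, 1500, 2000, 2500, 3000} V/cm, one sample
  per field by default (n = 7 per group),
* a field-dependent tissue conductivity following a sigmoid sigma(E)
  (electroporation raises conductivity with field until saturation),
* measurement noise (multiplicative Gaussian on current) and DC offsets on
  both channels — exactly the artifacts the conditioning stage removes,
* Cole–Cole dispersive impedance spectra over 1e3–1e6 Hz, and
* 2 Hz temperature traces from a lumped Joule-heating model.

Recordings emulate scope-style triggered acquisition: only a short window
around each pulse is stored (``recorded_gap_s`` of quiet signal per pulse,
plus a quiet ``lead_in_s`` before the first pulse), on a uniform time base.
The physical repetition period still governs the thermal model.

All generators are deterministic for a fixed :class:`NoiseSpec` seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .conductivity import TemperatureTrace
from .eis import ImpedanceSpectrum
from .errors import ConfigError, DomainError, SamplingError
from .geometry import CylindricalSample, FieldStrength, voltage_for_field
from .signal import PulseProtocol, PulseRecording

__all__ = [
    "DynamicConductivityModel",
    "ColeColeModel",
    "NoiseSpec",
    "ThermalModel",
    "CohortRecord",
    "DEFAULT_FIELDS_V_PER_CM",
    "synth_pulse_train",
    "synth_diagnostic",
    "synth_eis",
    "synth_temperature",
    "synth_cohort",
]

#: The seven protocol field strengths, in V/cm.
DEFAULT_FIELDS_V_PER_CM = (500.0, 750.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0)

#: Default acquisition settings (config-overridable): 100 us pulses at 1 Hz,
#: sampled at 1 MHz with 400 us of recorded quiet signal per pulse.
DEFAULT_PULSE_WIDTH_S = 100e-6
DEFAULT_REPETITION_PERIOD_S = 1.0
DEFAULT_SAMPLING_RATE_HZ = 1e6
DEFAULT_RECORDED_GAP_S = 400e-6
DEFAULT_LEAD_IN_S = 400e-6
DEFAULT_DIAGNOSTIC_VOLTAGE_V = 20.0

#: Minimum samples across one pulse width for a usable square shape.
MIN_SAMPLES_PER_PULSE = 20


@dataclass(frozen=True)
class DynamicConductivityModel:
    """Sigmoid ground-truth conductivity map sigma(E).

    ``sigma(E) = sigma0 + (sigma_max - sigma0) / (1 + exp(-(E - e_del)/slope))``

    with the transition field ``e_del`` and width ``slope`` in V/m.  The map
    is non-decreasing in E and bounded by ``sigma_max``; at fields far below
    ``e_del`` it is within the sigmoid tail of ``sigma0``.  Defaults roughly
    mimic pancreatic-tumor magnitudes: 0.24 S/m baseline rising to 0.40 S/m
    with a transition around 1000 V/cm.
    """

    sigma0_s_per_m: float = 0.24
    sigma_max_s_per_m: float = 0.40
    e_del_v_per_m: float = 1000.0 * 100.0
    slope_v_per_m: float = 300.0 * 100.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma0_s_per_m <= self.sigma_max_s_per_m:
            raise DomainError(
                f"need 0 < sigma0 <= sigma_max, got {self.sigma0_s_per_m}, "
                f"{self.sigma_max_s_per_m}"
            )
        if not self.slope_v_per_m > 0:
            raise DomainError(f"slope must be > 0, got {self.slope_v_per_m}")

    def sigma_at(self, field: FieldStrength) -> float:
        z = (field.v_per_m - self.e_del_v_per_m) / self.slope_v_per_m
        return self.sigma0_s_per_m + (self.sigma_max_s_per_m - self.sigma0_s_per_m) / (
            1.0 + math.exp(-z)
        )


@dataclass(frozen=True)
class ColeColeModel:
    """Single-dispersion Cole–Cole impedance model.

    ``Z(w) = r_inf + (r0 - r_inf) / (1 + (j w tau)^alpha)``

    ``alpha = 1`` reduces to a Debye (single-pole) dispersion; ``alpha < 1``
    broadens it, as observed for the beta dispersion of biological tissue.
    Re(Z) decreases monotonically from ``r0`` at DC to ``r_inf`` at high
    frequency.  Defaults give tissue-like conductivities (~0.15 S/m at
    10 kHz rising toward ~0.37 S/m) for the default sample geometry.
    """

    r0_ohm: float = 1366.0
    r_inf_ohm: float = 534.0
    tau_s: float = 1.6e-6
    alpha: float = 0.85

    def __post_init__(self) -> None:
        if not self.r0_ohm > self.r_inf_ohm > 0:
            raise DomainError(f"need r0 > r_inf > 0, got {self.r0_ohm}, {self.r_inf_ohm}")
        if not self.tau_s > 0:
            raise DomainError(f"tau must be > 0, got {self.tau_s}")
        if not 0 < self.alpha <= 1:
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")

    def impedance(self, frequencies_hz: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * np.asarray(frequencies_hz, dtype=float)
        return self.r_inf_ohm + (self.r0_ohm - self.r_inf_ohm) / (
            1.0 + (1j * w * self.tau_s) ** self.alpha
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: multiplicative Gaussian on current plus
    additive DC offsets on both channels.  Identical spec + seed gives
    bit-identical output."""

    relative_gaussian_sd: float = 0.0
    dc_offset_v: float = 0.0
    dc_offset_a: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_gaussian_sd < 0:
            raise DomainError(f"noise SD must be >= 0, got {self.relative_gaussian_sd}")


@dataclass(frozen=True)
class ThermalModel:
    """Lumped Joule-heating model.

    Each pulse deposits an adiabatic temperature step
    ``dT = sigma E^2 t_pulse / (rho c_p)``; between pulses the excess
    temperature relaxes exponentially to ambient at ``loss_coefficient``
    (1/s).  Defaults give a volumetric heat capacity of 3.6e6 J/(m^3 K),
    representative of soft tissue.
    """

    density_kg_per_m3: float = 1000.0
    specific_heat_j_per_kg_k: float = 3600.0
    loss_coefficient_per_s: float = 0.0
    ambient_temp_c: float = 22.0

    def __post_init__(self) -> None:
        if self.density_kg_per_m3 <= 0 or self.specific_heat_j_per_kg_k <= 0:
            raise DomainError("density and specific heat must be > 0")
        if self.loss_coefficient_per_s < 0:
            raise DomainError("loss coefficient must be >= 0")


def synth_pulse_train(
    model: DynamicConductivityModel,
    sample: CylindricalSample,
    protocol: PulseProtocol,
    noise: Optional[NoiseSpec] = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    recorded_gap_s: float = DEFAULT_RECORDED_GAP_S,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> PulseRecording:
    """Generate a square pulse-train recording at the protocol field.

    The plate voltage is ``V = E L``; the current during each pulse is
    ``I = sigma(E) V A / L`` (Ohm's law with the ground-truth conductivity at
    the nominal field), ~0 between pulses, plus the requested noise.  Only
    ``recorded_gap_s`` of quiet signal per repetition is recorded, after a
    quiet ``lead_in_s`` (triggered acquisition).
    """
    noise = noise or NoiseSpec()
    n_on = int(round(protocol.pulse_width_s * sampling_rate_hz))
    if n_on < MIN_SAMPLES_PER_PULSE:
        raise SamplingError(
            f"pulse width {protocol.pulse_width_s} s resolved by only {n_on} samples "
            f"at {sampling_rate_hz} Hz (need >= {MIN_SAMPLES_PER_PULSE})"
        )
    if recorded_gap_s >= protocol.repetition_period_s - protocol.pulse_width_s:
        recorded_gap_s = protocol.repetition_period_s - protocol.pulse_width_s
    n_gap = int(round(recorded_gap_s * sampling_rate_hz))
    n_lead = int(round(lead_in_s * sampling_rate_hz))

    field = protocol.nominal_field
    v_amp = voltage_for_field(field, sample)
    i_amp = model.sigma_at(field) * v_amp * sample.area_m2 / sample.thickness_m

    on = np.zeros(n_lead + protocol.n_pulses * (n_on + n_gap), dtype=bool)
    for k in range(protocol.n_pulses):
        start = n_lead + k * (n_on + n_gap)
        on[start : start + n_on] = True
    voltage = np.where(on, v_amp, 0.0)
    current = np.where(on, i_amp, 0.0)

    rng = np.random.default_rng(noise.seed)
    if noise.relative_gaussian_sd > 0:
        current = current * (1.0 + noise.relative_gaussian_sd * rng.standard_normal(len(current)))
    voltage = voltage + noise.dc_offset_v
    current = current + noise.dc_offset_a

    time = np.arange(len(on)) / sampling_rate_hz
    return PulseRecording(
        time_s=time,
        voltage_v=voltage,
        current_a=current,
        sampling_rate_hz=sampling_rate_hz,
        metadata={
            "sample_id": sample.sample_id,
            "nominal_field_V_per_cm": field.v_per_cm,
            "ground_truth_sigma_S_per_m": model.sigma_at(field),
            "n_pulses": protocol.n_pulses,
            "seed": noise.seed,
        },
    )


def synth_diagnostic(
    model: DynamicConductivityModel,
    sample: CylindricalSample,
    voltage_v: float = DEFAULT_DIAGNOSTIC_VOLTAGE_V,
    noise: Optional[NoiseSpec] = None,
    pulse_width_s: float = DEFAULT_PULSE_WIDTH_S,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> PulseRecording:
    """Single low-voltage diagnostic pulse (default ~20 V)."""
    field = FieldStrength(voltage_v / sample.thickness_m)
    protocol = PulseProtocol(
        n_pulses=1,
        pulse_width_s=pulse_width_s,
        repetition_period_s=10.0 * pulse_width_s,
        nominal_field=field,
    )
    return synth_pulse_train(model, sample, protocol, noise, sampling_rate_hz)


def synth_eis(
    model: ColeColeModel,
    frequencies_hz: Sequence[float],
    sample_id: str = "synthetic",
    relative_noise_sd: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Cole–Cole impedance spectrum, optionally with multiplicative noise."""
    f = np.asarray(list(frequencies_hz), dtype=float)
    if len(f) == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise DomainError("frequencies must be positive and strictly ascending")
    z = model.impedance(f)
    if relative_noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = z * (1.0 + relative_noise_sd * rng.standard_normal(len(f)))
    return ImpedanceSpectrum(frequencies_hz=f, impedance_ohm=z, sample_id=sample_id)


def synth_temperature(
    model: ThermalModel,
    sigma_s_per_m: float,
    field: FieldStrength,
    protocol: PulseProtocol,
    sample_rate_hz: float = 2.0,
) -> TemperatureTrace:
    """Temperature trace during a pulse train, sampled at 2 Hz by default.

    Pulse k (delivered at ``k * repetition_period``) contributes an
    instantaneous adiabatic step ``dT = sigma E^2 t_pulse / (rho c_p)``
    that subsequently decays as ``exp(-loss (t - t_k))``; the step registers
    strictly after its delivery time.  With zero loss the trace is the
    adiabatic staircase; with very large loss it stays pinned at ambient.
    """
    rho_cp = model.density_kg_per_m3 * model.specific_heat_j_per_kg_k
    d_t = sigma_s_per_m * field.v_per_m**2 * protocol.pulse_width_s / rho_cp
    duration = protocol.n_pulses * protocol.repetition_period_s
    times = np.arange(0.0, duration + 0.5 / sample_rate_hz, 1.0 / sample_rate_hz)
    pulse_times = np.arange(protocol.n_pulses) * protocol.repetition_period_s
    lag = times[:, None] - pulse_times[None, :]  # (samples, pulses)
    with np.errstate(over="ignore"):
        decay = np.where(lag > 0, np.exp(-model.loss_coefficient_per_s * np.maximum(lag, 0.0)), 0.0)
    temp = model.ambient_temp_c + d_t * decay.sum(axis=1)
    return TemperatureTrace(time_s=times, temp_c=temp)


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic sample with its recordings and ground truth."""

    sample: CylindricalSample
    protocol: PulseProtocol
    diagnostic: PulseRecording
    ire: PulseRecording
    ground_truth_sigma_s_per_m: float
    ground_truth_sigma0_s_per_m: float


def _child_seed(seed: int, index: int) -> int:
    # deterministic, collision-resistant per-recording seed below 2**31
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def synth_cohort(
    group_specs: Sequence[tuple[str, DynamicConductivityModel, int]],
    protocol_fields: Optional[Sequence[FieldStrength]] = None,
    noise: Optional[NoiseSpec] = None,
    sample: Optional[CylindricalSample] = None,
    n_pulses: int = 100,
    pulse_width_s: float = DEFAULT_PULSE_WIDTH_S,
    repetition_period_s: float = DEFAULT_REPETITION_PERIOD_S,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    diagnostic_voltage_v: float = DEFAULT_DIAGNOSTIC_VOLTAGE_V,
) -> list[CohortRecord]:
    """Generate a full cohort: per group, ``n_samples`` samples per field.

    The default design matches the protocol the analysis expects: seven
    field strengths with one sample each (n = 7 recordings per group), each
    sample contributing one diagnostic and one 100-pulse train.  Each
    recording draws noise from a seed derived deterministically from the
    cohort seed, so the whole cohort is reproducible.
    """
    noise = noise or NoiseSpec()
    if protocol_fields is None:
        protocol_fields = [FieldStrength.from_v_per_cm(f) for f in DEFAULT_FIELDS_V_PER_CM]
    protocol_fields = list(protocol_fields)
    if not protocol_fields:
        raise ConfigError("protocol_fields must be non-empty")
    if not group_specs:
        raise ConfigError("need at least one group spec")
    base_geom = sample
    records: list[CohortRecord] = []
    counter = 0
    for tissue_label, model, n_samples in group_specs:
        if n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1, got {n_samples} for {tissue_label!r}")
        for rep in range(n_samples):
            for field in protocol_fields:
                sid = f"{tissue_label}-{field.v_per_cm:.0f}Vcm-{rep}"
                geom = (
                    CylindricalSample(sample_id=sid, tissue_label=tissue_label)
                    if base_geom is None
                    else replace(base_geom, sample_id=sid, tissue_label=tissue_label)
                )
                protocol = PulseProtocol(
                    n_pulses=n_pulses,
                    pulse_width_s=pulse_width_s,
                    repetition_period_s=repetition_period_s,
                    nominal_field=field,
                )
                diag = synth_diagnostic(
                    model,
                    geom,
                    voltage_v=diagnostic_voltage_v,
                    noise=replace(noise, seed=_child_seed(noise.seed, counter)),
                    pulse_width_s=pulse_width_s,
                    sampling_rate_hz=sampling_rate_hz,
                )
                ire = synth_pulse_train(
                    model,
                    geom,
                    protocol,
                    noise=replace(noise, seed=_child_seed(noise.seed, counter + 1)),
                    sampling_rate_hz=sampling_rate_hz,
                )
                diag_field = FieldStrength(diagnostic_voltage_v / geom.thickness_m)
                records.append(
                    CohortRecord(
                        sample=geom,
                        protocol=protocol,
                        diagnostic=diag,
                        ire=ire,
                        ground_truth_sigma_s_per_m=model.sigma_at(field),
                        ground_truth_sigma0_s_per_m=model.sigma_at(diag_field),
                    )
                )
                counter += 2
    return records
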