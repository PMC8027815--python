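"""Electrical impedance spectroscopy: sigma(f) from complex impedance.

The real part of the measured impedance, together with the geometric cell
constant of the cylindrical sample, gives the conductivity spectrum
``sigma(f) = K / Re Z(f)``.  Spectra are log-sampled in frequency, so point
queries (conventionally 10 kHz "low frequency" and 1 MHz "high frequency")
interpolate sigma piecewise-linearly in log10(f); queries outside the
measured range raise rather than extrapolate.

:class:`EISStudy` / :class:`EISResults` wrap the per-sample spectra into a
group-level analysis with query-frequency summaries and Welch comparisons
against reference (literature) conductivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateVarianceError,
    DomainError,
    ExtrapolationError,
    InvalidSpectrumError,
    ParseError,
)
from .geometry import CylindricalSample, cell_constant
from .stats import GroupSummary, summarize, welch_from_summary

__all__ = [
    "ImpedanceSpectrum",
    "ReferenceConductivity",
    "conductivity_spectrum",
    "conductivity_at",
    "compare_to_reference",
    "EISStudy",
    "EISResults",
]

SPECTRUM_COLUMNS = ("frequency_Hz", "Z_real_ohm", "Z_imag_ohm")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance versus frequency for one sample."""

    frequencies_hz: np.ndarray
    impedance_ohm: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        z = np.asarray(self.impedance_ohm, dtype=complex)
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "impedance_ohm", z)
        if len(f) != len(z) or len(f) == 0:
            raise InvalidSpectrumError("frequency and impedance lengths must match (>=1)")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise InvalidSpectrumError("frequencies must be positive, strictly increasing")
        if np.any(z.real <= 0):
            raise InvalidSpectrumError("Re(Z) must be > 0 at every frequency")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frequency_Hz": self.frequencies_hz,
                "Z_real_ohm": self.impedance_ohm.real,
                "Z_imag_ohm": self.impedance_ohm.imag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_id: str = "") -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        return cls(
            frequencies_hz=df["frequency_Hz"].to_numpy(dtype=float),
            impedance_ohm=df["Z_real_ohm"].to_numpy(dtype=float)
            + 1j * df["Z_imag_ohm"].to_numpy(dtype=float),
            sample_id=sample_id or str(path),
        )


@dataclass(frozen=True)
class ReferenceConductivity:
    """A published conductivity value for comparison (mean ± SD at one
    frequency for one tissue)."""

    tissue: str
    frequency_hz: float
    mean_s_per_m: float
    sd_s_per_m: float
    n: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.mean_s_per_m > 0:
            raise DomainError(f"reference mean must be > 0, got {self.mean_s_per_m}")
        if self.sd_s_per_m < 0:
            raise DomainError(f"reference sd must be >= 0, got {self.sd_s_per_m}")


def conductivity_spectrum(spec: ImpedanceSpectrum, sample: CylindricalSample) -> pd.Series:
    """Pointwise conductivity ``sigma(f) = K / Re Z(f)`` as a Series
    indexed by frequency (Hz)."""
    sigma = cell_constant(sample) / spec.impedance_ohm.real
    return pd.Series(sigma, index=pd.Index(spec.frequencies_hz, name="frequency_Hz"), name="sigma_S_per_m")


def conductivity_at(spec: ImpedanceSpectrum, sample: CylindricalSample, f_query_hz: float) -> float:
    """Conductivity at one frequency, piecewise-linear in log10(f).

    Exact at grid points; raises :class:`ExtrapolationError` outside the
    measured range (no silent extrapolation).
    """
    f = spec.frequencies_hz
    if not (f[0] <= f_query_hz <= f[-1]):
        raise ExtrapolationError(
            f"query {f_query_hz} Hz outside measured range [{f[0]}, {f[-1]}] Hz"
        )
    sigma = conductivity_spectrum(spec, sample).to_numpy()
    return float(np.interp(np.log10(f_query_hz), np.log10(f), sigma))


def compare_to_reference(
    values: Sequence[tuple[str, float, GroupSummary]],
    refs: Sequence[ReferenceConductivity],
) -> pd.DataFrame:
    """Welch-compare measured group summaries with reference values.

    ``values`` entries are ``(tissue, frequency_hz, GroupSummary)``.  Pairs
    are matched on tissue label and frequency (1e-6 relative); unmatched
    measurements appear in the output flagged ``compared=False`` rather than
    raising.
    """
    rows = []
    for tissue, freq, summ in values:
        match = next(
            (
                r
                for r in refs
                if r.tissue == tissue and np.isclose(r.frequency_hz, freq, rtol=1e-6)
            ),
            None,
        )
        row = {
            "tissue": tissue,
            "frequency_Hz": freq,
            "mean_S_per_m": summ.mean,
            "sd_S_per_m": summ.sd,
            "n": summ.n,
            "ref_mean_S_per_m": np.nan,
            "ref_sd_S_per_m": np.nan,
            "ref_n": np.nan,
            "difference_S_per_m": np.nan,
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "compared": False,
        }
        if match is not None and match.n is not None:
            try:
                ref_summary = GroupSummary(
                    label=match.tissue, n=match.n, mean=match.mean_s_per_m, sd=match.sd_s_per_m
                )
                welch = welch_from_summary(summ, ref_summary)
            except DegenerateVarianceError:
                # zero-variance or n < 2 group: report the pairing untested
                rows.append(row)
                continue
            row.update(
                ref_mean_S_per_m=match.mean_s_per_m,
                ref_sd_S_per_m=match.sd_s_per_m,
                ref_n=match.n,
                difference_S_per_m=summ.mean - match.mean_s_per_m,
                t=welch.t_statistic,
                df=welch.degrees_of_freedom,
                p=welch.p_value,
                compared=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results objects for the EIS workflow
# ---------------------------------------------------------------------------


class EISStudy:
    """Impedance-spectroscopy characterization of a group of samples.

    Parameters
    ----------
    spectra : sequence of (ImpedanceSpectrum, CylindricalSample)
        One measured spectrum per sample with its geometry.
    group : str
        Tissue label used when comparing against references.
    query_frequencies_hz : sequence of float
        Frequencies to report point conductivities at; defaults to the
        conventional 10 kHz (low) and 1 MHz (high).
    """

    def __init__(
        self,
        spectra: Sequence[tuple[ImpedanceSpectrum, CylindricalSample]],
        group: str = "group",
        query_frequencies_hz: Sequence[float] = (1e4, 1e6),
    ) -> None:
        if not spectra:
            raise DomainError("need at least one spectrum")
        self.spectra = list(spectra)
        self.group = group
        self.query_frequencies_hz = list(query_frequencies_hz)

    def fit(self) -> "EISResults":
        long_rows = []
        query_rows = []
        for spec, geom in self.spectra:
            sigma = conductivity_spectrum(spec, geom)
            for f, s in sigma.items():
                long_rows.append(
                    {"sample_id": spec.sample_id, "frequency_Hz": f, "sigma_S_per_m": s}
                )
            for fq in self.query_frequencies_hz:
                query_rows.append(
                    {
                        "sample_id": spec.sample_id,
                        "frequency_Hz": fq,
                        "sigma_S_per_m": conductivity_at(spec, geom, fq),
                    }
                )
        query_table = pd.DataFrame(query_rows)
        summaries = []
        for fq, sub in query_table.groupby("frequency_Hz"):
            summ = summarize(sub["sigma_S_per_m"].to_list(), label=self.group)
            summaries.append(
                {
                    "frequency_Hz": fq,
                    "n": summ.n,
                    "sigma_mean_S_per_m": summ.mean,
                    "sigma_sd_S_per_m": summ.sd,
                }
            )
        return EISResults(
            model=self,
            spectrum_table=pd.DataFrame(long_rows),
            query_table=query_table,
            summary_table=pd.DataFrame(summaries),
        )


@dataclass
class EISResults:
    """Fitted EIS characterization: sigma(f) per sample plus group summaries
    at the query frequencies."""

    model: EISStudy
    spectrum_table: pd.DataFrame
    query_table: pd.DataFrame
    summary_table: pd.DataFrame
    comparison_table: Optional[pd.DataFrame] = dc_field(default=None)

    def sigma_at(self, frequency_hz: float) -> GroupSummary:
        sub = self.query_table[np.isclose(self.query_table["frequency_Hz"], frequency_hz)]
        if sub.empty:
            raise DomainError(f"{frequency_hz} Hz is not one of the query frequencies")
        return summarize(sub["sigma_S_per_m"].to_list(), label=self.model.group)

    def compare(self, refs: Sequence[ReferenceConductivity]) -> pd.DataFrame:
        values = [
            (self.model.group, row["frequency_Hz"], self.sigma_at(row["frequency_Hz"]))
            for _, row in self.summary_table.iterrows()
        ]
        self.comparison_table = compare_to_reference(values, refs)
        return self.comparison_table

    def summary(self) -> str:
        lines = [
            f"Impedance-spectroscopy characterization: {self.model.group}",
            f"  samples: {len(self.model.spectra)}",
            "",
            self.summary_table.to_string(index=False),
        ]
        if self.comparison_table is not None:
            lines += ["", "Reference comparison (Welch):", self.comparison_table.to_string(index=False)]
        return "\n".join(lines)

    def plot(self, **kwargs):
        from .plotting import plot_sigma_spectra

        return plot_sigma_spectra(self, **kwargs)
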