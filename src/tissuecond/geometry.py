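"""Sample geometry and field/voltage conversions.

A tissue sample is held in an insulating cylindrical mold of radius ``r`` and
plate-to-plate thickness ``L`` between parallel-plate electrodes.  Under the
uniform-field approximation the applied field is ``E = V / L`` and the
geometric cell constant ``K = L / (pi r^2)`` converts a measured resistance to
a conductivity, ``sigma = K / R``.

All quantities are stored in SI units (m, V, A, S/m).  Field strengths are
commonly quoted in V/cm in the electroporation literature; the conversion
(factor of exactly 100) happens only at interface boundaries via
:class:`FieldStrength`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, GeometryError

__all__ = [
    "CylindricalSample",
    "FieldStrength",
    "cell_constant",
    "field_from_voltage",
    "voltage_for_field",
]

#: Default mold geometry used throughout: 3 mm radius, 0.56 cm thickness.
DEFAULT_RADIUS_M = 3e-3
DEFAULT_THICKNESS_M = 0.56e-2


@dataclass(frozen=True)
class FieldStrength:
    """An electric-field magnitude, stored in V/m.

    Construct from the literature's V/cm convention with
    :meth:`from_v_per_cm` and read it back via :attr:`v_per_cm`.
    """

    v_per_m: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.v_per_m) or self.v_per_m < 0:
            raise DomainError(f"field magnitude must be finite and >= 0, got {self.v_per_m}")

    @classmethod
    def from_v_per_cm(cls, value: float) -> "FieldStrength":
        return cls(float(value) * 100.0)

    @property
    def v_per_cm(self) -> float:
        return self.v_per_m / 100.0


@dataclass(frozen=True)
class CylindricalSample:
    """A cylindrical tissue sample between parallel-plate electrodes.

    Parameters
    ----------
    sample_id : str
        Opaque label identifying the physical sample.
    tissue_label : str
        Free-text tissue description, e.g. ``"Panc01 tumor"``.
    radius_m : float
        Mold radius in meters (default 3 mm).
    thickness_m : float
        Plate-to-plate distance in meters (default 0.56 cm).
    """

    sample_id: str
    tissue_label: str = ""
    radius_m: float = DEFAULT_RADIUS_M
    thickness_m: float = DEFAULT_THICKNESS_M

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius_m) and self.radius_m > 0):
            raise GeometryError(f"radius must be > 0, got {self.radius_m}")
        if not (math.isfinite(self.thickness_m) and self.thickness_m > 0):
            raise GeometryError(f"thickness must be > 0, got {self.thickness_m}")

    @property
    def area_m2(self) -> float:
        """Electrode-facing cross-section, ``pi r^2``."""
        return math.pi * self.radius_m**2

    @classmethod
    def from_config(cls, entry: dict) -> "CylindricalSample":
        """Build from a config mapping with unit-suffixed keys.

        Expected keys: ``sample_id``, ``tissue_label``, ``radius_mm``,
        ``thickness_cm`` (units as named in the key).
        """
        return cls(
            sample_id=str(entry["sample_id"]),
            tissue_label=str(entry.get("tissue_label", "")),
            radius_m=float(entry.get("radius_mm", DEFAULT_RADIUS_M * 1e3)) * 1e-3,
            thickness_m=float(entry.get("thickness_cm", DEFAULT_THICKNESS_M * 1e2)) * 1e-2,
        )


def cell_constant(sample: CylindricalSample) -> float:
    """Geometric cell constant ``K = L / (pi r^2)`` in 1/m.

    For the default mold (r = 3 mm, L = 0.56 cm) this is about 198.06 1/m.
    """
    return sample.thickness_m / sample.area_m2


def field_from_voltage(voltage_v: float, sample: CylindricalSample) -> FieldStrength:
    """Uniform-field strength ``E = V / L`` for a plate voltage in volts."""
    if not math.isfinite(voltage_v) or voltage_v < 0:
        raise DomainError(f"voltage must be finite and >= 0, got {voltage_v}")
    return FieldStrength(voltage_v / sample.thickness_m)


def voltage_for_field(field: FieldStrength, sample: CylindricalSample) -> float:
    """Plate voltage ``V = E * L`` realizing a nominal field strength."""
    return field.v_per_m * sample.thickness_m
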