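"""Physical constants and the package-wide unit system.

Internal conventions used throughout :mod:`memkappa`:

* lengths in angstrom (Å), wave vectors in Å⁻¹;
* bending modulus κ in units of the thermal energy ``kBT``;
* smectic compression modulus B in ``kBT/Å⁴``;
* area-compressibility K_A and tilt modulus K_t in ``mN/m`` at the public
  interface, ``kBT/Å²`` internally.

These choices make the Caillé parameter and all spectrum prefactors
dimensionless or O(1), and they match how membrane elasticity results are
conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BOLTZMANN",
    "T_DEFAULT",
    "T_DLS_DEFAULT",
    "Thermo",
    "ModulusValue",
    "thermal_energy",
    "convert_modulus",
    "mn_per_m_to_kbt_per_ang2",
    "kbt_per_ang2_to_mn_per_m",
    "d_spacing_from_q1",
    "q1_from_d_spacing",
]

#: CODATA Boltzmann constant, J/K (exact since the 2019 SI redefinition).
BOLTZMANN = 1.380649e-23

#: Default temperature: 37 °C, the physiological measurement temperature.
T_DEFAULT = 310.15

#: Default temperature for dynamic light scattering (25 °C).
T_DLS_DEFAULT = 298.15

# 1 mN/m = 1e-3 J/m^2 = 1e-23 J/Å^2
_J_PER_ANG2_PER_MN_PER_M = 1.0e-23


def thermal_energy(T: float) -> float:
    """Thermal energy k_B·T in joule.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin; must be positive.
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got T={T!r} K")
    return BOLTZMANN * T


@dataclass(frozen=True)
class Thermo:
    """Thermodynamic state: a temperature and its thermal energy."""

    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        thermal_energy(self.T)  # validates T > 0

    @property
    def kBT(self) -> float:
        """Thermal energy in joule."""
        return BOLTZMANN * self.T


#: Supported modulus unit labels.
MODULUS_UNITS = ("kBT", "kBT/A^4", "mN/m", "kBT/A^2")


@dataclass(frozen=True)
class ModulusValue:
    """An elastic modulus tagged with its units.

    ``units`` is one of ``kBT`` (bending), ``kBT/A^4`` (smectic compression),
    ``mN/m`` or ``kBT/A^2`` (area-compressibility or tilt).
    """

    value: float
    units: str

    def __post_init__(self) -> None:
        if self.units not in MODULUS_UNITS:
            raise ValueError(
                f"unknown modulus units {self.units!r}; expected one of {MODULUS_UNITS}"
            )


def mn_per_m_to_kbt_per_ang2(value: float, T: float = T_DEFAULT) -> float:
    """Convert a surface modulus from mN/m to kBT/Å² at temperature ``T``."""
    return value * _J_PER_ANG2_PER_MN_PER_M / thermal_energy(T)


def kbt_per_ang2_to_mn_per_m(value: float, T: float = T_DEFAULT) -> float:
    """Convert a surface modulus from kBT/Å² to mN/m at temperature ``T``."""
    return value * thermal_energy(T) / _J_PER_ANG2_PER_MN_PER_M


def convert_modulus(m: ModulusValue, target_units: str, T: float = T_DEFAULT) -> ModulusValue:
    """Convert a :class:`ModulusValue` between supported unit pairs.

    Supported conversions: identity, and ``mN/m`` ↔ ``kBT/A^2`` (which needs
    the temperature because the kBT energy scale enters). Converting between
    physically incompatible units (e.g. bending κ in kBT to a surface modulus)
    raises ``ValueError`` naming both units.
    """
    if target_units not in MODULUS_UNITS:
        raise ValueError(
            f"unknown target units {target_units!r}; expected one of {MODULUS_UNITS}"
        )
    if m.units == target_units:
        return ModulusValue(m.value, target_units)
    pair = (m.units, target_units)
    if pair == ("mN/m", "kBT/A^2"):
        return ModulusValue(mn_per_m_to_kbt_per_ang2(m.value, T), target_units)
    if pair == ("kBT/A^2", "mN/m"):
        return ModulusValue(kbt_per_ang2_to_mn_per_m(m.value, T), target_units)
    raise ValueError(
        f"unsupported modulus conversion from {m.units!r} to {target_units!r}"
    )


def d_spacing_from_q1(q1: float) -> float:
    """Lamellar repeat spacing d = 2π/q₁ (Å) from the first-order peak (Å⁻¹)."""
    if not q1 > 0:
        raise ValueError(f"q1 must be positive, got {q1!r}")
    import math

    return 2.0 * math.pi / q1


def q1_from_d_spacing(d: float) -> float:
    """First-order lamellar peak position q₁ = 2π/d (Å⁻¹)."""
    if not d > 0:
        raise ValueError(f"d must be positive, got {d!r}")
    import math

    return 2.0 * math.pi / d
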