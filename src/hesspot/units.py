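"""Unit registry and conversion for the quantities the package touches.

Dimensions are tracked as powers of (energy, length); every energy-like unit
is molar.  A force is energy/length, a curvature (Hessian element)
energy/length**2.  Conversion is exact (CODATA factors, no rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import BOHR_TO_ANGSTROM, EV_TO_KCALMOL, HARTREE_TO_KCALMOL


class UnitError(ValueError):
    """Raised for unknown units or dimensionally incompatible conversions."""


# name -> (dims (energy_power, length_power), factor to internal base units)
# internal base: kcal/mol for energy, angstrom for length.
_REGISTRY: dict[str, tuple[tuple[int, int], float]] = {}


def _register(names: tuple[str, ...], dims: tuple[int, int], factor: float) -> None:
    for n in names:
        _REGISTRY[n] = (dims, factor)


_register(("kcal_per_mol", "kcal/mol"), (1, 0), 1.0)
_register(("hartree", "Eh"), (1, 0), HARTREE_TO_KCALMOL)
_register(("eV", "ev"), (1, 0), EV_TO_KCALMOL)
_register(("angstrom", "A", "Ang"), (0, 1), 1.0)
_register(("bohr", "Bohr"), (0, 1), BOHR_TO_ANGSTROM)

# force-like: energy / length
_register(("kcal_per_mol_per_angstrom", "kcal/mol/A"), (1, -1), 1.0)
_register(("hartree_per_bohr", "hartree/bohr", "Eh/bohr"), (1, -1),
          HARTREE_TO_KCALMOL / BOHR_TO_ANGSTROM)
_register(("eV_per_angstrom", "eV/A", "ev/A"), (1, -1), EV_TO_KCALMOL)

# curvature-like: energy / length**2
_register(("kcal_per_mol_per_angstrom2", "kcal/mol/A^2"), (1, -2), 1.0)
_register(("hartree_per_bohr2", "hartree/bohr^2"), (1, -2),
          HARTREE_TO_KCALMOL / BOHR_TO_ANGSTROM**2)
_register(("eV_per_angstrom2", "eV/A^2", "ev/A^2"), (1, -2),
          EV_TO_KCALMOL)


def _lookup(unit: str) -> tuple[tuple[int, int], float]:
    try:
        return _REGISTRY[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def convert_quantity(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two registered units.

    Raises :class:`UnitError` if the units carry different dimensions,
    naming both units.
    """
    dims_f, fac_f = _lookup(from_unit)
    dims_t, fac_t = _lookup(to_unit)
    if dims_f != dims_t:
        raise UnitError(
            f"incompatible dimensions: {from_unit!r} {dims_f} vs {to_unit!r} {dims_t}"
        )
    return value * fac_f / fac_t


@dataclass(frozen=True)
class UnitQuantity:
    """A scalar with an explicit unit tag."""

    value: float
    unit: str

    def to(self, unit: str) -> "UnitQuantity":
        return UnitQuantity(convert_quantity(self.value, self.unit, unit), unit)
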