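"""Unit presets.

Two global presets are provided:

``reduced``
    Dimensionless units with ``k_B = 1``; thermal energy equals the
    temperature parameter directly.  All bundled example systems use
    this preset.

``real``
    Angstrom / femtosecond / kcal·mol^-1 / g·mol^-1, the conventional
    small-molecule set.  ``mvv2e`` converts ``m v^2`` to energy units
    (1 g/mol * (A/fs)^2 = 1e7 J/mol = 2390.0574 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["UnitSystem", "REDUCED", "REAL", "get_units"]


@dataclass(frozen=True)
class UnitSystem:
    name: str
    kB: float      # Boltzmann constant in energy/temperature units
    mvv2e: float   # factor converting mass*velocity^2 to energy units


REDUCED = UnitSystem("reduced", kB=1.0, mvv2e=1.0)
REAL = UnitSystem("real", kB=0.0019872041, mvv2e=1.0e7 / 4184.0)

_PRESETS = {u.name: u for u in (REDUCED, REAL)}


def get_units(name: str) -> UnitSystem:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown unit preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
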