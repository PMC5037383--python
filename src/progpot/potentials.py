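"""One-dimensional pairwise interaction potentials phi(r).

Conventions
-----------
The Morse bond is written

    phi(r) = D * (1 - exp(-a*(r - r_eq)))**2 - D,

so the minimum is ``-D`` at ``r_eq`` and the potential tends to 0 at
infinity: the parameter ``D`` is then literally the dissociation energy,
the work needed to separate a bonded pair.  The transition-state
electron-repulsion term is the repulsive branch of the same Morse
potential shifted up by ``D`` and spliced to exactly 0 beyond ``r_eq``
(value and slope both vanish there, so the splice is C^1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PairPotential",
    "Morse",
    "RepulsiveMorse",
    "Harmonic",
    "Tabulated",
    "pair_energy",
    "pair_force_mag",
    "repulsive_part",
]


class PairPotential:
    """Base class: finite energy/derivative for all r > 0, finite limit at infinity."""

    def energy(self, r: float) -> float:
        raise NotImplementedError

    def dphi_dr(self, r: float) -> float:
        raise NotImplementedError

    @staticmethod
    def _check(r: float) -> float:
        r = float(r)
        if r <= 0:
            raise ValueError(f"pair distance must be positive, got {r}")
        return r


@dataclass(frozen=True)
class Morse(PairPotential):
    """Anharmonic bond: depth D (energy), width a (1/length), minimum at r_eq."""

    D: float
    a: float
    r_eq: float

    def __post_init__(self) -> None:
        if self.D <= 0 or self.a <= 0 or self.r_eq <= 0:
            raise ValueError("Morse parameters D, a, r_eq must all be positive")

    def energy(self, r: float) -> float:
        r = self._check(r)
        e = math.exp(-self.a * (r - self.r_eq))
        return self.D * (1.0 - e) ** 2 - self.D

    def dphi_dr(self, r: float) -> float:
        r = self._check(r)
        e = math.exp(-self.a * (r - self.r_eq))
        return 2.0 * self.D * self.a * e * (1.0 - e)


@dataclass(frozen=True)
class RepulsiveMorse(PairPotential):
    """Repulsive branch of a Morse bond: phi_morse(r) + D for r < r_eq, else 0."""

    D: float
    a: float
    r_eq: float

    def __post_init__(self) -> None:
        if self.D <= 0 or self.a <= 0 or self.r_eq <= 0:
            raise ValueError("Morse parameters D, a, r_eq must all be positive")

    def energy(self, r: float) -> float:
        r = self._check(r)
        if r >= self.r_eq:
            return 0.0
        e = math.exp(-self.a * (r - self.r_eq))
        return self.D * (1.0 - e) ** 2

    def dphi_dr(self, r: float) -> float:
        r = self._check(r)
        if r >= self.r_eq:
            return 0.0
        e = math.exp(-self.a * (r - self.r_eq))
        return 2.0 * self.D * self.a * e * (1.0 - e)


@dataclass(frozen=True)
class Harmonic(PairPotential):
    """Stiff spring 0.5*k*(r - r0)**2, used for intra-entity constraint bonds."""

    k: float
    r0: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.r0 <= 0:
            raise ValueError("harmonic bond needs k >= 0 and r0 > 0")

    def energy(self, r: float) -> float:
        r = self._check(r)
        return 0.5 * self.k * (r - self.r0) ** 2

    def dphi_dr(self, r: float) -> float:
        r = self._check(r)
        return self.k * (r - self.r0)


class Tabulated(PairPotential):
    """Monotone-cubic (PCHIP) interpolation of sampled (r, phi) values.

    Outside the sampled range the potential is clamped flat at the
    boundary values, keeping the r -> infinity limit finite.
    """

    def __init__(self, r_grid, phi_grid):
        r_grid = np.asarray(r_grid, dtype=float)
        phi_grid = np.asarray(phi_grid, dtype=float)
        if r_grid.ndim != 1 or r_grid.shape != phi_grid.shape or r_grid.size < 2:
            raise ValueError("need matching 1-D grids with at least two samples")
        if np.any(r_grid <= 0) or np.any(np.diff(r_grid) <= 0):
            raise ValueError("r grid must be positive and strictly increasing")
        self.r_grid = r_grid
        self.phi_grid = phi_grid
        self._interp = PchipInterpolator(r_grid, phi_grid, extrapolate=False)
        self._deriv = self._interp.derivative()

    def energy(self, r: float) -> float:
        r = self._check(r)
        if r <= self.r_grid[0]:
            return float(self.phi_grid[0])
        if r >= self.r_grid[-1]:
            return float(self.phi_grid[-1])
        return float(self._interp(r))

    def dphi_dr(self, r: float) -> float:
        r = self._check(r)
        if r <= self.r_grid[0] or r >= self.r_grid[-1]:
            return 0.0
        return float(self._deriv(r))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Tabulated)
            and np.array_equal(self.r_grid, other.r_grid)
            and np.array_equal(self.phi_grid, other.phi_grid)
        )


def pair_energy(r: float, spec: PairPotential) -> float:
    """Energy of a pairwise potential at separation r (> 0)."""
    return spec.energy(r)


def pair_force_mag(r: float, spec: PairPotential) -> float:
    """Radial force magnitude -dphi/dr; positive means repulsive."""
    return -spec.dphi_dr(r)


def repulsive_part(m: Morse) -> RepulsiveMorse:
    """Transition-state repulsion: the bond's repulsive branch, same parameters."""
    return RepulsiveMorse(D=m.D, a=m.a, r_eq=m.r_eq)
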