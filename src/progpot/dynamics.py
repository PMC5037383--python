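"""Time integration of the switched N-body potential.

Two integrators are provided.  ``run_verlet`` is symplectic velocity
Verlet for the deterministic Hamiltonian system (external forces
neglected) and is the tool for energy-conservation checks; it requires
exact gradients, i.e. ``full`` force mode.  ``run_langevin`` is the
primary simulation mode: underdamped Langevin dynamics at constant
temperature, discretized with the BAOAB splitting (half kick, half
drift, Ornstein-Uhlenbeck velocity refresh, half drift, half kick),
which has the best configurational accuracy at large time steps among
the standard splittings.

Randomness is fully seeded: the run seed is split into independent
streams for velocity initialization and thermostat noise, so identical
parameters give bitwise-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assembly import ForceMode, System
from .logic import AtomPair, Configuration

__all__ = [
    "IntegratorParams",
    "Trajectory",
    "IntegrationError",
    "maxwell_boltzmann_velocities",
    "run_verlet",
    "run_langevin",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


@dataclass
class IntegratorParams:
    dt: float = 0.005
    n_steps: int = 10_000
    temperature: float = 1.0     # in K for the real preset, energy units for reduced
    friction: float = 1.0        # Langevin gamma, 1/time
    seed: int = 0
    force_mode: ForceMode | None = None   # None: use the system's default
    stride: int = 10             # record every this many steps

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded time series with per-term energy bookkeeping."""

    times: np.ndarray                  # (F,)
    positions: np.ndarray              # (F, N, d)
    velocities: np.ndarray             # (F, N, d)
    potential: np.ndarray              # (F,)
    kinetic: np.ndarray                # (F,)
    term_labels: list[str]
    term_S: np.ndarray                 # (F, T)
    term_phi: np.ndarray               # (F, T)
    events: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    def configuration(self, frame: int) -> Configuration:
        return Configuration(self.positions[frame].copy())

    def pair_distance(self, p: AtomPair) -> np.ndarray:
        """Distance of a particle pair at every recorded frame."""
        delta = self.positions[:, p.i - 1, :] - self.positions[:, p.j - 1, :]
        return np.linalg.norm(delta, axis=1)


def maxwell_boltzmann_velocities(
    system: System, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities drawn from the Maxwell-Boltzmann distribution at T."""
    kT = system.units.kB * temperature
    sigma = np.sqrt(kT / (system.units.mvv2e * system.masses))
    return rng.standard_normal((system.n_particles, system.dim)) * sigma[:, None]


class _Recorder:
    def __init__(self, system: System, mode: ForceMode) -> None:
        self.system = system
        self.mode = mode
        self.times: list[float] = []
        self.xs: list[np.ndarray] = []
        self.vs: list[np.ndarray] = []
        self.us: list[float] = []
        self.ks: list[float] = []
        self.Ss: list[list[float]] = []
        self.phis: list[list[float]] = []
        self.labels = [t.label for t in system.terms]

    def record(self, t: float, x: np.ndarray, v: np.ndarray) -> None:
        cfg = Configuration(x.copy())
        u, rows = self.system.total_energy(cfg, breakdown=True)
        ke = 0.5 * self.system.units.mvv2e * float(
            np.sum(self.system.masses[:, None] * v * v)
        )
        self.times.append(t)
        self.xs.append(x.copy())
        self.vs.append(v.copy())
        self.us.append(u)
        self.ks.append(ke)
        self.Ss.append([row.S for row in rows])
        self.phis.append([row.phi for row in rows])

    def finish(self, events: list[str]) -> Trajectory:
        n_terms = len(self.labels)
        return Trajectory(
            times=np.asarray(self.times),
            positions=np.asarray(self.xs),
            velocities=np.asarray(self.vs),
            potential=np.asarray(self.us),
            kinetic=np.asarray(self.ks),
            term_labels=self.labels,
            term_S=np.asarray(self.Ss).reshape(len(self.times), n_terms),
            term_phi=np.asarray(self.phis).reshape(len(self.times), n_terms),
            events=events,
        )


def _guard(x: np.ndarray, step: int, dt: float) -> None:
    if not np.all(np.isfinite(x)):
        bad = int(np.argwhere(~np.isfinite(x))[0][0]) + 1
        raise IntegrationError(
            f"non-finite coordinate for particle {bad} at step {step} "
            f"(dt={dt} is likely too large)"
        )


def run_verlet(
    system: System,
    config0: Configuration,
    velocities0: np.ndarray | Sequence[Sequence[float]],
    params: IntegratorParams,
) -> Trajectory:
    """Deterministic symplectic velocity-Verlet integration (NVE)."""
    mode: ForceMode = params.force_mode or system.force_mode
    if mode != "full":
        raise ValueError(
            "Verlet needs exact gradients: use force mode 'full' "
            "(frozen_switch forces are not conservative)"
        )
    x = config0.positions.copy()
    v = np.array(velocities0, dtype=float).reshape(x.shape)
    inv_m = 1.0 / (system.units.mvv2e * system.masses)[:, None]
    dt = params.dt

    rec = _Recorder(system, mode)
    events: list[str] = []
    f = system.forces_raw(x, mode)
    rec.record(0.0, x, v)
    for step in range(1, params.n_steps + 1):
        v += 0.5 * dt * f * inv_m
        x += dt * v
        _guard(x, step, dt)
        f = system.forces_raw(x, mode)
        v += 0.5 * dt * f * inv_m
        if step % params.stride == 0 or step == params.n_steps:
            rec.record(step * dt, x, v)
    return rec.finish(events)


def run_langevin(
    system: System,
    config0: Configuration,
    params: IntegratorParams,
    velocities0: np.ndarray | None = None,
) -> Trajectory:
    """Langevin dynamics at constant temperature via the BAOAB splitting.

    Velocities are initialized from the Maxwell-Boltzmann distribution
    unless given explicitly.  With ``friction = 0`` and ``temperature =
    0`` the scheme reduces to velocity Verlet.
    """
    mode: ForceMode = params.force_mode or system.force_mode
    seeds = np.random.SeedSequence(params.seed).spawn(2)
    init_rng = np.random.default_rng(seeds[0])
    noise_rng = np.random.default_rng(seeds[1])

    x = config0.positions.copy()
    if velocities0 is None:
        v = maxwell_boltzmann_velocities(system, params.temperature, init_rng)
    else:
        v = np.array(velocities0, dtype=float).reshape(x.shape)

    m_eff = (system.units.mvv2e * system.masses)[:, None]
    inv_m = 1.0 / m_eff
    dt = params.dt
    kT = system.units.kB * params.temperature
    c1 = math.exp(-params.friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma = np.sqrt(kT * inv_m)

    rec = _Recorder(system, mode)
    events: list[str] = []
    f = system.forces_raw(x, mode)
    rec.record(0.0, x, v)
    for step in range(1, params.n_steps + 1):
        v += 0.5 * dt * f * inv_m                      # B
        x += 0.5 * dt * v                              # A
        if params.friction > 0:                        # O
            v = c1 * v + c2 * sigma * noise_rng.standard_normal(v.shape)
        x += 0.5 * dt * v                              # A
        _guard(x, step, dt)
        f = system.forces_raw(x, mode)
        v += 0.5 * dt * f * inv_m                      # B
        if step % params.stride == 0 or step == params.n_steps:
            rec.record(step * dt, x, v)
    return rec.finish(events)
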