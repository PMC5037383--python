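"""Trajectory post-processing and quasi-static probes.

Bond states are read from pair distances with a two-threshold
hysteresis: a pair becomes *formed* when its distance first drops below
``r_on`` and *broken* only when it later exceeds ``r_off > r_on``.
Under thermal jitter a single threshold would chatter; the hysteresis
band (defaults 1.2 x and 2.0 x the bond's equilibrium length) makes
occupancy fractions and event sequences well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import integrate

from .assembly import System
from .dynamics import Trajectory
from .logic import AtomPair, Configuration

__all__ = [
    "BondEvent",
    "bound_state_series",
    "bond_occupancy",
    "event_sequence",
    "binding_order_at_completion",
    "dissociation_work_probe",
    "energy_surface_scan",
]

#: default hysteresis thresholds relative to a bond's equilibrium length
R_ON_FACTOR = 1.2
R_OFF_FACTOR = 2.0


@dataclass(frozen=True)
class BondEvent:
    pair: AtomPair
    kind: Literal["formed", "broken"]
    time: float
    frame: int


def bound_state_series(
    distances: np.ndarray, r_on: float, r_off: float, debounce: int = 1
) -> np.ndarray:
    """Hysteresis-filtered bound/unbound state per frame.

    The state starts bound iff the first distance is below ``r_on``.
    Runs of identical state shorter than ``debounce`` frames are
    absorbed into the preceding state, suppressing single-frame flickers.
    """
    if r_off <= r_on:
        raise ValueError(f"hysteresis needs r_off > r_on, got {r_on} >= {r_off}")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty trajectory")
    state = np.empty(distances.size, dtype=bool)
    bound = bool(distances[0] < r_on)
    for k, r in enumerate(distances):
        if bound and r > r_off:
            bound = False
        elif not bound and r < r_on:
            bound = True
        state[k] = bound
    if debounce > 1:
        state = _debounce(state, debounce)
    return state


def _debounce(state: np.ndarray, window: int) -> np.ndarray:
    out = state.copy()
    k = 0
    n = out.size
    while k < n:
        j = k
        while j < n and out[j] == out[k]:
            j += 1
        run = j - k
        if k > 0 and run < window and j < n:  # interior short run: absorb
            out[k:j] = out[k - 1]
        k = j
    return out


def bond_occupancy(
    traj: Trajectory,
    pair: AtomPair,
    r_on: float,
    r_off: float | None = None,
    debounce: int = 1,
) -> float:
    """Fraction of recorded frames in which the pair is bound."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if r_off is None:
        r_off = r_on * (R_OFF_FACTOR / R_ON_FACTOR)
    state = bound_state_series(traj.pair_distance(pair), r_on, r_off, debounce)
    return float(np.mean(state))


def event_sequence(
    traj: Trajectory,
    pairs: Sequence[AtomPair],
    r_on: float,
    r_off: float,
    debounce: int = 1,
) -> list[BondEvent]:
    """Chronologically ordered formed/broken events for the given pairs."""
    if r_off <= r_on:
        raise ValueError(f"hysteresis needs r_off > r_on, got {r_on} >= {r_off}")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    events: list[BondEvent] = []
    for p in pairs:
        state = bound_state_series(traj.pair_distance(p), r_on, r_off, debounce)
        for k in range(1, state.size):
            if state[k] != state[k - 1]:
                kind = "formed" if state[k] else "broken"
                events.append(BondEvent(p, kind, float(traj.times[k]), k))
    events.sort(key=lambda e: (e.time, str(e.pair)))
    return events


def binding_order_at_completion(
    traj: Trajectory,
    pairs: Sequence[AtomPair],
    r_on: float,
    r_off: float,
    debounce: int = 1,
    switch: dict[AtomPair, np.ndarray] | None = None,
) -> list[AtomPair] | None:
    """Order in which the pairs formed the bonds that persist to completion.

    Completion is the first frame at which every pair is simultaneously
    in the hysteresis-bound state; ``None`` if that never happens.  The
    binding time of a pair is the start of its bound interval covering
    the last bound frame at or before completion — transient early
    passages that do not persist are ignored, which is the reading of a
    distance-trace figure: a bond forms when its dip lasts.

    If ``switch`` maps pairs to their per-frame encoding values, a bond
    instead forms at the first frame where the pair is within ``r_on``
    *while its switch exceeds 1/2* — the designed-bond reading, which
    distinguishes an engaged potential from coincidental proximity
    (relevant in crowded systems where unbonded particles may linger
    within the hysteresis band).  Completion then means every pair
    experienced its designed bond.
    """
    if switch is not None:
        starts = []
        for p in pairs:
            engaged = (traj.pair_distance(p) < r_on) & (
                np.asarray(switch[p]) > 0.5
            )
            idx = np.flatnonzero(engaged)
            if idx.size == 0:
                return None  # this bond never formed as designed
            starts.append((int(idx[0]), p))
        starts.sort(key=lambda kp: kp[0])
        return [p for _, p in starts]

    dist_states = {
        p: bound_state_series(traj.pair_distance(p), r_on, r_off, debounce)
        for p in pairs
    }
    all_bound = np.logical_and.reduce(list(dist_states.values()))
    if not np.any(all_bound):
        return None
    t_star = int(np.argmax(all_bound))
    starts = []
    for p in pairs:
        s = dist_states[p]
        k = t_star
        while k > 0 and s[k - 1]:
            k -= 1
        starts.append((k, p))
    starts.sort(key=lambda kp: kp[0])
    return [p for _, p in starts]


def dissociation_work_probe(
    system: System,
    config: Configuration,
    mover: int,
    anchor: int,
    r_start: float,
    r_end: float,
    direction: np.ndarray | None = None,
    epsabs: float = 1e-9,
    epsrel: float = 1e-9,
) -> float:
    """Quasi-static work to push ``mover`` from ``r_start`` to ``r_end``
    away-from/towards ``anchor`` along a straight line.

    The mover's entire entity is translated rigidly (so its internal
    constraint bonds stay at rest); every other particle stays frozen at
    its position in ``config``.  The work input is the line integral of
    the (negated) system force on the moved entity along the path,
    evaluated with adaptive quadrature of the exact full-mode gradient.
    For a switched bond held at its equilibrium length, driving the
    attacking particle well inside the switch-off radius must supply the
    bond's dissociation energy.
    """
    if r_start <= 0 or r_end <= 0:
        raise ValueError("path endpoints must be positive distances")
    x0 = config.positions.copy()
    a_xy = x0[anchor - 1]
    group = _entity_particles(system, mover)
    if anchor in group:
        raise ValueError("anchor must belong to a different entity than the mover")
    if direction is None:
        delta = x0[mover - 1] - a_xy
        nrm = float(np.linalg.norm(delta))
        if nrm == 0:
            raise ValueError("mover coincides with anchor; give a direction")
        direction = delta / nrm
    else:
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
    rows = [pid - 1 for pid in group]

    def radial_force(r: float) -> float:
        x = x0.copy()
        shift = (a_xy + r * direction) - x0[mover - 1]
        x[rows] = x0[rows] + shift
        f = system.forces(Configuration(x), mode="full")
        return float(f[rows].sum(axis=0) @ direction)

    lo, hi = sorted((r_end, r_start))
    work, err = integrate.quad(
        radial_force, lo, hi, epsabs=epsabs, epsrel=epsrel, limit=400
    )
    if not math.isfinite(work):
        raise RuntimeError("quadrature failed: non-finite work along the path")
    # pushing inward (r_start > r_end) against force F(r) costs +int F dr
    return work if r_start > r_end else -work


def _entity_particles(system: System, pid: int) -> tuple[int, ...]:
    for ent in system.entities:
        if pid in ent.particles:
            return ent.particles
    raise ValueError(f"particle {pid} is not declared in the system")


def energy_surface_scan(
    system: System,
    config: Configuration,
    movers: tuple[int, int],
    anchors: tuple[int, int],
    r_x: np.ndarray,
    r_y: np.ndarray,
    directions: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Potential energy on a 2-D grid of two pair separations.

    Entry ``[i, j]`` is the total energy with the first mover placed at
    distance ``r_x[i]`` from its anchor and the second at ``r_y[j]``
    from its anchor, along fixed directions (default: the directions in
    the reference configuration).  Each mover's entity translates
    rigidly with it; all remaining coordinates stay frozen.
    """
    r_x = np.asarray(r_x, dtype=float)
    r_y = np.asarray(r_y, dtype=float)
    if np.any(r_x <= 0) or np.any(r_y <= 0):
        raise ValueError("scan grid must keep pair distances positive")
    x0 = config.positions.copy()
    dirs = []
    groups = []
    for k, (m, a) in enumerate(zip(movers, anchors)):
        if directions is not None:
            u = np.asarray(directions[k], dtype=float)
        else:
            u = x0[m - 1] - x0[a - 1]
        nrm = float(np.linalg.norm(u))
        if nrm == 0:
            raise ValueError("mover coincides with anchor; give directions")
        dirs.append(u / nrm)
        groups.append([pid - 1 for pid in _entity_particles(system, m)])

    U = np.empty((r_x.size, r_y.size))
    x = x0.copy()
    for i, rx in enumerate(r_x):
        shift_x = (x0[anchors[0] - 1] + rx * dirs[0]) - x0[movers[0] - 1]
        x[groups[0]] = x0[groups[0]] + shift_x
        for j, ry in enumerate(r_y):
            shift_y = (x0[anchors[1] - 1] + ry * dirs[1]) - x0[movers[1] - 1]
            x[groups[1]] = x0[groups[1]] + shift_y
            U[i, j] = system.total_energy(Configuration(x))
    return U
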