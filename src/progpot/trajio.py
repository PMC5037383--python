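"""Trajectory and energy serialization: XYZ frames and CSV tables."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .analysis import BondEvent
from .assembly import System
from .dynamics import Trajectory

__all__ = [
    "site_labels",
    "write_xyz",
    "read_xyz",
    "write_energies_csv",
    "write_events_csv",
]


def site_labels(system: System) -> list[str]:
    """Entity-site labels in particle-id order, e.g. ``A1, A2, B1, ...``."""
    labels = [""] * system.n_particles
    for ent in system.entities:
        for k, pid in enumerate(ent.particles, start=1):
            labels[pid - 1] = f"{ent.name}{k}"
    return labels


def write_xyz(traj: Trajectory, path: str | Path, labels: Sequence[str]) -> None:
    """Standard multi-frame XYZ; 2-D configurations get z = 0.

    Each frame: atom-count line, comment line carrying the time and
    total energy, then one ``label x y z`` line per particle.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    n = traj.positions.shape[1]
    if len(labels) != n:
        raise ValueError(f"need {n} labels, got {len(labels)}")
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(
                f"t={float(traj.times[f])!r} U={float(traj.potential[f])!r} "
                f"E={float(traj.total_energy[f])!r}\n"
            )
            for i in range(n):
                xyz = list(traj.positions[f, i]) + [0.0] * (3 - traj.positions.shape[2])
                fh.write(f"{labels[i]} {xyz[0]:.10g} {xyz[1]:.10g} {xyz[2]:.10g}\n")


def read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a multi-frame XYZ file back as (times, positions, labels)."""
    times, frames = [], []
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k])
        comment = lines[k + 1]
        t = 0.0
        for tokenpair in comment.split():
            if tokenpair.startswith("t="):
                t = float(tokenpair[2:])
        rows, labs = [], []
        for line in lines[k + 2 : k + 2 + n]:
            parts = line.split()
            labs.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        times.append(t)
        frames.append(rows)
        labels = labs
        k += 2 + n
    return np.asarray(times), np.asarray(frames), labels


def write_energies_csv(traj: Trajectory, path: str | Path) -> None:
    """One row per recorded frame: time, energies, and per-term S / phi /
    S*phi bookkeeping columns."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    header = ["frame", "time", "potential", "kinetic", "total"]
    for label in traj.term_labels:
        header += [f"S[{label}]", f"phi[{label}]", f"Sphi[{label}]"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for f in range(traj.n_frames):
            row = [
                f,
                repr(float(traj.times[f])),
                repr(float(traj.potential[f])),
                repr(float(traj.kinetic[f])),
                repr(float(traj.total_energy[f])),
            ]
            for t in range(len(traj.term_labels)):
                s = float(traj.term_S[f, t])
                phi = float(traj.term_phi[f, t])
                row += [repr(s), repr(phi), repr(s * phi)]
            w.writerow(row)


def write_events_csv(events: Sequence[BondEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "frame", "pair_i", "pair_j", "kind"])
        for e in events:
            w.writerow([repr(e.time), e.frame, e.pair.i, e.pair.j, e.kind])
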