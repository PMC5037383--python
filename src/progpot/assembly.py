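"""Assembly and evaluation of the approximate N-body potential.

The potential is the switched sum over an interaction pair set P

    U(x) = sum_entities sum_internal-bonds phi_harm(r)
         + sum_{p in P} sum_{j=1}^{m(p)} S_{p,j}(x) * phi_{p,j}(r_p),

where ``m`` is the multiplicity (how many switched potentials a pair
carries — e.g. stable bond plus transition-state repulsion gives 2),
``phi_{p,j}`` depends on the pair distance only, and the encoding
function ``S_{p,j}`` is compiled from a logic rule that may reference
any pair distance except ``p`` itself.

Forces come in two modes: ``full`` is the exact negative gradient,
including the encoding-function gradients that generate transition-state
repulsion; ``frozen_switch`` treats every dS/dx as zero almost
everywhere and keeps only the -S * dphi/dr terms, the qualitative
approximation used for the inhibitor and transcription examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .logic import AtomPair, Configuration, Expr, validate_logic
from .potentials import Harmonic, PairPotential
from .smoothing import NOverrides, encoding_eval, smooth_expr
from .units import REDUCED, UnitSystem

__all__ = [
    "Entity",
    "PotentialTerm",
    "Confinement",
    "TermEnergy",
    "System",
    "ForceMode",
]

ForceMode = Literal["full", "frozen_switch"]


@dataclass(frozen=True)
class Entity:
    """A molecule: named group of particles tied together by stiff
    harmonic constraint bonds (always on, S = 1)."""

    name: str
    particles: tuple[int, ...]
    masses: tuple[float, ...]
    bonds: tuple[tuple[AtomPair, Harmonic], ...] = ()
    # optional internal rest geometry (one d-vector per particle), used by
    # initial-placement helpers; not consulted during energy evaluation
    reference: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "masses", tuple(float(m) for m in self.masses))
        object.__setattr__(self, "bonds", tuple(self.bonds))
        if self.reference is not None:
            ref = tuple(tuple(float(c) for c in row) for row in self.reference)
            object.__setattr__(self, "reference", ref)
            if len(ref) != len(self.particles):
                raise ValueError(
                    f"entity {self.name}: reference geometry needs one point per particle"
                )
        if len(self.particles) != len(set(self.particles)):
            raise ValueError(f"entity {self.name}: duplicate particle ids")
        if len(self.masses) != len(self.particles):
            raise ValueError(f"entity {self.name}: one mass per particle required")
        if any(m <= 0 for m in self.masses):
            raise ValueError(f"entity {self.name}: masses must be positive")
        for p, _ in self.bonds:
            if p.i not in self.particles or p.j not in self.particles:
                raise ValueError(
                    f"entity {self.name}: internal bond {p} joins a foreign particle"
                )


@dataclass(frozen=True)
class PotentialTerm:
    """One summand S_{p,j} * phi_{p,j} of the switched sum."""

    pair: AtomPair
    j: int
    potential: PairPotential
    logic: Expr
    encoding: Expr

    @property
    def label(self) -> str:
        return f"Phi{self.pair},{self.j}"


@dataclass(frozen=True)
class Confinement:
    """Optional flat-bottom harmonic well keeping entities from escaping:
    zero inside ``radius`` of ``center``, 0.5*k*(|x-c| - radius)^2 outside."""

    k: float
    radius: float
    center: tuple[float, ...] | None = None


@dataclass(frozen=True)
class TermEnergy:
    label: str
    pair: AtomPair
    j: int
    S: float
    phi: float

    @property
    def product(self) -> float:
        return self.S * self.phi


class System:
    """Entities + interaction pair set with multiplicity + switched terms."""

    def __init__(
        self,
        entities: Sequence[Entity],
        dim: int = 2,
        force_mode: ForceMode = "full",
        confinement: Confinement | None = None,
        units: UnitSystem = REDUCED,
    ) -> None:
        if dim not in (1, 2, 3):
            raise ValueError("spatial dimension must be 1, 2 or 3")
        self.entities = list(entities)
        self.dim = dim
        self.force_mode: ForceMode = force_mode
        self.confinement = confinement
        self.units = units
        self.terms: list[PotentialTerm] = []

        ids: list[int] = []
        for ent in self.entities:
            ids.extend(ent.particles)
        if len(ids) != len(set(ids)):
            raise ValueError("particle ids must be disjoint across entities")
        if not ids or set(ids) != set(range(1, len(ids) + 1)):
            raise ValueError("particle ids must cover 1..N without gaps")
        self.n_particles = len(ids)

        self._masses = np.empty(self.n_particles)
        for ent in self.entities:
            for pid, m in zip(ent.particles, ent.masses):
                self._masses[pid - 1] = m

    # --- construction ------------------------------------------------------

    @property
    def masses(self) -> np.ndarray:
        return self._masses.copy()

    def multiplicity(self, p: AtomPair) -> int:
        return sum(1 for t in self.terms if t.pair == p)

    @property
    def interacting_pairs(self) -> set[AtomPair]:
        return {t.pair for t in self.terms}

    def add_term(
        self,
        pair: AtomPair,
        potential: PairPotential,
        logic: Expr,
        n_default: int = 6,
        n_overrides: NOverrides | None = None,
        j: int | None = None,
    ) -> PotentialTerm:
        """Append a switched potential; the encoding is compiled on the spot.

        Self-referential logic (a leaf on ``pair`` itself) is rejected,
        as is a duplicate (pair, j) slot.
        """
        for pid in pair:
            if not 1 <= pid <= self.n_particles:
                raise ValueError(f"pair {pair}: particle {pid} is not declared")
        for leaf in logic.leaves():
            for pid in leaf.pair:
                if not 1 <= pid <= self.n_particles:
                    raise ValueError(
                        f"logic leaf near{leaf.pair}: particle {pid} is not declared"
                    )
        report = validate_logic(logic, pair)
        if not report.ok:
            raise ValueError(str(report))
        if j is None:
            j = self.multiplicity(pair) + 1
        if any(t.pair == pair and t.j == j for t in self.terms):
            raise ValueError(f"duplicate term slot ({pair}, j={j})")
        term = PotentialTerm(
            pair=pair,
            j=j,
            potential=potential,
            logic=logic,
            encoding=smooth_expr(logic, n_default=n_default, n_overrides=n_overrides),
        )
        self.terms.append(term)
        self._invalidate()
        return term

    # --- compiled evaluation core ------------------------------------------
    #
    # Energy and forces are evaluated through a compiled form of the system:
    # one table of unique particle pairs (bonds, term pairs, encoding leaves)
    # whose distances are computed in a single vectorized pass, a vector of
    # smoothed-leaf values h_l (and derivatives), and per-term expression
    # trees reduced to nested tuples over leaf slots.  Forces accumulate a
    # radial coefficient per unique pair and scatter once with np.add.at.

    def _invalidate(self) -> None:
        self._compiled = None

    def _compiled_form(self):
        compiled = getattr(self, "_compiled", None)
        if compiled is None:
            compiled = self._compile()
            self._compiled = compiled
        return compiled

    def _compile(self):
        from .smoothing import SmoothNear
        from .logic import Const, Near, Not, And, Or

        pair_index: dict[AtomPair, int] = {}

        def pidx(p: AtomPair) -> int:
            if p not in pair_index:
                pair_index[p] = len(pair_index)
            return pair_index[p]

        bond_slots: list[tuple[int, float, float]] = []
        for ent in self.entities:
            for p, bond in ent.bonds:
                bond_slots.append((pidx(p), bond.k, bond.r0))

        leaf_index: dict[tuple[int, float, int], int] = {}
        leaf_rows: list[tuple[int, float, int]] = []

        def lidx(p: AtomPair, alpha: float, n: int) -> int:
            key = (pidx(p), alpha, n)
            if key not in leaf_index:
                leaf_index[key] = len(leaf_rows)
                leaf_rows.append(key)
            return leaf_index[key]

        def build(node):
            if isinstance(node, Const):
                return ("const", float(node.value))
            if isinstance(node, SmoothNear):
                return ("leaf", lidx(node.pair, node.spec.alpha, node.spec.n))
            if isinstance(node, Near):  # hard leaf inside an encoding
                return ("hard", pidx(node.pair), node.R)
            if isinstance(node, Not):
                return ("not", build(node.term))
            if isinstance(node, And):
                return ("and", tuple(build(t) for t in node.terms))
            if isinstance(node, Or):
                return ("or", tuple(build(t) for t in node.terms))
            raise TypeError(f"malformed encoding tree: unknown node {node!r}")

        term_rows = [(pidx(t.pair), t.potential, build(t.encoding)) for t in self.terms]

        pairs = sorted(pair_index, key=pair_index.get)
        # signed incidence matrix scattering per-pair radial coefficients
        # to per-particle forces in one small matmul
        inc = np.zeros((self.n_particles, len(pairs)))
        for k, p in enumerate(pairs):
            inc[p.i - 1, k] = -1.0
            inc[p.j - 1, k] = 1.0
        leaf_alpha = np.array([s[1] for s in leaf_rows])
        leaf_n = np.array([s[2] for s in leaf_rows])
        regular = bool(
            leaf_rows
            and np.all(np.isfinite(leaf_alpha))
            and np.all(leaf_alpha > 0)
            and np.all(leaf_n == leaf_n[0])
        )
        return {
            "inc": inc,
            "pi": np.array([p.i - 1 for p in pairs], dtype=np.intp),
            "pj": np.array([p.j - 1 for p in pairs], dtype=np.intp),
            "bond_p": np.array([s[0] for s in bond_slots], dtype=np.intp),
            "bond_k": np.array([s[1] for s in bond_slots]),
            "bond_r0": np.array([s[2] for s in bond_slots]),
            "leaf_p": np.array([s[0] for s in leaf_rows], dtype=np.intp),
            "leaf_alpha": leaf_alpha,
            "leaf_n": leaf_n,
            # fast path: every leaf has finite positive alpha and the same n
            "leaf_regular": regular,
            "leaf_inv_a2": np.where(
                np.isfinite(leaf_alpha) & (leaf_alpha > 0), 1.0 / leaf_alpha**2, 0.0
            )
            if leaf_rows
            else np.zeros(0),
            "leaf_n0": int(leaf_n[0]) if regular else 0,
            "terms": term_rows,
            "n_pairs": len(pairs),
        }

    @staticmethod
    def _leaf_values(c, r: np.ndarray, with_deriv: bool):
        rl = r[c["leaf_p"]]
        if c["leaf_regular"]:
            n0 = c["leaf_n0"]
            v = rl * rl * c["leaf_inv_a2"]
            np.minimum(v, 10.0 ** (300.0 / n0), out=v)  # keep v**n0 finite
            hv = 1.0 / (1.0 + v**n0)
            if not with_deriv:
                return hv, None
            dh = (-2.0 * n0) * hv * (1.0 - hv) / (rl + (rl == 0.0))
            return hv, dh
        alpha = c["leaf_alpha"]
        n = c["leaf_n"]
        hv = np.empty_like(rl)
        dh = np.zeros_like(rl) if with_deriv else None
        finite = (alpha > 0) & np.isfinite(alpha)
        hv[alpha == 0] = 0.0
        hv[np.isinf(alpha)] = 1.0
        if np.any(finite):
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                u = (rl[finite] ** 2 / alpha[finite] ** 2) ** n[finite]
                hf = np.where(np.isinf(u), 0.0, 1.0 / (1.0 + u))
            hv[finite] = hf
            if with_deriv:
                rf = rl[finite]
                dh[finite] = np.where(
                    rf > 0,
                    -2.0 * n[finite] * hf * (1.0 - hf) / np.where(rf > 0, rf, 1.0),
                    0.0,
                )
        return hv, dh

    @staticmethod
    def _tree_value(node, hv, r) -> float:
        kind = node[0]
        if kind == "const":
            return node[1]
        if kind == "leaf":
            return float(hv[node[1]])
        if kind == "hard":
            return 1.0 if r[node[1]] < node[2] else 0.0
        if kind == "not":
            return 1.0 - System._tree_value(node[1], hv, r)
        if kind == "and":
            v = 1.0
            for t in node[1]:
                v *= System._tree_value(t, hv, r)
            return v
        v = 0.0  # or
        for t in node[1]:
            b = System._tree_value(t, hv, r)
            v = v + b - v * b
        return v

    @staticmethod
    def _tree_value_grad(node, hv, r):
        """Value and {leaf slot: dS/dh_slot} for one expression tree."""
        kind = node[0]
        if kind == "const":
            return node[1], {}
        if kind == "leaf":
            return float(hv[node[1]]), {node[1]: 1.0}
        if kind == "hard":
            return (1.0 if r[node[1]] < node[2] else 0.0), {}
        if kind == "not":
            v, g = System._tree_value_grad(node[1], hv, r)
            return 1.0 - v, {s: -d for s, d in g.items()}
        if kind == "and":
            v, g = 1.0, {}
            for t in node[1]:
                cv, cg = System._tree_value_grad(t, hv, r)
                g = {s: d * cv for s, d in g.items()}
                for s, d in cg.items():
                    g[s] = g.get(s, 0.0) + d * v
                v *= cv
            return v, g
        v, g = 0.0, {}  # or
        for t in node[1]:
            cv, cg = System._tree_value_grad(t, hv, r)
            g = {s: d * (1.0 - cv) for s, d in g.items()}
            for s, d in cg.items():
                g[s] = g.get(s, 0.0) + d * (1.0 - v)
            v = v + cv - v * cv
        return v, g

    def _geometry(self, x: np.ndarray):
        c = self._compiled_form()
        deltas = -(c["inc"].T @ x)  # x_i - x_j per unique pair
        r = np.sqrt(np.einsum("ij,ij->i", deltas, deltas))
        return c, deltas, r

    def energy_raw(self, x: np.ndarray) -> float:
        """Potential energy from a bare (N, d) position array."""
        c, _, r = self._geometry(x)
        u = self._confinement_energy(x)
        if c["bond_p"].size:
            dr = r[c["bond_p"]] - c["bond_r0"]
            u += float(np.sum(0.5 * c["bond_k"] * dr * dr))
        hv, _ = self._leaf_values(c, r, with_deriv=False)
        for tp, pot, tree in c["terms"]:
            u += self._tree_value(tree, hv, r) * pot.energy(float(r[tp]))
        return float(u)

    def forces_raw(self, x: np.ndarray, mode: ForceMode | None = None) -> np.ndarray:
        """Forces from a bare position array (no validation)."""
        if mode is None:
            mode = self.force_mode
        c, deltas, r = self._geometry(x)
        inv_r = 1.0 / (r + (r == 0.0))  # coincident pairs contribute zero force
        # radial dU/dr coefficient per unique pair
        if c["bond_p"].size:
            g = np.bincount(
                c["bond_p"],
                weights=c["bond_k"] * (r[c["bond_p"]] - c["bond_r0"]),
                minlength=c["n_pairs"],
            )
        else:
            g = np.zeros(c["n_pairs"])
        full = mode == "full"
        hv, dh = self._leaf_values(c, r, with_deriv=full)
        leaf_p = c["leaf_p"]
        for tp, pot, tree in c["terms"]:
            rr = float(r[tp])
            if full:
                s, grads = self._tree_value_grad(tree, hv, r)
                if grads:
                    phi = pot.energy(rr)
                    for slot, ds_dh in grads.items():
                        g[leaf_p[slot]] += phi * ds_dh * dh[slot]
            else:
                s = self._tree_value(tree, hv, r)
            g[tp] += s * pot.dphi_dr(rr)
        coeff = (g * inv_r)[:, None] * deltas
        f = c["inc"] @ coeff
        if self.confinement is not None:
            f += self._confinement_forces(x)
        return f

    # --- public evaluation --------------------------------------------------

    def _check_config(self, config: Configuration) -> None:
        if config.n_particles != self.n_particles or config.dim != self.dim:
            raise ValueError(
                f"configuration shape ({config.n_particles}, {config.dim}) does not "
                f"match system ({self.n_particles}, {self.dim})"
            )

    def _confinement_energy(self, x: np.ndarray) -> float:
        c = self.confinement
        if c is None:
            return 0.0
        center = np.zeros(self.dim) if c.center is None else np.asarray(c.center)
        d = np.linalg.norm(x - center, axis=1)
        over = np.maximum(d - c.radius, 0.0)
        return float(0.5 * c.k * np.sum(over**2))

    def _confinement_forces(self, x: np.ndarray) -> np.ndarray:
        c = self.confinement
        f = np.zeros_like(x)
        if c is None:
            return f
        delta = x if c.center is None else x - np.asarray(c.center)
        d = np.sqrt(np.einsum("ij,ij->i", delta, delta))
        mask = d > c.radius
        if np.any(mask):
            unit = delta[mask] / d[mask, None]
            f[mask] = -c.k * (d[mask] - c.radius)[:, None] * unit
        return f

    def total_energy(
        self, config: Configuration, breakdown: bool = False
    ) -> float | tuple[float, list[TermEnergy]]:
        """Potential energy; optionally with per-term (S, phi) bookkeeping."""
        self._check_config(config)
        if not breakdown:
            return self.energy_raw(config.positions)
        u = self._confinement_energy(config.positions)
        for ent in self.entities:
            for p, bond in ent.bonds:
                u += bond.energy(config.distance(p))
        rows: list[TermEnergy] = []
        for t in self.terms:
            s = encoding_eval(t.encoding, config)
            phi = t.potential.energy(config.distance(t.pair))
            u += s * phi
            rows.append(TermEnergy(t.label, t.pair, t.j, s, phi))
        return u, rows

    def forces(
        self, config: Configuration, mode: ForceMode | None = None
    ) -> np.ndarray:
        """Forces F_i = -grad_i U, shape (N, d).

        ``full`` differentiates through the encoding functions;
        ``frozen_switch`` keeps only the -S * dphi/dr contributions.
        """
        self._check_config(config)
        if mode is None:
            mode = self.force_mode
        if mode not in ("full", "frozen_switch"):
            raise ValueError(f"unknown force mode {mode!r}")
        return self.forces_raw(config.positions, mode)

    def effective_dimension(self) -> tuple[int, int]:
        """(reduced, full): coordinates the switched potential actually
        depends on (atoms in term pairs or their encoding leaves, times d)
        versus the full configuration-space dimension d * N."""
        atoms = {pid for t in self.terms for pid in t.pair}
        for t in self.terms:
            for leaf in t.logic.leaves():
                atoms.update(leaf.pair)
        return self.dim * len(atoms), self.dim * self.n_particles

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, System):
            return NotImplemented
        return (
            self.entities == other.entities
            and self.dim == other.dim
            and self.force_mode == other.force_mode
            and self.confinement == other.confinement
            and self.units == other.units
            and self.terms == other.terms
        )
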