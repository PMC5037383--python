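"""Boolean algebra of proximity-based logic functions.

Coarse-level interaction rules are expressed as logic functions
``L_{p,j}``: {0,1}-valued functions of a particle configuration built by
applying AND, OR and NOT to *elementary* proximity predicates "particles
``i`` and ``j`` are closer than ``R``".  Each logic function is attached
to an interacting pair ``p`` and is forbidden from referencing the
distance of ``p`` itself — the switch for a bond may only listen to the
rest of the system.

The connectives use the algebraic forms

    a AND b = a*b,    a OR b = a + b - a*b,    NOT a = 1 - a,

which agree with the usual truth tables on {0,1} and, unlike min/max,
stay smooth under the replacement procedure of :mod:`progpot.smoothing`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Configuration",
    "AtomPair",
    "pair",
    "Expr",
    "Const",
    "Near",
    "And",
    "Or",
    "Not",
    "TRUE",
    "FALSE",
    "proximity",
    "elementary_eval",
    "logic_eval",
    "validate_logic",
    "LogicViolation",
    "truth_table",
]


@dataclass
class Configuration:
    """Positions of ``N`` ordered particles in ``d``-dimensional space.

    Particle ids are 1-based throughout the public API (matching the
    rule files); id ``i`` maps to row ``i - 1`` of ``positions``.
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2:
            raise ValueError("positions must be an (N, d) array")
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one particle")
        if self.positions.shape[1] not in (1, 2, 3):
            raise ValueError("spatial dimension must be 1, 2 or 3")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("all coordinates must be finite")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def position(self, i: int) -> np.ndarray:
        """Position of particle ``i`` (1-based)."""
        if not 1 <= i <= self.n_particles:
            raise IndexError(f"particle id {i} outside [1, {self.n_particles}]")
        return self.positions[i - 1]

    def distance(self, p: "AtomPair") -> float:
        return float(np.linalg.norm(self.position(p.i) - self.position(p.j)))

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy())


@dataclass(frozen=True, order=True)
class AtomPair:
    """Unordered pair of distinct 1-based particle ids, stored sorted."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"pair ({self.i}, {self.j}) must join distinct particles")
        if self.i < 1 or self.j < 1:
            raise ValueError("particle ids are 1-based positive integers")
        if self.i > self.j:  # canonicalize: (3, 2) == (2, 3)
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    def __iter__(self) -> Iterator[int]:
        yield self.i
        yield self.j

    def __str__(self) -> str:
        return f"({self.i},{self.j})"


def pair(i: int, j: int) -> AtomPair:
    """Shorthand constructor for :class:`AtomPair`."""
    return AtomPair(i, j)


def proximity(r: float, R: float) -> int:
    """Indicator of the half-open interval [0, R) evaluated at ``r``.

    ``R`` may be ``inf`` (identically 1) or 0 (identically 0); the
    comparison is strict, so ``r == R`` gives 0.
    """
    if r < 0 or not math.isfinite(r):
        raise ValueError(f"distance must be finite and nonnegative, got {r}")
    if R < 0:
        raise ValueError(f"threshold must be nonnegative, got {R}")
    return 1 if r < R else 0


# --- expression trees -------------------------------------------------------


class Expr:
    """Base class for logic-expression nodes."""

    def __and__(self, other: "Expr") -> "Expr":
        return And((self, other))

    def __or__(self, other: "Expr") -> "Expr":
        return Or((self, other))

    def __invert__(self) -> "Expr":
        return Not(self)

    def leaves(self) -> Iterator["Near"]:
        """Iterate over the elementary predicates of the tree."""
        if isinstance(self, Near):
            yield self
        elif isinstance(self, Not):
            yield from self.term.leaves()
        elif isinstance(self, (And, Or)):
            for t in self.terms:
                yield from t.leaves()
        elif not isinstance(self, Const):
            raise TypeError(f"malformed logic tree: unknown node {self!r}")

    def pairs(self) -> set[AtomPair]:
        return {leaf.pair for leaf in self.leaves()}


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("constants are 0 or 1")


TRUE = Const(1)
FALSE = Const(0)


@dataclass(frozen=True)
class Near(Expr):
    """Elementary predicate: the pair's distance lies in [0, R)."""

    pair: AtomPair
    R: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"proximity threshold must be >= 0, got {self.R}")


@dataclass(frozen=True)
class And(Expr):
    terms: tuple[Expr, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.terms) < 1:
            raise ValueError("AND needs at least one operand")


@dataclass(frozen=True)
class Or(Expr):
    terms: tuple[Expr, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.terms) < 1:
            raise ValueError("OR needs at least one operand")


@dataclass(frozen=True)
class Not(Expr):
    term: Expr


def elementary_eval(config: Configuration, q: AtomPair, R: float) -> int:
    """Evaluate the elementary logic function E_{q,R} on a configuration."""
    return proximity(config.distance(q), R)


def logic_eval(expr: Expr, config: Configuration) -> int:
    """Recursively evaluate a logic function; the result is exactly 0 or 1."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Near):
        return elementary_eval(config, expr.pair, expr.R)
    if isinstance(expr, Not):
        return 1 - logic_eval(expr.term, config)
    if isinstance(expr, And):
        v = 1
        for t in expr.terms:
            v *= logic_eval(t, config)
        return v
    if isinstance(expr, Or):
        v = 0
        for t in expr.terms:
            b = logic_eval(t, config)
            v = v + b - v * b
        return v
    raise TypeError(f"malformed logic tree: unknown node {expr!r}")


@dataclass
class LogicViolation:
    """Report of self-referential leaves found by :func:`validate_logic`."""

    owner: AtomPair
    offending: list[Near] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.offending

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return f"ok: logic for pair {self.owner} is admissible"
        leaves = ", ".join(f"near{l.pair}<{l.R}" for l in self.offending)
        return (
            f"logic for pair {self.owner} may not depend on its own distance; "
            f"offending leaves: {leaves}"
        )


def validate_logic(expr: Expr, owner: AtomPair) -> LogicViolation:
    """Check that no elementary predicate references the owner pair itself.

    The switch attached to potential Phi_p must be a function of *other*
    pair distances only, otherwise the product S_p * Phi_p would no
    longer factor into switch times distance-only potential.
    """
    report = LogicViolation(owner=owner)
    for leaf in expr.leaves():
        if leaf.pair == owner:
            report.offending.append(leaf)
    return report


def _substitute_eval(expr: Expr, bits: Mapping[Near, int]) -> int:
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Near):
        try:
            return bits[expr]
        except KeyError:
            raise KeyError(
                f"predicate near{expr.pair}<{expr.R} is not among the "
                "declared truth-table conditions"
            ) from None
    if isinstance(expr, Not):
        return 1 - _substitute_eval(expr.term, bits)
    if isinstance(expr, And):
        v = 1
        for t in expr.terms:
            v *= _substitute_eval(t, bits)
        return v
    if isinstance(expr, Or):
        v = 0
        for t in expr.terms:
            b = _substitute_eval(t, bits)
            v = v + b - v * b
        return v
    raise TypeError(f"malformed logic tree: unknown node {expr!r}")


def truth_table(
    exprs: Sequence[tuple[str, Expr]],
    conditions: Sequence[Near],
) -> list[tuple[tuple[int, ...], dict[str, int]]]:
    """Enumerate all assignments of the elementary conditions.

    Returns one row per assignment of the ``k`` condition bits, in
    binary-counting order on the condition columns: each row is
    ``(bits, {name: value})``.  Every elementary leaf of every
    expression must appear in ``conditions``.
    """
    conditions = list(conditions)
    rows = []
    for bits in itertools.product((0, 1), repeat=len(conditions)):
        assignment = dict(zip(conditions, bits))
        rows.append(
            (bits, {name: _substitute_eval(e, assignment) for name, e in exprs})
        )
    return rows
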