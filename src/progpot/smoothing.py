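"""The replacement procedure: smooth proximity predicates into encoding functions.

A logic function is turned into a real-valued *encoding function*
``S in [0,1]`` by replacing every proximity indicator ``chi_[0,R)(r)``
with the sigmoid-like switch

    h_{alpha,n}(r) = 1 / (1 + (r/alpha)^(2n)),   h_{0,n} = 0,  h_{inf,n} = 1,

while the AND/OR/NOT connectives keep their algebraic forms.  The
transition point is ``alpha`` (``h(alpha) = 1/2`` for every ``n >= 1``;
to mimic the indicator of [0, R) choose ``alpha = R``) and ``n``
controls the sharpness of the 1 -> 0 transition.  Because ``h`` depends
on ``r**2`` only, the encoding function is a smooth function of the
Cartesian coordinates, with the analytic gradients required for forces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .logic import And, AtomPair, Configuration, Const, Expr, Near, Not, Or

__all__ = [
    "SmoothingSpec",
    "SmoothNear",
    "h",
    "h_prime",
    "smooth_expr",
    "encoding_eval",
    "encoding_value_and_pair_grads",
    "encoding_grad",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoothingSpec:
    """Transition point ``alpha`` (length units) and sharpness ``n``."""

    alpha: float
    n: int = 6

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"sharpness n must be an integer >= 1, got {self.n}")


def h(r, alpha: float, n: int = 6):
    """Smoothed proximity function ``h_{alpha,n}(r)``; accepts scalars or arrays.

    Degenerate thresholds follow the indicator limits: ``alpha = 0``
    gives identically 0 and ``alpha = inf`` identically 1.
    """
    spec = SmoothingSpec(alpha, n)  # validates parameters
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("distances must be finite and nonnegative")
    if spec.alpha == 0.0:
        out = np.zeros_like(r)
    elif math.isinf(spec.alpha):
        out = np.ones_like(r)
    else:
        with np.errstate(over="ignore"):
            u = (r * r / (alpha * alpha)) ** n  # (r/alpha)^(2n), cusp-free at r=0
        out = np.where(np.isinf(u), 0.0, 1.0 / (1.0 + u))
    return out if out.ndim else float(out)


def h_prime(r, alpha: float, n: int = 6):
    """Derivative dh/dr; everywhere <= 0, exactly 0 at r = 0.

    Uses the overflow-safe identity dh/dr = -(2n/r) * h * (1 - h).
    """
    SmoothingSpec(alpha, n)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("distances must be finite and nonnegative")
    if alpha == 0.0 or math.isinf(alpha):
        out = np.zeros_like(r)
    else:
        hv = np.asarray(h(r, alpha, n))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, -(2.0 * n) * hv * (1.0 - hv) / np.where(r > 0, r, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SmoothNear(Expr):
    """Smoothed elementary predicate: ``h_{alpha,n}(r_pair)``."""

    pair: AtomPair
    spec: SmoothingSpec


NOverrides = Mapping[Union[Near, AtomPair], int]


def smooth_expr(
    expr: Expr,
    n_default: int = 6,
    n_overrides: NOverrides | None = None,
) -> Expr:
    """Structure-preserving map from a logic tree to its encoding tree.

    Every ``Near(pair, R)`` leaf becomes ``SmoothNear(pair, h_{R,n})``;
    connectives and constants are kept.  Sharpness may be overridden per
    leaf (keyed by the ``Near`` leaf or by its ``AtomPair``).
    """
    overrides = dict(n_overrides or {})

    def walk(e: Expr) -> Expr:
        if isinstance(e, Const):
            return e
        if isinstance(e, Near):
            n = overrides.get(e, overrides.get(e.pair, n_default))
            return SmoothNear(e.pair, SmoothingSpec(alpha=e.R, n=n))
        if isinstance(e, Not):
            return Not(walk(e.term))
        if isinstance(e, And):
            return And(tuple(walk(t) for t in e.terms))
        if isinstance(e, Or):
            return Or(tuple(walk(t) for t in e.terms))
        raise TypeError(f"malformed logic tree: unknown node {e!r}")

    return walk(expr)


def encoding_eval(enc: Expr, config: Configuration) -> float:
    """Evaluate an encoding function; the algebraic connectives keep the
    result in [0, 1] whenever every leaf is in [0, 1]."""
    value, _ = _eval(enc, config, want_grad=False)
    return value


def encoding_value_and_pair_grads(
    enc: Expr, config: Configuration
) -> tuple[float, dict[AtomPair, float]]:
    """Value of S together with dS/dr_q for every leaf pair q."""
    return _eval(enc, config, want_grad=True)


def _eval(enc: Expr, config: Configuration, want_grad: bool):
    if isinstance(enc, Const):
        return float(enc.value), {}
    if isinstance(enc, Near):
        # hard leaves are admissible inside encodings (piecewise-constant,
        # zero gradient almost everywhere)
        from .logic import elementary_eval

        return float(elementary_eval(config, enc.pair, enc.R)), {}
    if isinstance(enc, SmoothNear):
        r = config.distance(enc.pair)
        v = h(r, enc.spec.alpha, enc.spec.n)
        if not want_grad:
            return v, {}
        return v, {enc.pair: h_prime(r, enc.spec.alpha, enc.spec.n)}
    if isinstance(enc, Not):
        v, g = _eval(enc.term, config, want_grad)
        return 1.0 - v, {q: -dv for q, dv in g.items()}
    if isinstance(enc, And):
        v, g = 1.0, {}
        for t in enc.terms:
            cv, cg = _eval(t, config, want_grad)
            if want_grad:
                g = {q: dv * cv for q, dv in g.items()}
                for q, dv in cg.items():
                    g[q] = g.get(q, 0.0) + dv * v
            v *= cv
        return v, g
    if isinstance(enc, Or):
        v, g = 0.0, {}
        for t in enc.terms:
            cv, cg = _eval(t, config, want_grad)
            if want_grad:
                g = {q: dv * (1.0 - cv) for q, dv in g.items()}
                for q, dv in cg.items():
                    g[q] = g.get(q, 0.0) + dv * (1.0 - v)
            v = v + cv - v * cv
        return v, g
    raise TypeError(f"malformed encoding tree: unknown node {enc!r}")


def encoding_grad(enc: Expr, config: Configuration) -> np.ndarray:
    """Cartesian gradient dS/dx_i for every particle, shape (N, d).

    Particles not referenced by any leaf get zero rows; the rows sum to
    the zero vector because S depends on relative distances only.
    Coincident leaf particles are safe by construction (the chain factor
    h'(0) vanishes); their contribution is set to zero and logged.
    """
    _, pair_grads = encoding_value_and_pair_grads(enc, config)
    grad = np.zeros_like(config.positions)
    for q, ds_dr in pair_grads.items():
        xi, xj = config.position(q.i), config.position(q.j)
        delta = xi - xj
        r = float(np.linalg.norm(delta))
        if r == 0.0:
            logger.warning(
                "coincident particles %s in encoding leaf; gradient set to 0", q
            )
            continue
        unit = delta / r
        grad[q.i - 1] += ds_dr * unit
        grad[q.j - 1] -= ds_dr * unit
    return grad
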