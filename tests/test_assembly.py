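"""The switched N-body sum: term registry, energies, forces, dimensions."""

import math

import numpy as np
import pytest

from progpot import (
    And,
    Configuration,
    Const,
    Entity,
    Harmonic,
    Morse,
    Near,
    Not,
    System,
    pair,
)
from progpot.potentials import PairPotential
from conftest import random_configuration, random_system


def naive_switched_energy(system, config):
    """Independent re-summation of the switched sum, written from scratch.

    Recomputes every encoding function by walking the term's *logic*
    tree and substituting 1/(1 + (r/R)^(2n)) for each predicate, without
    touching the package's encoding machinery.
    """
    from progpot.logic import And as _And, Const as _Const, Near as _Near
    from progpot.logic import Not as _Not, Or as _Or
    from progpot.smoothing import SmoothNear as _SN

    def dist(q):
        return float(
            np.linalg.norm(
                config.positions[q.i - 1] - config.positions[q.j - 1]
            )
        )

    def smooth_value(node, ns):
        if isinstance(node, _Const):
            return float(node.value)
        if isinstance(node, _Near):
            R, n = node.R, ns
            r = dist(node.pair)
            if R == 0:
                return 0.0
            if math.isinf(R):
                return 1.0
            try:
                ratio = (r / R) ** (2 * n)
            except OverflowError:
                return 0.0
            return 1.0 / (1.0 + ratio)
        if isinstance(node, _Not):
            return 1.0 - smooth_value(node.term, ns)
        if isinstance(node, _And):
            out = 1.0
            for t in node.terms:
                out *= smooth_value(t, ns)
            return out
        if isinstance(node, _Or):
            out = 0.0
            for t in node.terms:
                v = smooth_value(t, ns)
                out = out + v - out * v
            return out
        raise TypeError(node)

    total = 0.0
    for ent in system.entities:
        for q, bond in ent.bonds:
            total += 0.5 * bond.k * (dist(q) - bond.r0) ** 2
    for term in system.terms:
        # recover the sharpness actually compiled into this term's leaves
        leaf_ns = set()
        stack = [term.encoding]
        while stack:
            node = stack.pop()
            if isinstance(node, _SN):
                leaf_ns.add(node.spec.n)
            elif hasattr(node, "terms"):
                stack.extend(node.terms)
            elif hasattr(node, "term"):
                stack.append(node.term)
        ns = leaf_ns.pop() if leaf_ns else 6
        s = smooth_value(term.logic, ns)
        total += s * term.potential.energy(dist(term.pair))
    return total


class TestTermRegistry:
    def make_system(self):
        ents = [
            Entity("A", (1, 2), (1.0, 1.0)),
            Entity("B", (3, 4), (1.0, 1.0)),
            Entity("C", (5, 6), (1.0, 1.0)),
        ]
        return System(ents, dim=2)

    def test_multiplicity_counts_terms_per_pair(self):
        s = self.make_system()
        m = Morse(10.0, 1.0, 2.0)
        s.add_term(pair(2, 3), m, Not(Near(pair(2, 5), 3.0)))
        assert s.multiplicity(pair(2, 3)) == 1
        s.add_term(pair(2, 5), m, Const(1))
        s.add_term(pair(2, 5), m, Near(pair(1, 3), 3.0))
        assert s.multiplicity(pair(2, 5)) == 2
        labels = [t.label for t in s.terms]
        assert "Phi(2,5),1" in labels and "Phi(2,5),2" in labels

    def test_rejects_self_referential_logic(self):
        s = self.make_system()
        with pytest.raises(ValueError, match=r"\(2,3\)"):
            s.add_term(pair(2, 3), Morse(1, 1, 1), Near(pair(2, 3), 1.0))

    def test_rejects_duplicate_slot_and_unknown_particle(self):
        s = self.make_system()
        s.add_term(pair(2, 3), Morse(1, 1, 1), Const(1), j=1)
        with pytest.raises(ValueError, match="duplicate"):
            s.add_term(pair(2, 3), Morse(1, 1, 1), Const(0), j=1)
        with pytest.raises(ValueError, match="not declared"):
            s.add_term(pair(2, 9), Morse(1, 1, 1), Const(1))

    def test_entity_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            System([Entity("A", (1, 2), (1, 1)), Entity("B", (2, 3), (1, 1))])
        with pytest.raises(ValueError, match="foreign"):
            Entity("A", (1, 2), (1, 1), bonds=((pair(1, 3), Harmonic(1, 1)),))


class TestEnergy:
    def test_const_switch_reduces_to_bare_potential(self, rng):
        s = System([Entity("A", (1, 2), (1, 1)), Entity("B", (3, 4), (1, 1))], dim=2)
        m = Morse(12.0, 1.3, 1.7)
        s.add_term(pair(1, 3), m, Const(1))
        cfg = random_configuration(rng, s)
        r = cfg.distance(pair(1, 3))
        assert s.total_energy(cfg) == pytest.approx(m.energy(r), rel=1e-14)

    def test_switched_off_term_contributes_nothing(self):
        # inhibitor-style: contact close -> Phi(2,3) off even at its r_eq
        s = System([Entity("A", (1, 2), (1, 1)), Entity("B", (3, 4), (1, 1)),
                    Entity("C", (5, 6), (1, 1))], dim=2)
        m = Morse(100.0, 1.0, 2.0)
        s.add_term(pair(2, 3), m, Not(Near(pair(2, 5), 3.0)))
        x = np.array([[0, 1], [0, 0], [2, 0], [2, 1], [0.2, 0], [0.2, 1.0]])
        u, rows = s.total_energy(Configuration(x), breakdown=True)
        assert rows[0].S < 1e-6
        assert abs(rows[0].product) < 1e-4 * m.D

    def test_matches_independent_naive_summation(self, rng):
        for k in range(100):
            s = random_system(rng, n_particles=int(rng.integers(4, 9)),
                              n_terms=int(rng.integers(1, 5)))
            cfg = random_configuration(rng, s)
            assert s.total_energy(cfg) == pytest.approx(
                naive_switched_energy(s, cfg), rel=1e-10, abs=1e-10
            )

    def test_breakdown_S_in_unit_interval(self, rng):
        for _ in range(20):
            s = random_system(rng)
            cfg = random_configuration(rng, s)
            _, rows = s.total_energy(cfg, breakdown=True)
            assert all(0.0 <= row.S <= 1.0 for row in rows)

    def test_invariance_under_rigid_motions(self, rng):
        s = random_system(rng, n_particles=6, n_terms=3)
        cfg = random_configuration(rng, s)
        u0 = s.total_energy(cfg)
        shift = cfg.positions + np.array([3.7, -1.2])
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        rotated = cfg.positions @ rot.T
        assert s.total_energy(Configuration(shift)) == pytest.approx(u0, rel=1e-10)
        assert s.total_energy(Configuration(rotated)) == pytest.approx(u0, rel=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        s = random_system(rng)
        with pytest.raises(ValueError, match="match"):
            s.total_energy(Configuration(np.zeros((s.n_particles + 2, 2))))


class TestForces:
    def fd_forces(self, s, x, eps=1e-6):
        num = np.zeros_like(x)
        for i in range(x.shape[0]):
            for k in range(x.shape[1]):
                for sgn in (1, -1):
                    xs = x.copy()
                    xs[i, k] += sgn * eps
                    num[i, k] += sgn * s.total_energy(Configuration(xs))
        return num / (-2 * eps)

    def test_full_mode_is_exact_negative_gradient(self, rng):
        for _ in range(25):
            s = random_system(rng)
            cfg = random_configuration(rng, s)
            f = s.forces(cfg, "full")
            num = self.fd_forces(s, cfg.positions)
            scale = max(np.abs(f).max(), 1.0)
            assert np.abs(f - num).max() / scale < 1e-6

    def test_net_force_vanishes_in_both_modes(self, rng):
        for _ in range(10):
            s = random_system(rng)
            cfg = random_configuration(rng, s)
            for mode in ("full", "frozen_switch"):
                assert np.allclose(s.forces(cfg, mode).sum(axis=0), 0.0, atol=1e-9)

    def test_frozen_switch_agrees_far_from_thresholds(self):
        s = System([Entity("A", (1, 2), (1, 1)), Entity("B", (3, 4), (1, 1)),
                    Entity("C", (5, 6), (1, 1))], dim=2)
        s.add_term(pair(2, 3), Morse(100.0, 1.0, 2.0),
                   Not(Near(pair(2, 5), 3.0)), n_default=8)
        # contact distance 12 = 4x the threshold: dS/dx is negligible
        x = np.array([[0, 1], [0, 0], [2, 0], [2, 1], [12, 0], [12, 1.0]])
        cfg = Configuration(x)
        f_full = s.forces(cfg, "full")
        f_frozen = s.forces(cfg, "frozen_switch")
        assert np.abs(f_full - f_frozen).max() < 1e-6

    def test_unknown_mode_rejected(self, rng):
        s = random_system(rng)
        with pytest.raises(ValueError, match="mode"):
            s.forces(random_configuration(rng, s), "adiabatic")


class TestEffectiveDimension:
    def test_subset_of_particles(self):
        s = System([Entity("A", (1, 2), (1, 1)), Entity("B", (3, 4), (1, 1)),
                    Entity("C", (5, 6), (1, 1))], dim=2)
        s.add_term(pair(2, 3), Morse(1, 1, 1), Not(Near(pair(2, 5), 3.0)))
        # the switched sum depends on atoms 2, 3 (term) and 5 (switch leaf)
        assert s.effective_dimension() == (6, 12)

    def test_all_particles_interacting(self):
        s = System([Entity("A", (1, 2), (1, 1))], dim=3)
        s.add_term(pair(1, 2), Morse(1, 1, 1), Const(1))
        red, full = s.effective_dimension()
        assert red == full == 6
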