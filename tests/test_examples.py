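"""Bundled example systems: logic wiring, switch behavior, geometry helpers."""

import numpy as np
import pytest

from progpot import (
    Configuration,
    build_dna,
    build_fixture,
    build_inhibitor,
    build_reaction,
    build_signaling,
    encoding_eval,
    logic_eval,
    pair,
    random_initial_config,
    truth_table,
    validate_logic,
)
from progpot.analysis import energy_surface_scan
from progpot.logic import Near


@pytest.mark.parametrize("name", ["signaling", "inhibitor", "reaction", "dna"])
def test_every_fixture_has_admissible_logic(name):
    system = build_fixture(name)
    for t in system.terms:
        assert validate_logic(t.logic, t.pair).ok


def test_unknown_fixture_rejected():
    with pytest.raises(ValueError, match="unknown fixture"):
        build_fixture("ribosome")


class TestSignaling:
    def test_switch_follows_the_contact(self):
        s = build_signaling()
        (term,) = s.terms
        x = np.zeros((6, 2))
        x[0], x[1] = [0, 1], [0, 0]          # A rod
        x[2], x[3] = [2, 0], [2, 1]          # B rod
        x[4], x[5] = [30, 0], [30, 1]        # C far away
        far = Configuration(x.copy())
        assert encoding_eval(term.encoding, far) > 0.99
        x[4] = [0.3, 0.0]                    # C's site 5 at the receptor
        close = Configuration(x)
        assert encoding_eval(term.encoding, close) < 0.01

    def test_effective_dimension_counts_three_atoms(self):
        assert build_signaling().effective_dimension() == (6, 12)


class TestInhibitor:
    def test_truth_table_matches_designed_mechanism(self):
        s = build_inhibitor()
        c25 = Near(pair(2, 5), 3.0)
        c36 = Near(pair(3, 6), 3.0)
        exprs = [(t.label, t.logic) for t in s.terms]
        rows = truth_table(exprs, [c25, c36])
        values = [tuple(v.values()) for _, v in rows]
        # columns: L(2,3), L(2,5), L(3,6)
        assert values[0] == (1, 1, 1)   # all far: everything on
        assert values[1] == (0, 0, 1)   # BC formed: AB and AC blocked
        assert values[2] == (0, 1, 0)   # AC formed: AB and BC blocked
        assert values[3] == (0, 0, 0)   # both contacts: everything off

    def test_switch_values_on_extreme_configurations(self):
        s = build_inhibitor()
        far = np.array([[0, 1], [0, 0], [20, 0], [20, 1],
                        [40, 0], [40, 1.0]])
        cfg = Configuration(far)
        for t in s.terms:
            assert encoding_eval(t.encoding, cfg) > 0.99
        # C's site 5 occupying the receptor site 2
        occupied = far.copy()
        occupied[4] = [0.3, 0.0]
        occupied[5] = [0.3, 1.0]
        cfg = Configuration(occupied)
        S = {t.pair: encoding_eval(t.encoding, cfg) for t in s.terms}
        assert S[pair(2, 3)] < 0.01
        assert S[pair(3, 6)] < 0.01
        assert S[pair(2, 5)] > 0.99

    def test_dimension_reduction(self):
        assert build_inhibitor().effective_dimension() == (8, 12)


class TestReaction:
    def test_switch_table(self):
        """Attacker inside the switch radius: stable bond off, repulsion on."""
        s = build_reaction()
        by_label = {t.label: t for t in s.terms}
        x = np.array([[0, 0], [2, 0], [-2, 0], [-2, 1], [3.0, 0], [3.0, 1.0]])
        # r(2,5) = 1 < 3: attacking C close to A's site 2
        cfg = Configuration(x)
        assert encoding_eval(by_label["Phi(1,3),1"].encoding, cfg) < 0.01
        assert encoding_eval(by_label["Phi(1,3),2"].encoding, cfg) > 0.99
        # move C far: r(2,5) = 10 >= 3
        x2 = x.copy()
        x2[4] = [12.0, 0]
        x2[5] = [12.0, 1]
        cfg2 = Configuration(x2)
        assert encoding_eval(by_label["Phi(1,3),1"].encoding, cfg2) > 0.99
        assert encoding_eval(by_label["Phi(1,3),2"].encoding, cfg2) < 0.01
        # mirrored logic for the AC side, switched by r(1,3)
        x3 = x.copy()
        x3[2] = [-0.5, 0]   # B's site 3 close to A's site 1
        cfg3 = Configuration(x3)
        assert encoding_eval(by_label["Phi(2,5),1"].encoding, cfg3) < 0.01
        assert encoding_eval(by_label["Phi(2,5),2"].encoding, cfg3) > 0.99

    def test_multiplicity_two_on_both_reactive_pairs(self):
        s = build_reaction()
        assert s.multiplicity(pair(1, 3)) == 2
        assert s.multiplicity(pair(2, 5)) == 2

    def test_unbiased_energy_surface_is_transposition_symmetric(self):
        s = build_reaction(bias=1.0)
        s.confinement = None
        ref = reaction_reference_config()
        grid = np.linspace(1.2, 6.0, 25)
        U = energy_surface_scan(s, ref, movers=(3, 5), anchors=(1, 2),
                                r_x=grid, r_y=grid)
        assert np.abs(U - U.T).max() < 1e-10 * np.abs(U).max()

    def test_bias_validation_and_depth(self):
        with pytest.raises(ValueError, match="bias"):
            build_reaction(bias=-1.0)
        s = build_reaction(bias=2.0)
        by_label = {t.label: t for t in s.terms}
        assert by_label["Phi(2,5),1"].potential.D == pytest.approx(
            2.0 * by_label["Phi(1,3),1"].potential.D
        )

    def test_dimension_reduction(self):
        assert build_reaction().effective_dimension() == (8, 12)


def reaction_reference_config():
    """A rod horizontal, B and C collinear with it on opposite sides."""
    x = np.array([
        [0.0, 0.0],    # 1
        [2.0, 0.0],    # 2
        [-4.0, 0.0],   # 3 (B reactive site, left of atom 1)
        [-4.0, 2.0],   # 4 (B passive)
        [6.0, 0.0],    # 5 (C reactive site, right of atom 2)
        [6.0, 2.0],    # 6 (C passive)
    ])
    return Configuration(x)


class TestDNA:
    def place(self, close=()):
        """Geometry with selected predicate pairs in contact (distance 0.5),
        everything else scattered far apart."""
        x = np.zeros((20, 2))
        for i in range(20):
            x[i] = [100.0 + 7.0 * i, 50.0 + 3.0 * i]
        anchors = {1: [0, 0], 2: [2, 0], 5: [6, 0], 6: [9, 0], 7: [12, 0],
                   8: [15, 0]}
        for pid, xy in anchors.items():
            x[pid - 1] = xy
        for i, j in close:
            x[j - 1] = x[i - 1] + [0.5, 0.0]
        return Configuration(x)

    def test_no_base_pairing_before_polymerase_binds(self):
        s = build_dna()
        by_pair = {t.pair: t for t in s.terms}
        cfg = self.place()
        assert logic_eval(by_pair[pair(5, 9)].logic, cfg) == 0
        assert logic_eval(by_pair[pair(1, 3)].logic, cfg) == 1  # pol bond on

    def test_sequential_gating_after_first_base_pair(self):
        s = build_dna()
        by_pair = {t.pair: t for t in s.terms}
        cfg = self.place(close=[(1, 3), (2, 4), (5, 9)])
        assert logic_eval(by_pair[pair(6, 12)].logic, cfg) == 1
        assert logic_eval(by_pair[pair(7, 15)].logic, cfg) == 0

    def test_full_backbone_releases_strand_and_polymerase(self):
        s = build_dna()
        by_pair = {t.pair: t for t in s.terms}
        cfg = self.place(close=[(1, 3), (2, 4), (5, 9), (6, 12), (7, 15),
                                (8, 18), (11, 13), (14, 16), (17, 19)])
        for q in [pair(5, 9), pair(6, 12), pair(7, 15), pair(8, 18)]:
            assert logic_eval(by_pair[q].logic, cfg) == 0
        assert logic_eval(by_pair[pair(1, 3)].logic, cfg) == 0
        # backbone bonds stay on, holding the released strand together
        for q in [pair(11, 13), pair(14, 16), pair(17, 19)]:
            assert logic_eval(by_pair[q].logic, cfg) == 1


class TestRandomInitialConfig:
    def test_deterministic_under_seed(self):
        s = build_inhibitor()
        a = random_initial_config(s, 10.0, 4.0, seed=5)
        b = random_initial_config(s, 10.0, 4.0, seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_min_separation_between_entities(self):
        s = build_inhibitor()
        cfg = random_initial_config(s, 10.0, 4.0, seed=3)
        groups = [ent.particles for ent in s.entities]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        d = np.linalg.norm(cfg.position(i) - cfg.position(j))
                        assert d >= 4.0 - 1e-12

    def test_preformed_pair_at_requested_distance(self):
        s = build_inhibitor()
        cfg = random_initial_config(s, 10.0, 4.0, seed=9,
                                    preformed=[(pair(2, 3), 2.0)])
        assert cfg.distance(pair(2, 3)) == pytest.approx(2.0, abs=1e-9)

    def test_impossible_placement_raises(self):
        s = build_inhibitor()
        with pytest.raises(RuntimeError, match="box"):
            random_initial_config(s, 2.0, 50.0, seed=1, max_attempts=20)
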