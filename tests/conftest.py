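import numpy as np
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
    Or,
    RepulsiveMorse,
    System,
    pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_logic_tree(rng, pairs, depth=3, p_leaf=0.4):
    """Random logic expression over the given candidate pairs."""
    if depth == 0 or rng.random() < p_leaf:
        if rng.random() < 0.1:
            return Const(int(rng.integers(0, 2)))
        q = pairs[rng.integers(0, len(pairs))]
        return Near(q, float(rng.uniform(0.5, 4.0)))
    kind = rng.integers(0, 3)
    if kind == 0:
        return Not(random_logic_tree(rng, pairs, depth - 1, p_leaf))
    children = tuple(
        random_logic_tree(rng, pairs, depth - 1, p_leaf)
        for _ in range(rng.integers(2, 4))
    )
    return And(children) if kind == 1 else Or(children)


def random_system(rng, n_particles=6, n_terms=3, dim=2, with_bonds=True):
    """Small random switched system for oracle comparisons."""
    n_particles = max(4, n_particles) // 2 * 2
    entities = [
        Entity(
            name=f"E{i}",
            particles=(2 * i + 1, 2 * i + 2),
            masses=(1.0, 1.0),
            bonds=((pair(2 * i + 1, 2 * i + 2), Harmonic(k=50.0, r0=1.0)),)
            if with_bonds
            else (),
        )
        for i in range(n_particles // 2)
    ]
    system = System(entities, dim=dim, force_mode="full")
    all_pairs = [
        pair(i, j)
        for i in range(1, n_particles + 1)
        for j in range(i + 1, n_particles + 1)
    ]
    added = 0
    attempts = 0
    while added < n_terms and attempts < 50 * n_terms:
        attempts += 1
        p = all_pairs[rng.integers(0, len(all_pairs))]
        candidates = [q for q in all_pairs if q != p]
        logic = random_logic_tree(rng, candidates)
        if rng.random() < 0.5:
            pot = Morse(
                D=float(rng.uniform(1.0, 20.0)),
                a=float(rng.uniform(0.5, 2.0)),
                r_eq=float(rng.uniform(0.8, 2.0)),
            )
        else:
            pot = RepulsiveMorse(
                D=float(rng.uniform(1.0, 20.0)),
                a=float(rng.uniform(0.5, 2.0)),
                r_eq=float(rng.uniform(0.8, 2.0)),
            )
        try:
            system.add_term(p, pot, logic, n_default=int(rng.integers(1, 8)))
        except ValueError:
            continue
        added += 1
    return system


def random_configuration(rng, system, spread=3.0, min_dist=0.3):
    """Random positions with no two particles closer than min_dist."""
    while True:
        x = rng.uniform(-spread, spread, size=(system.n_particles, system.dim))
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            return Configuration(x)
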