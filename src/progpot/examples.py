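"""Builders for the bundled example systems.

Four systems of increasing complexity, each expressed entirely through
coarse-level proximity rules:

* ``signaling`` — three two-site rods A, B, C; the A-B bond is switched
  off whenever the signaling site of C approaches the receptor site.
* ``inhibitor`` — same three rods, but C can occupy either binding
  partner: whichever of the (2,5) or (3,6) contacts forms first blocks
  both the A-B complex and the other contact.
* ``reaction`` — the reversible bond-breaking exchange AB + C <-> AC + B.
  Each reactive pair carries multiplicity 2: a Morse bond switched off
  when the attacking particle gets close, plus a transition-state
  electron-repulsion term (the repulsive Morse branch) switched on in
  exactly the complementary region.  Runs with full gradients so the
  encoding-function derivatives supply the activation-energy wall.
* ``dna`` — a 20-particle transcription cartoon: RNA-polymerase binding
  to the promoter gates a strictly sequential cascade of base-pairing
  and backbone-forming bonds along the template strand ACTG, ending
  with the release of the complementary strand and the polymerase.

Numeric defaults follow the printed example values where available
(Morse depth 100, width 1, equilibrium length 2, switch radii 3 = 1.5 x
the partner bond's equilibrium length, sharpness n = 6); the remaining
run conditions (masses, temperature, friction, confinement, step sizes)
are package defaults chosen to put each system in its intended working
regime, and every one can be overridden per call.  All fixtures use the
reduced unit preset (k_B = 1).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .assembly import Confinement, Entity, System
from .dynamics import IntegratorParams
from .logic import And, AtomPair, Configuration, Expr, Near, Not, Or, pair
from .potentials import Harmonic, Morse, repulsive_part

__all__ = [
    "build_signaling",
    "build_inhibitor",
    "build_reaction",
    "build_dna",
    "build_fixture",
    "default_integrator",
    "default_initial",
    "random_initial_config",
    "FIXTURES",
]

#: relative bond-length fluctuation the constraint springs allow (sigma/r0)
_CONSTRAINT_SIGMA = 0.02


def _rod(name: str, i: int, j: int, r0: float, k: float, mass: float) -> Entity:
    return Entity(
        name=name,
        particles=(i, j),
        masses=(mass, mass),
        bonds=((pair(i, j), Harmonic(k=k, r0=r0)),),
        reference=((0.0, 0.0), (r0, 0.0)),
    )


def _constraint_k(kT: float, r0: float) -> float:
    # <dr^2> = kT/k for the radial mode; keep sigma at 2% of the rest length
    return kT / (_CONSTRAINT_SIGMA * r0) ** 2


def build_signaling(
    R: float = 3.0,
    D: float = 100.0,
    a: float = 1.0,
    r_eq: float = 2.0,
    n: int = 6,
    rod_r0: float = 2.0,
    mass: float = 1.0,
    temperature: float = 20.0,
) -> System:
    """Motivating three-rod system with a single switched A-B bond."""
    k = _constraint_k(temperature, rod_r0)
    system = System(
        entities=[
            _rod("A", 1, 2, rod_r0, k, mass),
            _rod("B", 3, 4, rod_r0, k, mass),
            _rod("C", 5, 6, rod_r0, k, mass),
        ],
        dim=2,
        force_mode="frozen_switch",
        confinement=Confinement(k=10.0, radius=7.0),
    )
    system.add_term(
        pair(2, 3), Morse(D, a, r_eq), Not(Near(pair(2, 5), R)), n_default=n
    )
    return system


def build_inhibitor(
    R25: float = 3.0,
    R36: float = 3.0,
    D: float = 100.0,
    a: float = 1.0,
    r_eq: float = 2.0,
    n: int = 6,
    rod_r0: float = 2.0,
    mass: float = 1.0,
    temperature: float = 20.0,
) -> System:
    """Inhibitor mechanism: C blocks the A-B complex via either contact.

    Terms (multiplicity identically 1):
        Phi(2,3) gated by NOT(near(2,5) OR near(3,6))
        Phi(2,5) gated by NOT(near(3,6))
        Phi(3,6) gated by NOT(near(2,5))
    """
    k = _constraint_k(temperature, rod_r0)
    system = System(
        entities=[
            _rod("A", 1, 2, rod_r0, k, mass),
            _rod("B", 3, 4, rod_r0, k, mass),
            _rod("C", 5, 6, rod_r0, k, mass),
        ],
        dim=2,
        force_mode="frozen_switch",
        confinement=Confinement(k=10.0, radius=7.0),
    )
    c25 = Near(pair(2, 5), R25)
    c36 = Near(pair(3, 6), R36)
    morse = Morse(D, a, r_eq)
    system.add_term(pair(2, 3), morse, Not(Or((c25, c36))), n_default=n)
    system.add_term(pair(2, 5), morse, Not(c36), n_default=n)
    system.add_term(pair(3, 6), morse, Not(c25), n_default=n)
    return system


def inhibitor_logic() -> list[tuple[str, Expr]]:
    """The three inhibitor logic functions as (name, expression) rows."""
    sys_ = build_inhibitor()
    return [(t.label.replace(",1", ""), t.logic) for t in sys_.terms]


def build_reaction(
    bias: float = 1.0,
    D_AB: float = 100.0,
    a: float = 1.0,
    r_eq: float = 2.0,
    R_off_factor: float = 1.5,
    n: int = 6,
    rod_r0: float = 2.0,
    mass: float = 1.0,
    temperature: float = 40.0,
) -> System:
    """Bond-breaking exchange AB + C <-> AC + B with well-depth ratio ``bias``.

    A is the rod (1,2); B and C carry one reactive site each (3 and 5)
    plus a passive partner site.  The A-B bond lives on (1,3) and is
    switched by the (2,5) distance; the A-C bond lives on (2,5) and is
    switched by (1,3).  Each reactive pair also carries the repulsive
    Morse branch, on exactly when the stable bond is off (multiplicity 2).
    The switch-off radius is ``R_off_factor`` times the partner bond's
    equilibrium length, so a bond is already off before the attacker
    reaches its own equilibrium distance.
    """
    if bias <= 0:
        raise ValueError(f"well-depth bias ratio must be positive, got {bias}")
    k = _constraint_k(temperature, rod_r0)
    system = System(
        entities=[
            _rod("A", 1, 2, rod_r0, k, mass),
            _rod("B", 3, 4, rod_r0, k, mass),
            _rod("C", 5, 6, rod_r0, k, mass),
        ],
        dim=2,
        force_mode="full",
        confinement=Confinement(k=10.0, radius=7.0),
    )
    morse_ab = Morse(D_AB, a, r_eq)
    morse_ac = Morse(bias * D_AB, a, r_eq)
    R_off_13 = R_off_factor * morse_ac.r_eq   # threshold on r(2,5), switches (1,3)
    R_off_25 = R_off_factor * morse_ab.r_eq   # threshold on r(1,3), switches (2,5)
    c_attack_ab = Near(pair(2, 5), R_off_13)
    c_attack_ac = Near(pair(1, 3), R_off_25)
    system.add_term(pair(1, 3), morse_ab, Not(c_attack_ab), n_default=n)
    system.add_term(pair(1, 3), repulsive_part(morse_ab), c_attack_ab, n_default=n)
    system.add_term(pair(2, 5), morse_ac, Not(c_attack_ac), n_default=n)
    system.add_term(pair(2, 5), repulsive_part(morse_ac), c_attack_ac, n_default=n)
    return system


def build_dna(
    D_H: float = 100.0,
    D_SP: float = 150.0,
    D_pol: float = 100.0,
    a: float = 1.0,
    r_eq: float = 1.0,
    R_bond: float = 2.2,
    n: int = 6,
    base_spacing: float = 3.0,
    link_r0: float = 1.0,
    mass: float = 1.0,
    temperature: float = 5.0,
) -> System:
    """Transcription cartoon: sequential, promoter-gated base pairing.

    Particles: promoter (1,2); RNA polymerase (3,4); template strand
    A=5, C=6, T=7, G=8; free nucleotides U=(9,10,11), G=(12,13,14),
    A=(15,16,17), C=(18,19,20), each a base-sugar-phosphate chain.
    Base pairs bind through a hydrogen-bond-like Morse phi_H, the
    complementary backbone through a stronger covalent-like phi_SP.

    The rules, with Pr := near(1,3) AND near(2,4) (polymerase bound) and
    b1..b4 / k1..k3 the base-pair / backbone contact predicates:

        L(1,3) = L(2,4) = NOT(k1 k2 k3 AND (b1 OR b2 OR b3 OR b4))
        L(5,9)   = Pr AND NOT(k1 k2 k3)
        L(6,12)  = Pr AND b1 AND NOT(k1 k2 k3)
        L(11,13) = (Pr AND b1 AND b2) OR (k2 AND k3)
        L(7,15)  = Pr AND b1 AND b2 AND k1 AND NOT(k1 k2 k3)
        L(14,16) = (Pr AND b1 AND b2 AND b3 AND k1) OR (k1 AND k3)
        L(8,18)  = Pr AND b1 AND b2 AND b3 AND k1 AND k2 AND NOT(k1 k2 k3)
        L(17,19) = (Pr AND b1 AND b2 AND b3 AND b4 AND k1 AND k2)
                   OR (k1 AND k2 AND NOT(b1 OR b2 OR b3 OR b4))
                   OR (k1 AND k2 AND NOT Pr)

    "Remains on once the backbone has formed" is encoded by the backbone
    conjunction excluding the rule's own pair (self-reference being
    forbidden); "still attached" means any base-pair contact holds.
    """
    k = _constraint_k(temperature, link_r0)

    def chain(name: str, ids: tuple[int, ...], spacing: float) -> Entity:
        bonds = tuple(
            (pair(ids[i], ids[i + 1]), Harmonic(k=k, r0=spacing))
            for i in range(len(ids) - 1)
        )
        ref = tuple((i * spacing, 0.0) for i in range(len(ids)))
        return Entity(name, ids, (mass,) * len(ids), bonds, reference=ref)

    system = System(
        entities=[
            chain("promoter", (1, 2), 2.0),
            chain("pol", (3, 4), 2.0),
            chain("template", (5, 6, 7, 8), base_spacing),
            chain("U", (9, 10, 11), link_r0),
            chain("G", (12, 13, 14), link_r0),
            chain("A", (15, 16, 17), link_r0),
            chain("C", (18, 19, 20), link_r0),
        ],
        dim=2,
        force_mode="frozen_switch",
        confinement=Confinement(k=10.0, radius=10.0),
    )

    def near(i: int, j: int) -> Near:
        return Near(pair(i, j), R_bond)

    Pr = And((near(1, 3), near(2, 4)))
    b1, b2, b3, b4 = near(5, 9), near(6, 12), near(7, 15), near(8, 18)
    k1, k2, k3 = near(11, 13), near(14, 16), near(17, 19)
    backbone = And((k1, k2, k3))
    attached = Or((b1, b2, b3, b4))

    phi_H = Morse(D_H, a, r_eq)
    phi_SP = Morse(D_SP, a, r_eq)
    phi_pol = Morse(D_pol, a, r_eq)

    pol_logic = Not(And((backbone, attached)))
    system.add_term(pair(1, 3), phi_pol, pol_logic, n_default=n)
    system.add_term(pair(2, 4), phi_pol, pol_logic, n_default=n)
    system.add_term(pair(5, 9), phi_H, And((Pr, Not(backbone))), n_default=n)
    system.add_term(pair(6, 12), phi_H, And((Pr, b1, Not(backbone))), n_default=n)
    system.add_term(
        pair(11, 13), phi_SP, Or((And((Pr, b1, b2)), And((k2, k3)))), n_default=n
    )
    system.add_term(
        pair(7, 15), phi_H, And((Pr, b1, b2, k1, Not(backbone))), n_default=n
    )
    system.add_term(
        pair(14, 16),
        phi_SP,
        Or((And((Pr, b1, b2, b3, k1)), And((k1, k3)))),
        n_default=n,
    )
    system.add_term(
        pair(8, 18), phi_H, And((Pr, b1, b2, b3, k1, k2, Not(backbone))), n_default=n
    )
    system.add_term(
        pair(17, 19),
        phi_SP,
        Or((
            And((Pr, b1, b2, b3, b4, k1, k2)),
            And((k1, k2, Not(attached))),
            And((k1, k2, Not(Pr))),
        )),
        n_default=n,
    )
    return system


FIXTURES = {
    "signaling": build_signaling,
    "inhibitor": build_inhibitor,
    "reaction": build_reaction,
    "dna": build_dna,
}

_DEFAULT_RUNS = {
    "signaling": IntegratorParams(
        dt=0.002, n_steps=50_000, temperature=20.0, friction=1.0, stride=50
    ),
    "inhibitor": IntegratorParams(
        dt=0.002, n_steps=100_000, temperature=20.0, friction=1.0, stride=50
    ),
    "reaction": IntegratorParams(
        dt=0.002, n_steps=200_000, temperature=40.0, friction=1.0, stride=100
    ),
    "dna": IntegratorParams(
        dt=0.002, n_steps=200_000, temperature=5.0, friction=1.0, stride=100
    ),
}

_DEFAULT_INITIAL = {
    "signaling": dict(box=10.0, min_separation=4.0, preformed=[(pair(2, 3), 2.0)]),
    "inhibitor": dict(box=10.0, min_separation=4.0, preformed=[(pair(2, 3), 2.0)]),
    "reaction": dict(box=10.0, min_separation=5.0, preformed=[(pair(1, 3), 2.0)]),
    "dna": dict(box=16.0, min_separation=3.5, preformed=[]),
}


def build_fixture(name: str, **overrides) -> System:
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder(**overrides)


def default_integrator(name: str, seed: int = 0) -> IntegratorParams:
    if name not in _DEFAULT_RUNS:
        raise ValueError(f"unknown fixture {name!r}")
    return replace(_DEFAULT_RUNS[name], seed=seed)


def default_initial(name: str) -> dict:
    if name not in _DEFAULT_INITIAL:
        raise ValueError(f"unknown fixture {name!r}")
    spec = _DEFAULT_INITIAL[name]
    return dict(spec, preformed=list(spec["preformed"]))


def random_initial_config(
    system: System,
    box: float,
    min_separation: float,
    seed: int,
    preformed: list[tuple[AtomPair, float]] | None = None,
    max_attempts: int = 2000,
) -> Configuration:
    """Place entities at their rest geometry with random centers/orientations.

    Entity centers are drawn uniformly in the cube of half-extent
    ``box`` and rejected until all inter-entity site distances are at
    least ``min_separation``.  ``preformed`` constraints pin a pair to a
    given distance (e.g. a pre-formed complex): the entity owning the
    second particle is placed so the pair sits exactly at that distance,
    and separation checks are skipped between the linked entities.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    preformed = list(preformed or [])
    d = system.dim

    def rest_coords(ent: Entity) -> np.ndarray:
        if ent.reference is not None:
            ref = np.asarray(ent.reference, dtype=float)
        elif len(ent.particles) == 1:
            ref = np.zeros((1, d))
        elif len(ent.particles) == 2 and ent.bonds:
            r0 = ent.bonds[0][1].r0
            ref = np.array([[0.0] * d, [r0] + [0.0] * (d - 1)])
        else:
            raise ValueError(
                f"entity {ent.name} needs a reference geometry for placement"
            )
        if ref.shape[1] != d:
            raise ValueError(f"entity {ent.name}: reference dimension mismatch")
        return ref - ref.mean(axis=0)

    def random_rotation() -> np.ndarray:
        if d == 1:
            return np.array([[rng.choice([-1.0, 1.0])]])
        if d == 2:
            t = rng.uniform(0.0, 2.0 * math.pi)
            return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        # 3-D: QR of a Gaussian matrix, sign-fixed
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        return q * np.sign(np.diag(r))

    owner = {pid: k for k, ent in enumerate(system.entities) for pid in ent.particles}
    linked: dict[int, list[tuple[int, AtomPair, float]]] = {}
    for p, r_target in preformed:
        ka, kb = owner[p.i], owner[p.j]
        if ka == kb:
            raise ValueError(f"preformed pair {p} lies within a single entity")
        late, early = max(ka, kb), min(ka, kb)
        linked.setdefault(late, []).append((early, p, r_target))

    placed: list[np.ndarray | None] = [None] * len(system.entities)
    linked_pairs = {
        frozenset((early, late)) for late, cs in linked.items() for early, _, _ in cs
    }

    def ok(k: int, coords: np.ndarray) -> bool:
        for other, oc in enumerate(placed):
            if oc is None or other == k:
                continue
            if frozenset((k, other)) in linked_pairs:
                continue
            dists = np.linalg.norm(coords[:, None, :] - oc[None, :, :], axis=2)
            if dists.min() < min_separation:
                return False
        return True

    for k, ent in enumerate(system.entities):
        base = rest_coords(ent)
        success = False
        for _ in range(max_attempts):
            coords = base @ random_rotation().T
            if k in linked:
                early, p, r_target = linked[k][0]
                anchor_ent = system.entities[early]
                anchor_xy = placed[early][anchor_ent.particles.index(p.i if owner[p.i] == early else p.j)]
                own_pid = p.j if owner[p.j] == k else p.i
                own_local = coords[ent.particles.index(own_pid)]
                direction = random_rotation()[:, 0]
                coords = coords + (anchor_xy + r_target * direction - own_local)
            else:
                center = rng.uniform(-box / 2.0, box / 2.0, size=d)
                coords = coords + center
            if ok(k, coords):
                placed[k] = coords
                success = True
                break
        if not success:
            raise RuntimeError(
                f"could not place entity {ent.name} after {max_attempts} attempts; "
                "try a larger box or smaller min_separation"
            )

    positions = np.zeros((system.n_particles, d))
    for ent, coords in zip(system.entities, placed):
        for pid, xy in zip(ent.particles, coords):
            positions[pid - 1] = xy
    return Configuration(positions)
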