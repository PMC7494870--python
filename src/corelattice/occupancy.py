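"""Occupancy patterns, steric exclusion, enumeration and symmetry classes.

A PX trimer bound interior to one E2 trimer occupies that trimer's vertex and
its three incident bridge pockets, and its "basket" sterically forbids
another basket within two intermediate trimers.  On the lattice graph this is
a pairwise minimum-distance rule: occupied vertices must be at graph distance
>= 3 of each other (occluding trimers), or >= 2 for hypothetical
non-occluding trimers (simple non-adjacency).

Valid occupancies are enumerated exhaustively and partitioned into orbits of
the proper rotation group; each orbit is a :class:`ConfigurationClass` with a
canonical representative, orbit size, stabilizer order, point-group label and
a jammed flag (no further valid addition possible).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np

from .lattice import CoreLattice, RotationGroup

__all__ = [
    "ExclusionRule",
    "OCCLUDING_RULE",
    "NON_OCCLUDING_RULE",
    "ConfigurationClass",
    "is_valid",
    "is_jammed",
    "enumerate_valid",
    "classify",
    "canonical_form",
    "point_group_label",
]

Occupancy = frozenset  # set of occupied vertex ids


@dataclass(frozen=True)
class ExclusionRule:
    """Minimum allowed graph distance between occupied trimer sites.

    ``min_distance=3`` encodes volume-occluding baskets (two occupied trimers
    need at least two intermediate trimers between them); ``min_distance=2``
    encodes non-occluding trimers (non-adjacency); ``min_distance=1`` means
    no exclusion at all.
    """

    min_distance: int = 3
    description: str = ""

    def __post_init__(self):
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")


OCCLUDING_RULE = ExclusionRule(3, "volume-occluding interior trimers")
NON_OCCLUDING_RULE = ExclusionRule(2, "non-occluding interior trimers")


@dataclass(frozen=True)
class ConfigurationClass:
    """One rotation-orbit of valid occupancies.

    ``canonical`` is the lexicographically minimal sorted image of the
    occupancy under the rotation group, so class identity is independent of
    which labelled member was supplied.  ``orbit_size * stabilizer_order``
    always equals the group order.
    """

    canonical: tuple[int, ...]
    size: int
    orbit_size: int
    stabilizer_order: int
    point_group: str
    jammed: bool
    alias: str | None = None
    members: tuple[tuple[int, ...], ...] = ()

    @property
    def occupancy(self) -> Occupancy:
        return frozenset(self.canonical)

    def to_dict(self) -> dict:
        return {
            "canonical": list(self.canonical),
            "size": self.size,
            "orbit_size": self.orbit_size,
            "stabilizer_order": self.stabilizer_order,
            "point_group": self.point_group,
            "jammed": self.jammed,
            "alias": self.alias,
        }


def _check_occ(core: CoreLattice, occ) -> frozenset:
    occ = frozenset(occ)
    for v in occ:
        core._check_vertex(v)
    return occ


def is_valid(occ, rule: ExclusionRule, core: CoreLattice) -> bool:
    """True iff every pair of occupied vertices is at distance >= the rule's minimum."""
    occ = sorted(_check_occ(core, occ))
    md = rule.min_distance
    return all(
        core.dist[u, v] >= md for i, u in enumerate(occ) for v in occ[i + 1 :]
    )


def _addable(core: CoreLattice, occ: frozenset, md: int) -> list[int]:
    return [
        v
        for v in core.vertices
        if v not in occ and all(core.dist[v, u] >= md for u in occ)
    ]


def is_jammed(occ, rule: ExclusionRule, core: CoreLattice) -> bool:
    """True iff no unoccupied vertex can be added without violating the rule."""
    occ = _check_occ(core, occ)
    if not is_valid(occ, rule, core):
        raise ValueError("occupancy is not valid under the exclusion rule")
    return not _addable(core, occ, rule.min_distance)


def enumerate_valid(
    core: CoreLattice, rule: ExclusionRule, size: int | None = None
) -> list[Occupancy]:
    """Exhaustively enumerate valid labelled occupancies.

    Depth-first extension adding only vertex ids larger than the current
    maximum, so each subset is produced exactly once.  Branches are pruned as
    soon as a pair violates the rule, which keeps the full enumeration
    (sizes 0..max) instantaneous on these lattices.

    Parameters
    ----------
    size : int, optional
        Restrict to occupancies of exactly this size; all sizes if omitted.

    Returns
    -------
    list of frozenset
        Deterministic order (sorted by size, then sorted vertex tuple).
    """
    if size is not None and size < 0:
        raise ValueError("size must be >= 0")
    md = rule.min_distance
    out: list[tuple[int, tuple[int, ...]]] = []

    def extend(current: list[int]) -> None:
        if size is None or len(current) == size:
            out.append((len(current), tuple(current)))
        if size is not None and len(current) == size:
            return
        start = current[-1] + 1 if current else 0
        for v in range(start, core.n_vertices):
            if all(core.dist[v, u] >= md for u in current):
                current.append(v)
                extend(current)
                current.pop()

    extend([])
    out.sort()
    return [frozenset(t) for _, t in out]


def canonical_form(occ, group: RotationGroup) -> tuple[int, ...]:
    """Lexicographically minimal sorted image of the occupancy over the group."""
    occ = tuple(occ)
    return min(tuple(sorted(p[v] for v in occ)) for p in group.permutations)


def _perm_order(perm: tuple[int, ...]) -> int:
    """Order of a permutation (lcm of cycle lengths)."""
    n = len(perm)
    seen = [False] * n
    order = 1
    for start in range(n):
        if seen[start]:
            continue
        length = 0
        v = start
        while not seen[v]:
            seen[v] = True
            v = perm[v]
            length += 1
        order = order * length // gcd(order, length)
    return order


def _compose(p: tuple[int, ...], q: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(p[q[i]] for i in range(len(p)))


def point_group_label(elements) -> str:
    """Name a finite proper rotation group from its element-order census.

    Parameters
    ----------
    elements : iterable of (permutation, matrix) pairs, or of permutations
        Must form a group (closed under composition, containing the
        identity); raises ``ValueError`` otherwise.

    Returns
    -------
    str
        ``C1``, ``Cn`` (cyclic), ``Dn`` (dihedral), ``T`` (order 12,
        8 threefold + 3 twofold rotations), ``O`` (order 24) or ``I``
        (order 60).
    """
    perms = [e[0] if isinstance(e, tuple) and not isinstance(e[0], (int, np.integer)) else e for e in elements]
    perms = [tuple(int(x) for x in p) for p in perms]
    n = len(perms)
    pset = set(perms)
    identity = tuple(range(len(perms[0])))
    if identity not in pset:
        raise ValueError("element set lacks the identity")
    for p in perms:
        for q in perms:
            if _compose(p, q) not in pset:
                raise ValueError("element set is not closed under composition")
    orders = sorted(_perm_order(p) for p in perms)
    census = {k: orders.count(k) for k in set(orders)}
    if n == 1:
        return "C1"
    if census == {1: 1, 2: 3, 3: 8}:
        return "T"
    if census == {1: 1, 2: 9, 3: 8, 4: 6}:
        return "O"
    if census == {1: 1, 2: 15, 3: 20, 5: 24}:
        return "I"
    if max(census) == n:  # a generator of the whole group exists
        return f"C{n}"
    m = n // 2
    twofolds = census.get(2, 0)
    expected_twofolds = m + 1 if m % 2 == 0 else m
    if n == 2 * m and census.get(m, 0) >= 1 and twofolds == expected_twofolds:
        return f"D{m}"
    return f"G{n}"  # pragma: no cover - not reachable for subgroups of I or O


# Paper-style aliases for the icosahedral lattice with occluding trimers:
# size-4 jammed classes are the tetrahedral saturated arrangements X4S/Y4S
# ("X" = lexicographically smaller canonical form; the pairing with the
# deposited X and Y maps is arbitrary without map registration), size-3 and
# size-2 jammed classes are the suboptimal 3S/2S, and with non-occluding
# trimers the size-8 saturated class is 8S.
def _alias_for(cls_size: int, jammed: bool, rank: int, rule: ExclusionRule,
               core: CoreLattice) -> str | None:
    if core.name != "icosahedral-60mer":
        return None
    if rule.min_distance == 3 and jammed:
        if cls_size == 4:
            return ("X4S", "Y4S")[rank] if rank < 2 else None
        if cls_size == 3:
            return "3S" if rank == 0 else f"3S-{rank}"
        if cls_size == 2:
            return "2S" if rank == 0 else f"2S-{rank}"
    if rule.min_distance == 2 and jammed and cls_size == 8:
        return "8S" if rank == 0 else f"8S-{rank}"
    return None


def classify(
    configs,
    group: RotationGroup,
    rule: ExclusionRule,
    core: CoreLattice,
) -> list[ConfigurationClass]:
    """Partition valid occupancies into rotation-orbits.

    Parameters
    ----------
    configs : iterable of vertex-id sets
        All must be valid under ``rule`` on ``core``.

    Returns
    -------
    list of ConfigurationClass
        Sorted by (size, canonical form).  One class per orbit, with the
        canonical representative, orbit size, stabilizer order (their
        product equals the group order), point-group label and jammed flag.
    """
    by_canon: dict[tuple[int, ...], set[tuple[int, ...]]] = {}
    for occ in configs:
        occ = _check_occ(core, occ)
        if not is_valid(occ, rule, core):
            raise ValueError(f"occupancy {sorted(occ)} violates the exclusion rule")
        canon = canonical_form(occ, group)
        by_canon.setdefault(canon, set()).add(tuple(sorted(occ)))

    classes = []
    rank_by_size: dict[tuple[int, bool], int] = {}
    for canon in sorted(by_canon, key=lambda c: (len(c), c)):
        occ = frozenset(canon)
        orbit = {tuple(sorted(group.apply(p, occ))) for p in group.permutations}
        stab = [
            (p, m) for p, m in group.elements if group.apply(p, occ) == occ
        ]
        assert len(orbit) * len(stab) == group.order
        jam = is_jammed(occ, rule, core)
        key = (len(canon), jam)
        rank = rank_by_size.get(key, 0)
        rank_by_size[key] = rank + 1
        classes.append(
            ConfigurationClass(
                canonical=canon,
                size=len(canon),
                orbit_size=len(orbit),
                stabilizer_order=len(stab),
                point_group=point_group_label(stab),
                jammed=jam,
                alias=_alias_for(len(canon), jam, rank, rule, core),
                members=tuple(sorted(by_canon[canon])),
            )
        )
    return classes


def enumerate_classes(
    core: CoreLattice,
    group: RotationGroup,
    rule: ExclusionRule,
    size: int | None = None,
) -> list[ConfigurationClass]:
    """Enumerate valid occupancies and classify them in one step."""
    return classify(enumerate_valid(core, rule, size), group, rule, core)
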