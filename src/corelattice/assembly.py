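"""Sequential attachment of PX trimers to the core, exact and Monte Carlo.

The naive assembly model: trimeric PX oligomers attach one at a time to a
preformed core, each attachment choosing uniformly among the vertices whose
addition keeps the occupancy valid under the steric-exclusion rule; the
process is irreversible and stops (jams) when no valid vertex remains.  The
exact absorbing-state distribution of this Markov chain is computed by
recursion with memoization on canonical forms; on the icosahedral core with
occluding baskets each of the two tetrahedral saturated arrangements
receives exactly 3/20 = 15% of the probability mass.

A co-assembly variant lets PX bind while the core itself grows: core
vertices appear in uniformly random order, a vertex becomes PX-competent
once it and its three neighbours are present (its bridge pockets then
exist), and each newly competent, non-excluded vertex binds immediately with
probability ``p_bind``; any sites still addable after core completion fill
sequentially as in the preformed-core model.  ``p_bind=0`` reduces to the
preformed-core chain; ``p_bind>0`` probes the co-assembly enrichment
hypothesis for the saturated tetrahedral arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .lattice import CoreLattice, RotationGroup, rotation_group
from .occupancy import (
    ConfigurationClass,
    ExclusionRule,
    canonical_form,
    classify,
)

__all__ = [
    "JammingDistribution",
    "AssemblyTrajectory",
    "exact_jamming_distribution",
    "simulate_rsa",
    "simulate_coassembly",
]


@dataclass(frozen=True)
class AssemblyTrajectory:
    """One realization: attachment events in order, plus the terminal state."""

    events: tuple[tuple[int, int], ...]  # (vertex id, step index)
    terminal: frozenset
    core_growth_order: tuple[int, ...] | None = None


@dataclass(frozen=True)
class JammingDistribution:
    """Probability over terminal (jammed) configuration classes.

    Keys of ``probabilities`` are canonical forms; ``classes`` maps each key
    to its :class:`ConfigurationClass` (with alias, symmetry, etc.).
    Probabilities are exact rationals for the exact recursion and exact
    frequencies (count / n_runs) for Monte Carlo.
    """

    probabilities: dict[tuple[int, ...], Fraction]
    classes: dict[tuple[int, ...], ConfigurationClass]
    provenance: str  # "exact" | "monte_carlo"
    n_runs: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        assert all(p >= 0 for p in self.probabilities.values())
        assert sum(self.probabilities.values()) == 1

    def by_alias(self) -> dict[str, float]:
        """Probabilities keyed by paper-style alias (canonical tuple otherwise)."""
        out = {}
        for canon, p in self.probabilities.items():
            cls = self.classes[canon]
            out[cls.alias or str(canon)] = float(p)
        return out

    def prob_terminal_size(self, size: int) -> Fraction:
        return sum(
            (p for c, p in self.probabilities.items() if len(c) == size),
            Fraction(0),
        )

    @property
    def saturation_probability(self) -> Fraction:
        """Mass on terminal states of maximal size (complete interiors)."""
        if not self.probabilities:
            return Fraction(0)
        return self.prob_terminal_size(max(len(c) for c in self.probabilities))

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "classes": [
                {
                    **self.classes[c].to_dict(),
                    "probability": float(p),
                    "probability_exact": str(p),
                }
                for c, p in sorted(self.probabilities.items(), key=lambda kv: (len(kv[0]), kv[0]))
            ],
            **self.extra,
        }


def _addable_mask(core: CoreLattice, occ, md: int) -> list[int]:
    return [
        v
        for v in core.vertices
        if v not in occ and all(core.dist[v, u] >= md for u in occ)
    ]


def _finish(
    core: CoreLattice,
    rule: ExclusionRule,
    group: RotationGroup,
    terminal_probs: dict[tuple[int, ...], Fraction],
    provenance: str,
    **meta,
) -> JammingDistribution:
    classes = classify(
        [frozenset(c) for c in terminal_probs], group, rule, core
    )
    class_map = {cls.canonical: cls for cls in classes}
    return JammingDistribution(
        probabilities=dict(terminal_probs),
        classes=class_map,
        provenance=provenance,
        **meta,
    )


def exact_jamming_distribution(
    core: CoreLattice,
    rule: ExclusionRule,
    group: RotationGroup | None = None,
) -> JammingDistribution:
    """Exact terminal-class probabilities of the sequential-attachment chain.

    Recursion over occupancy states: from state S, each addable vertex is
    chosen with probability 1/|addable(S)|; absorption when addable(S) is
    empty.  States are memoized on their canonical form under the rotation
    group — the chain's law is symmetry-invariant, so symmetric states have
    identical terminal distributions up to relabelling, and terminal mass is
    accumulated directly on canonical forms.  All arithmetic is in exact
    rationals.
    """
    if rule.min_distance < 2:
        raise ValueError("sequential attachment needs min_distance >= 2")
    if group is None:
        group = rotation_group(core)
    md = rule.min_distance
    memo: dict[tuple[int, ...], dict[tuple[int, ...], Fraction]] = {}

    def recurse(occ: frozenset) -> dict[tuple[int, ...], Fraction]:
        canon = canonical_form(occ, group)
        hit = memo.get(canon)
        if hit is not None:
            return hit
        # recurse from the canonical representative itself: its terminal
        # distribution (already over canonical forms) equals that of occ
        rep = frozenset(canon)
        addable = _addable_mask(core, rep, md)
        if not addable:
            res = {canon: Fraction(1)}
        else:
            res = {}
            w = Fraction(1, len(addable))
            for v in addable:
                for t, p in recurse(rep | {v}).items():
                    res[t] = res.get(t, Fraction(0)) + w * p
        memo[canon] = res
        return res

    terminal = recurse(frozenset())
    return JammingDistribution(
        probabilities=dict(terminal),
        classes={
            cls.canonical: cls
            for cls in classify(
                [frozenset(c) for c in terminal], group, rule, core
            )
        },
        provenance="exact",
        extra={"n_states_visited": len(memo)},
    )


def simulate_rsa(
    core: CoreLattice,
    rule: ExclusionRule,
    n_runs: int,
    seed: int,
    group: RotationGroup | None = None,
    return_trajectories: bool = False,
):
    """Monte-Carlo random sequential attachment to a preformed core.

    A single numpy Generator seeded with ``seed`` drives all runs in
    sequence, so identical (seed, n_runs) gives identical output.

    Returns
    -------
    JammingDistribution, or (JammingDistribution, list of AssemblyTrajectory)
        Frequencies are exact fractions count / n_runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rule.min_distance < 2:
        raise ValueError("sequential attachment needs min_distance >= 2")
    if group is None:
        group = rotation_group(core)
    md = rule.min_distance
    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, ...], int] = {}
    trajectories: list[AssemblyTrajectory] = []
    for _ in range(n_runs):
        occ: set[int] = set()
        events = []
        while True:
            addable = _addable_mask(core, occ, md)
            if not addable:
                break
            v = addable[rng.integers(len(addable))]
            events.append((v, len(occ)))
            occ.add(v)
        canon = canonical_form(occ, group)
        counts[canon] = counts.get(canon, 0) + 1
        if return_trajectories:
            trajectories.append(AssemblyTrajectory(tuple(events), frozenset(occ)))
    probs = {c: Fraction(k, n_runs) for c, k in counts.items()}
    dist = _finish(core, rule, group, probs, "monte_carlo", n_runs=n_runs, seed=seed)
    return (dist, trajectories) if return_trajectories else dist


def simulate_coassembly(
    core: CoreLattice,
    rule: ExclusionRule,
    p_bind: float,
    n_runs: int,
    seed: int,
    group: RotationGroup | None = None,
) -> JammingDistribution:
    """Monte-Carlo co-assembly: PX binds while the core grows.

    Core vertices are added in uniformly random order.  A vertex becomes
    PX-competent at the moment it and its three neighbours are all present
    (all three bridge pockets exist).  When several vertices become
    competent at the same growth step their processing order is randomized.
    Each newly competent vertex that is not excluded by already-bound PX
    binds immediately with probability ``p_bind``.  After the core is
    complete, remaining valid vertices fill sequentially as in
    :func:`simulate_rsa`.  ``p_bind=0`` is distributionally identical to the
    preformed-core chain.
    """
    if not 0.0 <= p_bind <= 1.0:
        raise ValueError("p_bind must lie in [0, 1]")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rule.min_distance < 2:
        raise ValueError("sequential attachment needs min_distance >= 2")
    if group is None:
        group = rotation_group(core)
    md = rule.min_distance
    n = core.n_vertices
    closures = [frozenset((v, *core.neighbors(v))) for v in core.vertices]
    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, ...], int] = {}
    for _ in range(n_runs):
        order = rng.permutation(n)
        arrival = np.empty(n, dtype=int)
        arrival[order] = np.arange(n)
        # competence time of v = growth step at which the last member of
        # {v} + neighbours(v) arrives
        competence = np.array([max(arrival[u] for u in closures[v]) for v in range(n)])
        occ: set[int] = set()
        if p_bind > 0.0:
            for step in range(n):
                newly = [v for v in range(n) if competence[v] == step]
                if len(newly) > 1:
                    newly = [newly[i] for i in rng.permutation(len(newly))]
                for v in newly:
                    if all(core.dist[v, u] >= md for u in occ):
                        if rng.random() < p_bind:
                            occ.add(v)
        # post-completion fill, identical to the preformed-core chain
        while True:
            addable = _addable_mask(core, occ, md)
            if not addable:
                break
            occ.add(addable[rng.integers(len(addable))])
        canon = canonical_form(occ, group)
        counts[canon] = counts.get(canon, 0) + 1
    probs = {c: Fraction(k, n_runs) for c, k in counts.items()}
    return _finish(
        core,
        rule,
        group,
        probs,
        "monte_carlo",
        n_runs=n_runs,
        seed=seed,
        extra={"mode": "coassembly", "p_bind": p_bind},
    )
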