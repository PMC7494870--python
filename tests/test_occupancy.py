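"""Exclusion rule, exhaustive enumeration, orbit classification, symmetry labels."""

from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corelattice import (
    ExclusionRule,
    canonical_form,
    classify,
    enumerate_classes,
    enumerate_valid,
    is_jammed,
    is_valid,
    point_group_label,
)


def cube_inscribed(dodeca, rule2, dodeca_group):
    """The 8 vertices of one inscribed coordinate cube."""
    classes = enumerate_classes(dodeca, dodeca_group, rule2, 8)
    return frozenset(classes[0].canonical)


class TestValidity:
    def test_adjacent_pair_invalid_under_occlusion(self, dodeca, rule3):
        u, v = dodeca.edges[0]
        assert not is_valid({u, v}, rule3, dodeca)
        assert is_valid({u}, rule3, dodeca)

    def test_inscribed_cube_valid_only_without_occlusion(
        self, dodeca, dodeca_group, rule2, rule3
    ):
        cube8 = cube_inscribed(dodeca, rule2, dodeca_group)
        assert is_valid(cube8, rule2, dodeca)  # pairwise distance >= 2
        assert not is_valid(cube8, rule3, dodeca)  # cube-edge pairs at distance 2

    def test_min_distance_one_admits_everything(self, dodeca):
        assert is_valid(set(dodeca.vertices), ExclusionRule(1), dodeca)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            ExclusionRule(0)


class TestEnumeration:
    @pytest.mark.parametrize(
        "size, expected",
        [(0, 1), (1, 20), (2, 100), (3, 100), (4, 10), (5, 0), (6, 0)],
    )
    def test_occluding_counts_by_size(self, dodeca, rule3, size, expected):
        # size 2: 190 pairs minus 30 adjacent minus 60 at distance 2
        assert len(enumerate_valid(dodeca, rule3, size)) == expected

    def test_full_enumeration_is_union_over_sizes(self, dodeca, rule3):
        full = enumerate_valid(dodeca, rule3)
        assert len(full) == 1 + 20 + 100 + 100 + 10
        assert len(set(full)) == len(full)

    def test_occlusion_monotonicity(self, dodeca, rule2, rule3):
        """Every occupancy valid under occlusion is valid without it."""
        assert set(enumerate_valid(dodeca, rule3)) <= set(enumerate_valid(dodeca, rule2))

    @pytest.mark.parametrize(
        "min_distance, max_size", [(2, 8), (3, 4)]
    )
    def test_maximum_occupancy(self, dodeca, min_distance, max_size):
        occs = enumerate_valid(dodeca, ExclusionRule(min_distance))
        assert max(len(o) for o in occs) == max_size

    def test_no_exclusion_counts_binomial(self, dodeca):
        # sanity against closed form: all subsets are valid at min_distance=1
        rule1 = ExclusionRule(1)
        assert len(enumerate_valid(dodeca, rule1, 3)) == comb(20, 3)


class TestClassification:
    def test_two_tetrahedral_classes(self, tetra_classes):
        """The 10 maximal occupancies fall into exactly 2 rotation classes,
        each a tetrahedral (T, order-12) arrangement of 5 labelled copies."""
        assert len(tetra_classes) == 2
        for cls in tetra_classes:
            assert cls.size == 4
            assert cls.orbit_size == 5
            assert cls.stabilizer_order == 12
            assert cls.point_group == "T"
            assert cls.jammed
        assert {c.alias for c in tetra_classes} == {"X4S", "Y4S"}

    def test_empty_occupancy_has_full_icosahedral_symmetry(
        self, dodeca, dodeca_group, rule3
    ):
        (cls,) = classify([frozenset()], dodeca_group, rule3, dodeca)
        assert cls.stabilizer_order == 60
        assert cls.point_group == "I"
        assert cls.orbit_size == 1

    def test_size8_maximal_classes_are_tetrahedral(self, dodeca, dodeca_group, rule2):
        classes = enumerate_classes(dodeca, dodeca_group, rule2, 8)
        assert classes, "size-8 non-occluding occupancies must exist"
        assert all(c.point_group == "T" for c in classes)
        # empirically: a single class of 5 labelled copies — the inscribed cubes
        assert [(c.orbit_size, c.stabilizer_order) for c in classes] == [(5, 12)]

    def test_orbit_stabilizer_product_over_all_sizes(self, dodeca, dodeca_group, rule3):
        classes = classify(
            enumerate_valid(dodeca, rule3), dodeca_group, rule3, dodeca
        )
        for cls in classes:
            assert cls.orbit_size * cls.stabilizer_order == 60
        # orbit sizes partition the labelled enumeration at each size
        for size, count in [(0, 1), (1, 20), (2, 100), (3, 100), (4, 10)]:
            assert sum(c.orbit_size for c in classes if c.size == size) == count

    def test_classification_agrees_with_naive_orbit_oracle(
        self, dodeca, dodeca_group, rule3
    ):
        """Canonical-form classes match naive pairwise orbit testing."""
        valid = enumerate_valid(dodeca, rule3)
        canon_of = {occ: canonical_form(occ, dodeca_group) for occ in valid}
        for a in valid[::7]:  # systematic subsample of anchors
            orbit_a = {
                frozenset(p[v] for v in a) for p in dodeca_group.permutations
            }
            for b in valid:
                same_naive = b in orbit_a
                assert same_naive == (canon_of[a] == canon_of[b])

    def test_invalid_config_rejected(self, dodeca, dodeca_group, rule3):
        u, v = dodeca.edges[0]
        with pytest.raises(ValueError, match="violates"):
            classify([frozenset((u, v))], dodeca_group, rule3, dodeca)


class TestChirality:
    def test_tetrahedral_classes_rotation_inequivalent_but_mirror_related(
        self, tetra_classes, dodeca_group, inversion_partner
    ):
        a, b = (frozenset(c.canonical) for c in tetra_classes)
        # no proper rotation maps one onto the other
        assert canonical_form(a, dodeca_group) != canonical_form(b, dodeca_group)
        # but the central inversion exchanges them
        mirrored = frozenset(inversion_partner[v] for v in a)
        assert canonical_form(mirrored, dodeca_group) == canonical_form(
            b, dodeca_group
        )


class TestPointGroupLabel:
    def test_antipodal_pair_stabilizer_is_d3(self, dodeca, dodeca_group):
        pair = frozenset((0, 19))
        assert dodeca.dist[0, 19] == 5
        stab = [
            (p, m)
            for p, m in dodeca_group.elements
            if frozenset(p[v] for v in pair) == pair
        ]
        assert len(stab) == 6
        assert point_group_label(stab) == "D3"

    def test_trivial_and_cyclic_labels(self, dodeca, dodeca_group):
        identity = dodeca_group.elements[0]
        assert point_group_label([identity]) == "C1"
        # stabilizer of a single vertex: the C3 about its radial axis
        stab = [
            (p, m)
            for p, m in dodeca_group.elements
            if p[0] == 0
        ]
        assert point_group_label(stab) == "C3"

    def test_whole_groups(self, dodeca_group, cube_group):
        assert point_group_label(list(dodeca_group.elements)) == "I"
        assert point_group_label(list(cube_group.elements)) == "O"

    def test_non_closed_set_rejected(self, dodeca_group):
        elems = list(dodeca_group.elements)[:7]  # identity + arbitrary others
        with pytest.raises(ValueError):
            point_group_label(elems)


class TestJamming:
    def test_antipodal_pair_is_jammed(self, dodeca, rule3):
        """The two radius-2 balls around antipodes cover all 20 vertices."""
        assert is_jammed({0, 19}, rule3, dodeca)

    def test_saturated_tetrahedra_are_jammed(self, dodeca, rule3, tetra_classes):
        for cls in tetra_classes:
            assert is_jammed(cls.occupancy, rule3, dodeca)

    def test_tetrahedron_minus_one_is_unsaturated(self, dodeca, rule3, tetra_classes):
        """Any 3-subset of a saturated arrangement is extendable (Y3U-style)."""
        for cls in tetra_classes:
            occ = sorted(cls.canonical)
            for drop in occ:
                sub = frozenset(occ) - {drop}
                assert not is_jammed(sub, rule3, dodeca)

    def test_jammed_requires_valid_input(self, dodeca, rule3):
        u, v = dodeca.edges[0]
        with pytest.raises(ValueError):
            is_jammed({u, v}, rule3, dodeca)


@settings(derandomize=True, max_examples=60)
@given(
    subset=st.sets(st.integers(min_value=0, max_value=19), max_size=6),
    gidx=st.integers(min_value=0, max_value=59),
)
def test_validity_and_canonical_form_are_rotation_invariant(
    dodeca, dodeca_group, subset, gidx
):
    """Rotating an occupancy changes neither its validity nor its class."""
    from corelattice import OCCLUDING_RULE

    core, group = dodeca, dodeca_group
    perm = group.permutations[gidx]
    image = frozenset(perm[v] for v in subset)
    assert is_valid(subset, OCCLUDING_RULE, core) == is_valid(
        image, OCCLUDING_RULE, core
    )
    assert canonical_form(subset, group) == canonical_form(image, group)
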