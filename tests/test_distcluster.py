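"""Forbes distances, evenness standardisation, constrained clustering."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodiv.distcluster import (
    DissimilarityMatrix,
    coniss,
    distance_matrix,
    forbes_corrected,
    rac_corrected_distance,
    redefine_zones,
)

from conftest import make_table, make_units


class TestForbes:
    def test_identical_sets_similarity_one(self):
        pc = forbes_corrected({"a", "b", "c"}, {"a", "b", "c"})
        assert pc.similarity == 1.0 and pc.distance == 0.0

    def test_disjoint_sets_similarity_zero(self):
        pc = forbes_corrected({"a"}, {"b", "c"})
        assert pc.similarity == 0.0 and pc.distance == 1.0

    def test_hand_derived_value(self):
        # a=2, b=1, c=1, n=4: F = 2(4+2) / (2(4+2) + 1.5) = 12/13.5
        pc = forbes_corrected({"s", "t", "x"}, {"s", "t", "y"})
        assert pc.similarity == pytest.approx(12 / 13.5)
        assert pc.distance == pytest.approx(1 - 12 / 13.5)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            forbes_corrected(set(), set())

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        x=st.sets(st.integers(0, 15)),
        y=st.sets(st.integers(0, 15)),
    )
    def test_symmetry_and_bounds_property(self, x, y):
        if not (x | y):
            return
        f_xy = forbes_corrected(x, y)
        f_yx = forbes_corrected(y, x)
        assert f_xy.similarity == pytest.approx(f_yx.similarity)
        assert 0.0 <= f_xy.distance <= 1.0
        if x == y:
            assert f_xy.distance == 0.0
        if not (x & y):
            assert f_xy.distance == 1.0

    def test_symmetry_and_bounds_random(self):
        rng = random.Random(31)
        universe = [f"t{i}" for i in range(12)]
        for _ in range(100):
            x = {t for t in universe if rng.random() < 0.4}
            y = {t for t in universe if rng.random() < 0.4}
            if not (x | y):
                continue
            f_xy = forbes_corrected(x, y)
            f_yx = forbes_corrected(y, x)
            assert f_xy.similarity == pytest.approx(f_yx.similarity)
            assert 0.0 <= f_xy.distance <= 1.0


class TestRACCorrection:
    def test_identical_vectors_near_zero(self):
        d = rac_corrected_distance([10, 10, 5], [10, 10, 5], replicates=2000, seed=4)
        assert d < 0.05

    def test_disjoint_units_exactly_one(self):
        d = rac_corrected_distance([5, 5, 0, 0], [0, 0, 5, 5], replicates=200, seed=4)
        assert d == 1.0

    def test_against_bruteforce_resampling_oracle(self):
        """Independent oracle with a different RNG (python random.sample)."""
        x, y = [10, 10], [18, 1, 1]
        # pad to a shared taxon universe: x has taxa 0,1; y has taxa 2,3,4
        xv = [10, 10, 0, 0, 0]
        yv = [0, 0, 18, 1, 1]
        m, reps = 5, 2000

        rng = random.Random(999)
        pool_x = [i for i, c in enumerate(xv) for _ in range(c)]
        pool_y = [i for i, c in enumerate(yv) for _ in range(c)]
        acc = 0.0
        for _ in range(reps):
            sx = set(rng.sample(pool_x, m))
            sy = set(rng.sample(pool_y, m))
            acc += forbes_corrected(sx, sy).distance
        oracle = acc / reps

        d = rac_corrected_distance(xv, yv, replicates=reps, seed=12, cap=m)
        assert d == pytest.approx(oracle, abs=0.02)

    def test_small_m_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            rac_corrected_distance([1], [1], replicates=10, seed=0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            rac_corrected_distance([0, 0], [1, 2])


class TestConiss:
    def test_two_units_single_merge(self):
        D = DissimilarityMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        d = coniss(D)
        assert len(d.merges) == 1
        assert d.merges[0].height == pytest.approx(0.4**2)

    def test_three_units_picks_cheapest_adjacent(self):
        # both admissible first merges evaluated exhaustively: (1,2) costs
        # 0.1^2, (2,3) costs 0.9^2 -> {1,2} merges first
        D = DissimilarityMatrix(
            ["u1", "u2", "u3"],
            np.array([[0, 0.1, 0.8], [0.1, 0, 0.9], [0.8, 0.9, 0]]),
        )
        d = coniss(D)
        assert {d.merges[0].left, d.merges[0].right} == {0, 1}

    def test_adjacency_and_monotone_heights_random(self):
        """Brute-force adjacency check of every merge on random matrices."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(3, 10))
            vals = rng.random((n, n))
            D = np.triu(vals, 1)
            D = D + D.T
            dendro = coniss(DissimilarityMatrix([f"u{i}" for i in range(n)], D))
            # replay merges tracking contiguous leaf ranges
            ranges = {i: (i, i) for i in range(n)}
            heights = []
            for step, m in enumerate(dendro.merges):
                lo1, hi1 = ranges.pop(m.left)
                lo2, hi2 = ranges.pop(m.right)
                assert hi1 + 1 == lo2 or hi2 + 1 == lo1, "non-adjacent merge"
                ranges[n + step] = (min(lo1, lo2), max(hi1, hi2))
                heights.append(m.height)
            assert heights == sorted(heights)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b"], np.array([[0, 0.5], [0.2, 0]]))

    def test_two_block_fixture_recovers_boundary(self):
        """Units forming two internally identical blocks split exactly at
        the block boundary when cut at k=2."""
        counts = np.array(
            [
                [5, 5, 5, 0, 0],
                [3, 3, 3, 0, 0],
                [0, 0, 0, 4, 4],
                [0, 0, 0, 6, 6],
            ]
        )
        t = make_table(counts)
        dist = distance_matrix(t, replicates=200, seed=6)
        d = coniss(dist)
        assert d.cut(2) == [["U0", "U1", "U2"], ["U3", "U4"]]

    def test_newick_parses_with_dendropy(self):
        import dendropy

        D = DissimilarityMatrix(
            ["Arroyo", "Vale", "Choza"],
            np.array([[0, 0.2, 0.7], [0.2, 0, 0.6], [0.7, 0.6, 0]]),
        )
        newick = coniss(D).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == 3
        labels = {leaf.taxon.label for leaf in tree.leaf_nodes()}
        assert labels == {"Arroyo", "Vale", "Choza"}


class TestRedefineZones:
    def _dendro(self, n=4):
        rng = np.random.default_rng(2)
        vals = rng.random((n, n))
        D = np.triu(vals, 1)
        return coniss(DissimilarityMatrix([f"U{i}" for i in range(n)], D + D.T))

    def test_k_equals_leaves_is_per_unit(self):
        d = self._dendro(4)
        scheme = redefine_zones(d, 4)
        assert [b.units for b in scheme.bins] == [("U0",), ("U1",), ("U2",), ("U3",)]

    def test_k_one_spans_section(self):
        d = self._dendro(4)
        scheme = redefine_zones(d, 1)
        assert scheme.bins[0].units == ("U0", "U1", "U2", "U3")

    def test_k_out_of_range(self):
        d = self._dendro(3)
        with pytest.raises(ValueError):
            d.cut(0)
        with pytest.raises(ValueError):
            d.cut(4)

    def test_majority_labels_with_older_tie_break(self):
        counts = np.array([[5, 5, 5, 0], [0, 0, 0, 4]])
        t = make_table(counts, zones=["Old", "Old", "Young", "Young"])
        dist = distance_matrix(t, replicates=100, seed=1)
        scheme = redefine_zones(coniss(dist), 2, units=t.units)
        # first cluster {U0,U1,U2}: majority Old; second {U3}: Young
        assert [b.label for b in scheme.bins] == ["Old", "Young"]
        assert scheme.bins[0].age_base == t.units[0].age_base
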