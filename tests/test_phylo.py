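import numpy as np
import pytest
from hypothesis import given, strategies as st

import gh57
from gh57.phylo import (
    PhyloError,
    bootstrap_support,
    monophyly_fraction,
    neighbor_joining,
    p_distance,
    pdistance_matrix,
    tree_splits,
)

from _oracles import least_squares_topology, random_additive_tree


def _tip_distances(tree):
    tips = list(tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestPDistance:
    def test_identical_and_disjoint(self):
        fp = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRS"
        assert p_distance(fp, fp) == 0.0
        shifted = fp[1:] + fp[0]
        assert 0.0 < p_distance(fp, shifted) <= 1.0
        other = "".join("L" if c != "L" else "V" for c in fp)
        assert p_distance(fp, other) == 1.0

    def test_quarter_distance(self):
        a = "A" * 36
        b = "C" * 9 + "A" * 27
        assert p_distance(a, b) == pytest.approx(9 / 36)

    def test_nonstandard_positions_excluded(self):
        a = "A" * 35 + "X"
        b = "A" * 34 + "CC"
        # position 36 dropped; one mismatch over 35 comparable positions
        assert p_distance(a, b) == pytest.approx(1 / 35)

    def test_length_mismatch_rejected(self):
        with pytest.raises(PhyloError):
            p_distance("AAA", "AA")

    @given(st.integers(min_value=0, max_value=5_000))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        aa = np.array(list(gh57.AA_ALPHABET))
        a = "".join(rng.choice(aa, size=36))
        b = "".join(rng.choice(aa, size=36))
        assert p_distance(a, b) == p_distance(b, a)
        assert 0.0 <= p_distance(a, b) <= 1.0

    def test_matrix_properties(self, small_dataset):
        fps = [s.fingerprint for s in small_dataset.sequences[:25]]
        ids = [s.id for s in small_dataset.sequences[:25]]
        dm = pdistance_matrix(fps, ids)
        D = np.asarray(dm.data)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5))
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        tree = neighbor_joining(D, ids=list("ABCD"))
        splits = tree_splits(tree, list("ABCD"))
        assert splits == {0b0011}  # AB | CD
        dists = _tip_distances(tree)
        assert dists[frozenset("AB")] == pytest.approx(5)
        assert dists[frozenset("AD")] == pytest.approx(8)
        assert dists[frozenset("CD")] == pytest.approx(9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(D, ids=list("ABC"))
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_leaf_count_preserved(self):
        rng = np.random.default_rng(2)
        n = 9
        M = rng.uniform(0.1, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(D)
        assert len(list(tree.tips())) == n

    def test_small_and_asymmetric_inputs_rejected(self):
        with pytest.raises(PhyloError):
            neighbor_joining(np.zeros((2, 2)))
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], dtype=float)
        with pytest.raises(PhyloError):
            neighbor_joining(bad)

    @pytest.mark.parametrize("n_leaves,seed", [(4, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
    def test_additive_trees_recovered_against_ls_oracle(self, n_leaves, seed):
        rng = np.random.default_rng(seed)
        D, true_splits = random_additive_tree(n_leaves, rng)
        ids = [str(i) for i in range(n_leaves)]
        tree = neighbor_joining(D, ids=ids)
        assert tree_splits(tree, ids) == true_splits
        oracle_splits, residual, _ = least_squares_topology(D)
        assert residual == pytest.approx(0.0, abs=1e-8)
        assert oracle_splits == true_splits
        dists = _tip_distances(tree)
        for i in range(n_leaves):
            for j in range(i + 1, n_leaves):
                assert dists[frozenset((str(i), str(j)))] == pytest.approx(D[i, j])

    def test_matches_reference_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on a generic matrix."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        n = 8
        M = rng.uniform(0.2, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"t{i}" for i in range(n)]
        ours = tree_splits(neighbor_joining(D, ids=ids), ids)
        theirs = tree_splits(skbio_nj(DistanceMatrix(D, ids)), ids)
        assert ours == theirs


class TestBootstrap:
    def _two_groups(self, n_per_group=5, seed=11):
        rng = np.random.default_rng(seed)
        cons = gh57.build_group_consensus(seed=seed)
        fps, labels = [], {}
        for group in ("AAMY", "GBE"):
            for i in range(n_per_group):
                fp = list(cons[group])
                for pos in rng.choice(36, size=2, replace=False):
                    fp[pos] = str(rng.choice(list(gh57.AA_ALPHABET)))
                name = f"{group}{i}"
                fps.append("".join(fp))
                labels[name] = group
        ids = list(labels)
        return fps, ids, labels

    def test_well_separated_groups_get_high_support(self):
        fps, ids, labels = self._two_groups()
        tree = bootstrap_support(fps, ids, n_trials=100, seed=5)
        group_a = frozenset(i for i in ids if labels[i] == "AAMY")
        found = False
        for node in tree.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if clade in (group_a, frozenset(ids) - group_a):
                found = True
                assert node.support >= 0.95
        assert found

    def test_single_trial_supports_are_binary(self):
        fps, ids, _ = self._two_groups(seed=13)
        tree = bootstrap_support(fps, ids, n_trials=1, seed=3)
        supports = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert supports and all(s in (0.0, 1.0) for s in supports)

    def test_deterministic_in_seed(self):
        fps, ids, _ = self._two_groups(seed=17)
        t1 = bootstrap_support(fps, ids, n_trials=25, seed=9)
        t2 = bootstrap_support(fps, ids, n_trials=25, seed=9)
        assert str(t1) == str(t2)

    def test_invalid_trial_count_rejected(self):
        fps, ids, _ = self._two_groups()
        with pytest.raises(PhyloError):
            bootstrap_support(fps, ids, n_trials=0)


class TestMonophyly:
    def test_perfect_separation_scores_one(self):
        cfg = gh57.SyntheticConfig(
            seed=19, conservation=1.0, dropout_fraction=0.0,
            counts={"AAMY": 6, "GBE": 6, "AGAL": 4},
        )
        ds = gh57.generate_dataset(cfg)
        fps = [s.fingerprint for s in ds.sequences]
        ids = [s.id for s in ds.sequences]
        labels = {s.id: s.group for s in ds.sequences}
        tree = neighbor_joining(pdistance_matrix(fps, ids))
        scores = monophyly_fraction(tree, labels)
        assert scores == {"AAMY": 1.0, "GBE": 1.0, "AGAL": 1.0}

    def test_split_group_scores_below_one(self):
        # a group interleaved across two clades cannot be monophyletic
        D = np.array(
            [
                [0.0, 0.1, 0.8, 0.8],
                [0.1, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.1],
                [0.8, 0.8, 0.1, 0.0],
            ]
        )
        ids = ["a1", "b1", "a2", "b2"]
        tree = neighbor_joining(D, ids=ids)
        scores = monophyly_fraction(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert scores["A"] < 1.0 and scores["B"] < 1.0

    def test_singleton_group_always_one(self):
        fps = ["A" * 36, "C" * 36, "D" * 36, "E" * 36]
        ids = ["w", "x", "y", "z"]
        tree = neighbor_joining(pdistance_matrix(fps, ids))
        scores = monophyly_fraction(tree, {"w": "solo", "x": "rest", "y": "rest", "z": "rest"})
        assert scores["solo"] == 1.0

    def test_missing_labels_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        tree = neighbor_joining(D, ids=list("ABC"))
        with pytest.raises(PhyloError):
            monophyly_fraction(tree, {"A": "g"})
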