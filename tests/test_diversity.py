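import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from urobiome.diversity import (
    bray_curtis,
    compute_diversity,
    diversity_by_group,
    faith_pd,
    faith_pd_matrix,
    shannon,
    unweighted_unifrac,
)
from urobiome.io import CountMatrix, SampleMetadata, parse_tree

from oracles import faith_pd_naive, shannon_naive, unifrac_naive


def _random_tree(rng, n_leaves):
    from urobiome.simulate import _coalesce
    from skbio import TreeNode
    from urobiome.io import PhyloTree

    tips = [TreeNode(name=f"L{i}", length=float(rng.exponential(1.0))) for i in range(n_leaves)]
    return PhyloTree(_coalesce(tips, rng, 1.0))


class TestShannon:
    def test_single_taxon_is_zero(self):
        assert shannon([7]) == 0.0

    def test_uniform_four_taxa_is_two_bits(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(2.0)

    def test_matches_naive_formula(self):
        assert shannon([1, 2, 3, 4]) == pytest.approx(shannon_naive([1, 2, 3, 4]), abs=1e-12)

    def test_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(1, 50, size=6)
            assert shannon(counts) <= shannon([1] * 6) + 1e-12

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestFaithPD:
    def test_toy_tree_values(self, toy_tree):
        sample = pd.Series({"A": 1, "B": 0, "C": 0})
        assert faith_pd(sample, toy_tree) == pytest.approx(2.0)
        assert faith_pd(pd.Series({"A": 1, "B": 1, "C": 1}), toy_tree) == pytest.approx(5.0)

    def test_monotone_in_taxa(self, toy_tree):
        pd_a = faith_pd(pd.Series({"A": 1, "B": 0, "C": 0}), toy_tree)
        pd_ab = faith_pd(pd.Series({"A": 1, "B": 1, "C": 0}), toy_tree)
        assert pd_ab >= pd_a

    def test_missing_taxon_raises(self, toy_tree):
        with pytest.raises(ValueError, match="absent"):
            faith_pd(pd.Series({"Z": 1}), toy_tree)

    def test_matches_naive_on_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = _random_tree(rng, 8)
            present = set(rng.choice([t for t in tree.leaf_names], size=3, replace=False))
            sample = pd.Series({name: int(name in present) for name in tree.leaf_names})
            assert faith_pd(sample, tree) == pytest.approx(
                faith_pd_naive(tree.tree, present), abs=1e-10
            )


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        rel = pd.DataFrame([[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], [0, 0, 0.9, 0.1]])
        dm = bray_curtis(rel)
        assert dm.iloc[0, 1] == 0.0
        assert dm.iloc[0, 2] == 1.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.random((12, 5))
        dm = bray_curtis(pd.DataFrame(x))
        for i in range(12):
            for j in range(i + 1, 12):
                assert dm.iloc[i, j] == pytest.approx(scipy_braycurtis(x[i], x[j]), abs=1e-12)


class TestUniFrac:
    def test_identical_sets_zero(self, toy_tree):
        presence = pd.DataFrame([[1, 1, 0], [1, 1, 0]], columns=["A", "B", "C"], dtype=bool)
        assert unweighted_unifrac(presence, toy_tree).iloc[0, 1] == 0.0

    def test_star_tree_disjoint_is_one(self):
        tree = parse_tree("(A:1,B:1,C:1);")
        presence = pd.DataFrame([[1, 0, 0], [0, 1, 0]], columns=["A", "B", "C"], dtype=bool)
        assert unweighted_unifrac(presence, tree).iloc[0, 1] == pytest.approx(1.0)

    def test_empty_sample_raises(self, toy_tree):
        presence = pd.DataFrame([[1, 0, 0], [0, 0, 0]], columns=["A", "B", "C"], dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            unweighted_unifrac(presence, toy_tree)

    def test_matches_edge_enumeration_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree = _random_tree(rng, 8)
            names = tree.leaf_names
            pres = rng.random((2, 8)) < 0.5
            pres[:, 0] = True  # no empty samples
            frame = pd.DataFrame(pres, columns=names)
            mine = unweighted_unifrac(frame, tree).iloc[0, 1]
            naive = unifrac_naive(
                tree.tree,
                {n for n, v in zip(names, pres[0]) if v},
                {n for n, v in zip(names, pres[1]) if v},
            )
            assert mine == pytest.approx(naive, abs=1e-12)

    def test_metric_properties(self, desk_pipeline):
        dm = compute_diversity(
            desk_pipeline(1)["rarefied"].subset(
                samples=desk_pipeline(1)["rarefied"].sample_ids[:20]
            ),
            desk_pipeline(1)["tree"],
        ).beta["unweighted_unifrac"]
        x = dm.to_numpy()
        assert np.allclose(x, x.T)
        assert np.allclose(np.diag(x), 0)
        assert (x >= 0).all() and (x <= 1).all()


class TestGroupComparison:
    @staticmethod
    def _result_from(alpha_values, groups):
        from urobiome.diversity import DiversityResult

        alpha = pd.DataFrame({"shannon": alpha_values})
        meta = SampleMetadata(
            pd.DataFrame(
                {"gender": groups, "age": [50] * len(groups), "region": "x"},
                index=alpha.index,
            )
        )
        return DiversityResult(alpha=alpha, beta={}), meta

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]),
            index=[f"S{i}" for i in range(100)],
        )
        result, meta = self._result_from(values, ["female"] * 50 + ["male"] * 50)
        out = diversity_by_group(result, meta, "gender")
        assert out["shannon"]["wilcoxon"]["female_vs_male"]["p"] < 0.01

    def test_null_calibration(self):
        # two groups from one distribution: rejection rate at 0.05 stays
        # nominal; 2,000 reps keep the binomial SE small against the band
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            values = pd.Series(rng.normal(0, 1, 60), index=[f"S{i}" for i in range(60)])
            result, meta = self._result_from(values, ["female"] * 30 + ["male"] * 30)
            out = diversity_by_group(result, meta, "gender")
            rejections += out["shannon"]["wilcoxon"]["female_vs_male"]["p"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
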