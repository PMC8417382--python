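import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from urobiome.diversity import bray_curtis
from urobiome.profiling import TaxonProfile
from urobiome.urotyping import (
    build_urotype_matrix,
    label_urotypes,
    modality_classify,
    select_k,
    urotype_prevalence_compare,
    ward_cluster,
)

from oracles import (
    calinski_harabasz_naive,
    chi2_independence_naive,
    silhouette_naive,
    ward_d2_linkage_naive,
)


def _profile(rel, columns=None):
    rel = np.asarray(rel, dtype=float)
    columns = columns or [f"G{j}" for j in range(rel.shape[1])]
    frame = pd.DataFrame(rel, index=[f"S{i}" for i in range(rel.shape[0])], columns=columns)
    return TaxonProfile(rank="genus", rel_abund=frame)


class TestUrotypeMatrix:
    def test_cutoff_is_strict_and_rows_conserved(self):
        rel = np.array([[0.001, 0.899, 0.1], [0.001, 0.899, 0.1]])
        profile = _profile(rel, ["Rare", "Big", "Mid"])
        matrix = build_urotype_matrix(profile, mra_cutoff=0.001)
        assert "Rare" not in matrix.columns  # MRA exactly at cutoff pools into Others
        assert matrix["Others"].tolist() == pytest.approx([0.001, 0.001])
        assert matrix.sum(axis=1).tolist() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_no_genus_passing_raises(self):
        with pytest.raises(ValueError):
            build_urotype_matrix(_profile([[0.5, 0.5]]), mra_cutoff=0.9)


class TestWardCluster:
    def test_separable_groups_recovered(self):
        rng = np.random.default_rng(0)
        points = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(3, 0.05, (10, 2))])
        d = pd.DataFrame(squareform(pdist(points)))
        _, labels = ward_cluster(d, [2])
        first, second = labels[2][:10], labels[2][10:]
        assert len(set(first)) == 1 and len(set(second)) == 1 and first[0] != second[0]

    def test_merge_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(1)
        points = rng.random((6, 3))
        d = squareform(pdist(points))
        z, _ = ward_cluster(pd.DataFrame(d), [2, 3])
        naive = ward_d2_linkage_naive(d)
        assert np.allclose(sorted(z[:, 2]), sorted(h for h, _ in naive), atol=1e-10)

    def test_heights_non_decreasing(self, desk_pipeline):
        item = desk_pipeline(1)
        matrix = build_urotype_matrix(item["profile"])
        z, _ = ward_cluster(bray_curtis(matrix), [2])
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        points = np.vstack([rng.normal(c, 0.1, (8, 2)) for c in (0, 4, 9)])
        d = squareform(pdist(points))
        _, labels = ward_cluster(pd.DataFrame(d), [3])
        perm = rng.permutation(len(points))
        _, labels_p = ward_cluster(pd.DataFrame(d[np.ix_(perm, perm)]), [3])
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(np.asarray(labels[3])[perm], labels_p[3]) == 1.0

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(bad, [2])


class TestSelectK:
    def test_three_blobs_peak_at_three(self):
        rng = np.random.default_rng(3)
        points = np.vstack([rng.normal(c, 0.1, (15, 2)) for c in (0, 5, 11)])
        d = pd.DataFrame(squareform(pdist(points)))
        _, labels = ward_cluster(d, range(2, 7))
        k, diagnostics = select_k(d, labels, pd.DataFrame(points))
        assert k == 3
        assert diagnostics["calinski_harabasz"].idxmax() == 3

    def test_diagnostics_match_naive_oracles(self):
        rng = np.random.default_rng(4)
        points = rng.random((12, 3))
        d = squareform(pdist(points))
        _, labels = ward_cluster(pd.DataFrame(d), [2, 3, 4])
        _, diagnostics = select_k(pd.DataFrame(d), labels, pd.DataFrame(points))
        for k in (2, 3, 4):
            assert diagnostics.loc[k, "calinski_harabasz"] == pytest.approx(
                calinski_harabasz_naive(points, labels[k]), abs=1e-10
            )
            assert diagnostics.loc[k, "mean_silhouette"] == pytest.approx(
                silhouette_naive(d, labels[k]), abs=1e-10
            )

    def test_deterministic_recompute(self):
        rng = np.random.default_rng(5)
        points = rng.random((15, 3))
        d = pd.DataFrame(squareform(pdist(points)))
        _, labels = ward_cluster(d, [2, 3])
        k1, d1 = select_k(d, labels, pd.DataFrame(points))
        k2, d2 = select_k(d, labels, pd.DataFrame(points))
        assert k1 == k2 and d1.equals(d2)


class TestLabelUrotypes:
    def test_dominant_and_mixed(self):
        rel = np.array(
            [[0.6, 0.2, 0.2], [0.7, 0.2, 0.1], [0.12, 0.1, 0.78], [0.12, 0.08, 0.8]]
        )
        profile = _profile(rel, ["Prevotella", "Others2", "Lactobacillus"])
        labels = pd.Series([1, 1, 2, 2], index=profile.rel_abund.index)
        out = label_urotypes(labels, profile)
        assert out[1] == "Prevotella" and out[2] == "Lactobacillus"
        mixed = label_urotypes(labels, profile, dominance_threshold=0.9)
        assert mixed[1] == "mixed"


class TestModality:
    def test_single_lognormal_called_unimodal(self):
        rng = np.random.default_rng(6)
        hits = 0
        for i in range(40):
            x = rng.lognormal(-3, 1.0, size=500)
            hits += modality_classify(x, seed=i)["classification"] == "unimodal_lognormal"
        assert hits >= 38

    def test_separated_mixture_called_multimodal(self):
        rng = np.random.default_rng(7)
        hits = 0
        for i in range(40):
            comp = rng.random(500) < 0.5
            x = np.where(comp, rng.lognormal(-6, 1, 500), rng.lognormal(-2, 1, 500))
            hits += modality_classify(x, seed=i)["classification"] == "multimodal"
        assert hits >= 38

    def test_degenerate_input(self):
        assert modality_classify(np.full(100, 0.25))["classification"] == "insufficient_data"
        assert modality_classify([0.1] * 10)["classification"] == "insufficient_data"


class TestPrevalenceCompare:
    def test_textbook_table(self):
        labels = pd.Series(
            ["U1"] * 100 + ["U2"] * 100, index=[f"S{i}" for i in range(200)]
        )
        gender = pd.Series(
            ["f"] * 55 + ["m"] * 45 + ["f"] * 34 + ["m"] * 66, index=labels.index
        )
        meta = pd.DataFrame({"gender": gender})
        out = urotype_prevalence_compare(labels, meta, "gender")
        expected = chi2_independence_naive([[55, 45], [34, 66]])[1]
        assert out["p"] == pytest.approx(expected, abs=1e-9)

    def test_exclusive_urotype_significant(self):
        labels = pd.Series(["U1"] * 60 + ["U2"] * 60, index=[f"S{i}" for i in range(120)])
        gender = pd.Series(["f"] * 60 + ["m"] * 60, index=labels.index)
        out = urotype_prevalence_compare(labels, pd.DataFrame({"gender": gender}), "gender")
        assert out["p"] < 0.01

    def test_single_group_rejected(self):
        labels = pd.Series(["U1", "U2"], index=["S0", "S1"])
        meta = pd.DataFrame({"gender": pd.Series(["f", "f"], index=labels.index)})
        with pytest.raises(ValueError):
            urotype_prevalence_compare(labels, meta, "gender")
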