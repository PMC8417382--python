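"""Urotype discovery: hierarchical clustering of genus profiles.

Samples are stratified into "urotypes" (community state types of the
genitourinary microbiome, analogous to gut enterotypes) by agglomerative
clustering of Bray-Curtis dissimilarities with the Ward.D2 criterion.
The cluster number is selected by mean silhouette width, with the
Calinski-Harabasz index reported alongside; each cluster is labelled by
its dominant genus, and per-genus abundance distributions are classified
as unimodal log-normal versus bi-/multimodal with a two-component
Gaussian mixture on log abundances.

Ward's criterion formally assumes Euclidean input; applying it to
Bray-Curtis dissimilarities is a deliberate, field-standard choice for
enterotype-style analyses and is documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .profiling import TaxonProfile

logger = logging.getLogger(__name__)


@dataclass
class UrotypeResult:
    """Cluster labels, k-selection diagnostics, dominant-genus labels."""

    labels: pd.Series  # per-sample cluster id (1..k)
    k: int
    linkage_tree: np.ndarray  # scipy linkage matrix (merge history + heights)
    diagnostics: pd.DataFrame  # per k: calinski_harabasz, mean_silhouette
    dominant_genus: dict = field(default_factory=dict)  # cluster id -> genus | "mixed"
    modality: dict = field(default_factory=dict)  # genus -> classification dict


def build_urotype_matrix(profile: TaxonProfile, mra_cutoff: float = 0.001) -> pd.DataFrame:
    """Keep genera with MRA strictly above ``mra_cutoff`` (default 0.1%)
    as columns; pool all remaining genera into an ``Others`` column so
    rows still sum to 1."""
    mra = profile.mra
    keep = list(mra.index[mra > mra_cutoff])
    if not keep:
        raise ValueError(f"no genus has MRA > {mra_cutoff}")
    rest = [g for g in mra.index if g not in keep]
    out = profile.rel_abund[keep].copy()
    out["Others"] = profile.rel_abund[rest].sum(axis=1) if rest else 0.0
    return out


def ward_cluster(distance_matrix: pd.DataFrame, k_range) -> tuple[np.ndarray, dict]:
    """Agglomerative clustering with the Ward.D2 criterion on a
    dissimilarity matrix (squared-dissimilarity Lance-Williams update,
    heights on the original scale — the behaviour of R's ``hclust``
    ``ward.D2``).  Returns the linkage matrix and flat labels per k."""
    d = distance_matrix.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    k_range = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError("k_range must lie within [2, n-1]")
    z = linkage(squareform(d, checks=False), method="ward")
    labels = {k: fcluster(z, t=k, criterion="maxclust") for k in k_range}
    return z, labels


def select_k(
    distance_matrix: pd.DataFrame, labels_per_k: dict, feature_matrix: pd.DataFrame
) -> tuple[int, pd.DataFrame]:
    """Score each candidate k by mean silhouette width (on the
    dissimilarities) and the Calinski-Harabasz index (on the feature
    matrix); return the k maximizing mean silhouette (CH reported, ties
    broken toward smaller k)."""
    if len(labels_per_k) < 2:
        raise ValueError("need at least 2 candidate k values")
    d = distance_matrix.to_numpy(dtype=float)
    x = feature_matrix.to_numpy(dtype=float)
    rows = []
    for k in sorted(labels_per_k):
        labels = np.asarray(labels_per_k[k])
        if len(np.unique(labels)) < 2:
            raise ValueError(f"labels for k={k} are degenerate")
        sil = float(silhouette_score(d, labels, metric="precomputed"))
        ch = float(calinski_harabasz_score(x, labels))
        rows.append({"k": k, "mean_silhouette": sil, "calinski_harabasz": ch})
    diagnostics = pd.DataFrame(rows).set_index("k")
    best = int(diagnostics["mean_silhouette"].idxmax())
    return best, diagnostics


def label_urotypes(
    labels: pd.Series, profile: TaxonProfile, dominance_threshold: float = 0.25
) -> dict:
    """Per cluster, the genus with the highest within-cluster MRA, or
    ``"mixed"`` when the top genus stays below ``dominance_threshold``."""
    out = {}
    rel = profile.rel_abund
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        cluster_mra = rel.loc[members].mean(axis=0)
        cluster_mra = cluster_mra.drop("Others", errors="ignore")
        top = cluster_mra.idxmax()
        out[int(cluster)] = top if cluster_mra[top] >= dominance_threshold else "mixed"
    return out


def modality_classify(
    genus_abundances,
    min_positive: int = 50,
    bic_margin: float = 10.0,
    min_separation_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Classify a genus abundance distribution as ``unimodal_lognormal``
    or ``multimodal``.

    Zeros are excluded; with fewer than ``min_positive`` positive
    observations the outcome is ``insufficient_data``.  One- and
    two-component Gaussian mixtures are fitted on log abundances; the
    distribution is called multimodal when the two-component fit wins by
    more than ``bic_margin`` BIC *and* the component means are separated
    by more than ``min_separation_sd`` pooled standard deviations.
    """
    x = np.asarray(genus_abundances, dtype=float)
    x = x[x > 0]
    result = {"n_positive": int(x.size)}
    if x.size < min_positive or np.ptp(x) == 0:
        result["classification"] = "insufficient_data"
        return result
    logx = np.log(x).reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(logx)
    gm2 = GaussianMixture(2, n_init=3, random_state=seed).fit(logx)
    bic1, bic2 = gm1.bic(logx), gm2.bic(logx)
    means = gm2.means_.ravel()
    variances = gm2.covariances_.ravel()
    weights = gm2.weights_.ravel()
    pooled_sd = float(np.sqrt(np.sum(weights * variances)))
    separation = float(abs(means[0] - means[1]) / pooled_sd) if pooled_sd > 0 else np.inf
    multimodal = (bic1 - bic2 > bic_margin) and (separation > min_separation_sd)
    result.update(
        {
            "classification": "multimodal" if multimodal else "unimodal_lognormal",
            "bic_1": float(bic1),
            "bic_2": float(bic2),
            "delta_bic": float(bic1 - bic2),
            "separation_sd": separation,
            "component_means": [float(m) for m in means],
            "component_weights": [float(w) for w in weights],
        }
    )
    return result


def urotype_prevalence_compare(
    labels: pd.Series, metadata, grouping: str
) -> dict:
    """Urotype x group contingency table with a chi-square test (Fisher
    when a 2x2 table has an expected cell < 5) and per-group urotype
    prevalence fractions."""
    from scipy import stats

    groups = metadata[grouping].reindex(labels.index)
    table = pd.crosstab(labels, groups)
    if table.shape[1] < 2:
        raise ValueError("prevalence comparison needs at least two groups")
    observed = table.to_numpy()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
    if observed.shape == (2, 2) and expected.min() < 5:
        p = float(stats.fisher_exact(observed)[1])
        test = "fisher"
    else:
        p = float(stats.chi2_contingency(observed, correction=False)[1])
        test = "chi_square"
    prevalence = (table / table.sum(axis=0)).to_dict()
    return {"table": table, "p": p, "test": test, "prevalence": prevalence}


def discover_urotypes(
    profile: TaxonProfile,
    k_range=range(2, 11),
    mra_cutoff: float = 0.001,
    dominance_threshold: float = 0.25,
    classify_modality: bool = True,
    seed: int = 0,
) -> UrotypeResult:
    """End-to-end urotype discovery from a genus-rank profile."""
    from .diversity import bray_curtis

    matrix = build_urotype_matrix(profile, mra_cutoff)
    dm = bray_curtis(matrix)
    z, labels_per_k = ward_cluster(dm, k_range)
    k, diagnostics = select_k(dm, labels_per_k, matrix)
    labels = pd.Series(labels_per_k[k], index=matrix.index, name="urotype")
    dominant = label_urotypes(labels, profile, dominance_threshold)
    modality = {}
    if classify_modality:
        for cluster, genus in dominant.items():
            if genus != "mixed" and genus in profile.rel_abund.columns:
                modality[genus] = modality_classify(profile.rel_abund[genus], seed=seed)
    return UrotypeResult(
        labels=labels,
        k=k,
        linkage_tree=z,
        diagnostics=diagnostics,
        dominant_genus=dominant,
        modality=modality,
    )
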