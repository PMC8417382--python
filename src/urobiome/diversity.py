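"""Alpha and beta diversity from first principles.

Implements the four indices used throughout the pipeline — Shannon's
index (log base 2 by convention of the QIIME2 diversity plugin; the base
is configurable), Faith's phylogenetic diversity, Bray-Curtis
dissimilarity, and unweighted UniFrac — directly on count/presence
profiles and a rooted ASV tree, plus gender/age-group comparisons of the
resulting values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, PhyloTree, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class DiversityResult:
    """Per-sample alpha values and sample x sample beta distance matrices."""

    alpha: pd.DataFrame  # columns: shannon (bits), faith_pd (branch-length units)
    beta: dict  # name -> symmetric DataFrame with zero diagonal


# ---------------------------------------------------------------------------
# alpha


def shannon(sample_counts, base: float = 2.0) -> float:
    """H = -sum p_i log_base p_i over taxa with p_i > 0."""
    x = np.asarray(sample_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample has no Shannon diversity")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _tree_arrays(tree: PhyloTree):
    """Post-order edge table: (lengths, leaf-index lists per node)."""
    leaves = tree.leaf_names
    leaf_pos = {name: i for i, name in enumerate(leaves)}
    nodes = list(tree.tree.postorder(include_self=False))
    lengths = np.array([n.length or 0.0 for n in nodes])
    masks = np.zeros((len(nodes), len(leaves)), dtype=bool)
    node_index = {id(n): i for i, n in enumerate(nodes)}
    for i, n in enumerate(nodes):
        if n.is_tip():
            masks[i, leaf_pos[n.name]] = True
        else:
            for child in n.children:
                masks[i] |= masks[node_index[id(child)]]
    return leaves, lengths, masks


def faith_pd(sample_counts: pd.Series, tree: PhyloTree) -> float:
    """Total branch length of the minimal rooted subtree spanning the
    sample's taxa (the union of root-to-leaf paths)."""
    observed = set(sample_counts[np.asarray(sample_counts) > 0].index)
    leaves = set(tree.leaf_names)
    missing = observed - leaves
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]}")
    if not observed:
        raise ValueError("empty sample")
    leaf_list, lengths, masks = _tree_arrays(tree)
    present = np.array([name in observed for name in leaf_list])
    on_path = masks[:, present].any(axis=1)
    return float(lengths[on_path].sum())


def faith_pd_matrix(cm: CountMatrix, tree: PhyloTree) -> pd.Series:
    """Vectorized Faith's PD for every sample of a count matrix."""
    leaf_list, lengths, masks = _tree_arrays(tree)
    counts = cm.counts.reindex(columns=leaf_list, fill_value=0)
    extra = set(cm.asv_ids) - set(leaf_list)
    if extra:
        raise ValueError(f"taxa absent from tree: {sorted(extra)[:5]}")
    presence = counts.to_numpy() > 0  # samples x leaves
    on_path = presence @ masks.T > 0  # samples x edges
    return pd.Series(on_path @ lengths, index=cm.sample_ids, name="faith_pd")


# ---------------------------------------------------------------------------
# beta


def bray_curtis(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """d(x, y) = sum |x_i - y_i| / sum (x_i + y_i), pairwise."""
    x = rel_abund.to_numpy(dtype=float)
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        tot = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1), 0.0)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return pd.DataFrame(out, index=rel_abund.index, columns=rel_abund.index)


def unweighted_unifrac(presence: pd.DataFrame, tree: PhyloTree) -> pd.DataFrame:
    """Unweighted UniFrac over all sample pairs by post-order edge
    classification: d = (branch length unique to one sample) / (branch
    length observed in either)."""
    if (presence.sum(axis=1) == 0).any():
        raise ValueError("empty sample in presence table")
    leaf_list, lengths, masks = _tree_arrays(tree)
    extra = set(presence.columns) - set(leaf_list)
    if extra:
        raise ValueError(f"taxa absent from tree: {sorted(extra)[:5]}")
    aligned = presence.reindex(columns=leaf_list, fill_value=False).to_numpy(dtype=bool)
    observed = (aligned @ masks.T) > 0  # samples x edges
    weighted = observed * lengths  # samples x edges
    a = weighted.sum(axis=1)  # observed branch length per sample
    shared = weighted @ observed.T  # pairwise shared branch length
    union = a[:, None] + a[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, 1.0 - shared / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=presence.index, columns=presence.index)


def compute_diversity(
    cm: CountMatrix, tree: PhyloTree, base: float = 2.0
) -> DiversityResult:
    """All four indices for one (typically rarefied) count matrix."""
    counts = cm.counts
    alpha = pd.DataFrame(
        {
            "shannon": [shannon(row, base=base) for row in counts.to_numpy()],
            "faith_pd": faith_pd_matrix(cm, tree),
        },
        index=cm.sample_ids,
    )
    libs = counts.sum(axis=1).to_numpy(dtype=float)[:, None]
    rel = pd.DataFrame(
        counts.to_numpy() / np.maximum(libs, 1), index=cm.sample_ids, columns=cm.asv_ids
    )
    beta = {
        "bray_curtis": bray_curtis(rel),
        "unweighted_unifrac": unweighted_unifrac(counts > 0, tree),
    }
    return DiversityResult(alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# group comparisons


def diversity_by_group(
    result: DiversityResult, metadata: SampleMetadata, grouping: str
) -> dict:
    """Per-group alpha summaries with pairwise Wilcoxon rank-sum tests,
    and pairwise comparisons of within-group beta-distance distributions.

    The beta comparison tests the within-group pairwise distances of one
    group against those of another by Wilcoxon rank-sum; pairwise
    distances are not independent observations, so those p-values are
    descriptive (logged once per call).
    """
    groups = metadata[grouping].reindex(result.alpha.index).dropna()
    sizes = groups.value_counts()
    usable = [g for g in sizes.index if sizes[g] >= 2]
    skipped = [g for g in sizes.index if sizes[g] < 2]
    if skipped:
        logger.warning("groups with <2 samples excluded: %s", skipped)
    summary = {}
    for metric in result.alpha.columns:
        by = {
            g: result.alpha.loc[groups[groups == g].index, metric] for g in usable
        }
        rows = {
            g: {"n": len(v), "mean": float(v.mean()), "median": float(v.median())}
            for g, v in by.items()
        }
        tests = {}
        for i, g1 in enumerate(usable):
            for g2 in usable[i + 1 :]:
                stat, p = stats.mannwhitneyu(by[g1], by[g2], alternative="two-sided")
                tests[f"{g1}_vs_{g2}"] = {"statistic": float(stat), "p": float(p)}
        summary[metric] = {"groups": rows, "wilcoxon": tests}
    logger.info("beta-distance group tests treat pairwise distances as observations "
                "(non-independent); interpret descriptively")
    for name, dm in result.beta.items():
        within = {}
        for g in usable:
            ids = [s for s in groups[groups == g].index if s in dm.index]
            sub = dm.loc[ids, ids].to_numpy()
            within[g] = sub[np.triu_indices(len(ids), k=1)]
        tests = {}
        for i, g1 in enumerate(usable):
            for g2 in usable[i + 1 :]:
                if len(within[g1]) and len(within[g2]):
                    stat, p = stats.mannwhitneyu(
                        within[g1], within[g2], alternative="two-sided"
                    )
                    tests[f"{g1}_vs_{g2}"] = {"statistic": float(stat), "p": float(p)}
        summary[name] = {
            "groups": {g: {"n_pairs": len(v), "mean": float(v.mean()) if len(v) else np.nan}
                       for g, v in within.items()},
            "wilcoxon": tests,
        }
    return summary
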