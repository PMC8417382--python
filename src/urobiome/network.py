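"""Genus co-occurrence networks, keystone taxa, and trio analysis.

Edges connect genus pairs whose Spearman correlation over samples passes
both an effect-size threshold (|rho| > 0.35) and a Benjamini-Hochberg
false-discovery threshold (q < 0.05), computed in one family over all
genus pairs.  Keystone genera are the most connected nodes (degree,
ties broken by summed |rho|).  The trio analysis quantifies the joint
presence, mutual co-abundance, and alpha-diversity association of a
designated three-genus group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .profiling import TaxonProfile

logger = logging.getLogger(__name__)


@dataclass
class CoocNetwork:
    """Genus-genus co-occurrence network with thresholds and keystones."""

    graph: nx.Graph  # nodes carry mra; edges carry rho, q
    edges: pd.DataFrame  # genus_a, genus_b, rho, p, q (retained edges only)
    all_pairs: pd.DataFrame  # every tested pair, for audit
    thresholds: tuple  # (rho_min, q_max)

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree), dtype=int)


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_network(
    profile: TaxonProfile, rho_min: float = 0.35, q_max: float = 0.05
) -> CoocNetwork:
    """All-pairs Spearman correlations (midrank ties, large-sample t
    approximation for p), BH adjustment across the full pair family, and
    edge retention by both thresholds.  Pairs involving a constant genus
    have undefined rho and are skipped with a log message."""
    rel = profile.rel_abund
    n_samples, n_genera = rel.shape
    if n_samples < 3 or n_genera < 2:
        raise ValueError("need >= 3 samples and >= 2 genera")
    x = rel.to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        logger.info("skipping %d constant genera", int(constant.sum()))
    # midranks + Pearson on ranks; p by the large-sample t approximation
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_matrix = np.corrcoef(ranks, rowvar=False)
        t_stat = rho_matrix * np.sqrt(
            (n_samples - 2) / np.clip(1.0 - rho_matrix**2, 1e-300, None)
        )
        p_matrix = 2.0 * stats.t.sf(np.abs(t_stat), df=n_samples - 2)
    genera = list(rel.columns)
    rows = []
    for i, j in itertools.combinations(range(n_genera), 2):
        if constant[i] or constant[j]:
            continue
        rows.append(
            {
                "genus_a": genera[i],
                "genus_b": genera[j],
                "rho": float(rho_matrix[i, j]),
                "p": float(p_matrix[i, j]),
            }
        )
    all_pairs = pd.DataFrame(rows, columns=["genus_a", "genus_b", "rho", "p"])
    if len(all_pairs):
        all_pairs["q"] = bh_adjust(all_pairs["p"].to_numpy())
    else:
        all_pairs["q"] = []
    kept = all_pairs[(all_pairs["rho"].abs() > rho_min) & (all_pairs["q"] < q_max)]
    graph = nx.Graph()
    mra = profile.mra
    for g in genera:
        graph.add_node(g, mra=float(mra[g]))
    for row in kept.itertuples():
        graph.add_edge(row.genus_a, row.genus_b, rho=row.rho, q=row.q)
    return CoocNetwork(
        graph=graph,
        edges=kept.reset_index(drop=True),
        all_pairs=all_pairs,
        thresholds=(rho_min, q_max),
    )


def detect_keystones(network: CoocNetwork, top_n: int = 10) -> pd.DataFrame:
    """Genera ranked by degree, ties broken by summed |rho| of incident
    edges; empty networks return an empty frame with a warning."""
    if network.graph.number_of_edges() == 0:
        logger.warning("network has no edges; no keystones")
        return pd.DataFrame(columns=["genus", "degree", "strength"])
    rows = []
    for node in network.graph.nodes:
        incident = network.graph.edges(node, data=True)
        strength = sum(abs(d["rho"]) for _, _, d in incident)
        rows.append({"genus": node, "degree": network.graph.degree(node), "strength": strength})
    ranked = (
        pd.DataFrame(rows)
        .sort_values(["degree", "strength"], ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return ranked.head(top_n)


def trio_analysis(profile: TaxonProfile, trio_genera, alpha_values: pd.Series) -> dict:
    """Joint-presence, mutual co-abundance, and diversity association of
    a three-genus group.

    Co-occurrence is tested by chi-square independence on the 2x2 table
    of (first genus present) x (both other genera present) — a correctly
    calibrated contingency test of the triple pattern.  Pairwise Spearman
    correlations quantify co-abundance; the Pearson correlation of the
    summed trio abundance with per-sample Shannon values quantifies the
    diversity association.
    """
    trio = list(trio_genera)
    missing = [g for g in trio if g not in profile.rel_abund.columns]
    if missing:
        raise ValueError(f"trio genera absent from profile: {missing}")
    rel = profile.rel_abund[trio]
    present = rel > 0
    joint = present.all(axis=1)
    a = present[trio[0]].to_numpy()
    bc = (present[trio[1]] & present[trio[2]]).to_numpy()
    table = np.array(
        [
            [int((a & bc).sum()), int((a & ~bc).sum())],
            [int((~a & bc).sum()), int((~a & ~bc).sum())],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        cooc_p = 1.0
    else:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if expected.min() < 5:
            cooc_p = float(stats.fisher_exact(table)[1])
        else:
            cooc_p = float(stats.chi2_contingency(table, correction=False)[1])
    pairwise = {}
    for g1, g2 in itertools.combinations(trio, 2):
        rho, p = stats.spearmanr(rel[g1], rel[g2])
        pairwise[f"{g1}~{g2}"] = {"rho": float(rho), "p": float(p)}
    aligned_alpha = alpha_values.reindex(rel.index)
    trio_sum = rel.sum(axis=1)
    r, rp = stats.pearsonr(trio_sum, aligned_alpha)
    return {
        "joint_presence_count": int(joint.sum()),
        "n_samples": int(len(rel)),
        "cooccurrence_p": cooc_p,
        "pairwise_rhos": pairwise,
        "shannon_assoc": {"r": float(r), "p": float(rp)},
    }
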