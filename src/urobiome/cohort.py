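"""Gender/age-group comparisons of taxa: the cohort-statistics surface.

Abundances are compared between groups by Wilcoxon rank-sum tests,
prevalences by chi-square (Fisher's exact for sparse tables).  Raw
p-values are the primary output, mirroring the published presentation;
a Benjamini-Hochberg-adjusted column is always emitted alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata
from .network import bh_adjust
from .profiling import TaxonProfile

logger = logging.getLogger(__name__)

AGE_BINS = ((45, 54, "T1"), (55, 64, "T2"), (65, 74, "T3"), (75, None, "T4"))


def assign_age_groups(metadata: SampleMetadata) -> pd.Series:
    """Bin ages into the four stages T1 (45-54), T2 (55-64), T3 (65-74),
    T4 (>= 75); ages below 45 are labelled ``out_of_range`` with a
    warning, missing ages are excluded."""
    ages = metadata["age"]
    missing = ages.isna()
    if missing.any():
        logger.warning("%d samples without age excluded", int(missing.sum()))
    ages = ages[~missing]
    labels = pd.Series("out_of_range", index=ages.index, dtype="object")
    for lo, hi, name in AGE_BINS:
        mask = (ages >= lo) if hi is None else ((ages >= lo) & (ages <= hi))
        labels[mask] = name
    n_low = int((labels == "out_of_range").sum())
    if n_low:
        logger.warning("%d samples below the first age bin labelled out_of_range", n_low)
    return labels.rename("age_group")


def _group_vectors(profile: TaxonProfile, groups: pd.Series):
    groups = groups.reindex(profile.rel_abund.index).dropna()
    sizes = groups.value_counts()
    usable = sorted(g for g in sizes.index if sizes[g] >= 2)
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    return groups, usable


def compare_abundance(
    profile: TaxonProfile,
    metadata,
    grouping: str | pd.Series,
    level: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon Wilcoxon rank-sum tests of relative abundance between
    groups (all pairs when more than two), with per-group MRAs, raw p,
    BH-adjusted q, and a significance call at ``level``."""
    groups = metadata[grouping] if isinstance(grouping, str) else grouping
    groups, usable = _group_vectors(profile, groups)
    rel = profile.rel_abund.loc[groups.index]
    rows = []
    for g1, g2 in itertools.combinations(usable, 2):
        x1 = rel.loc[groups == g1]
        x2 = rel.loc[groups == g2]
        for taxon in rel.columns:
            a, b = x1[taxon].to_numpy(), x2[taxon].to_numpy()
            if np.ptp(np.concatenate([a, b])) == 0:
                logger.debug("taxon %s constant across %s vs %s; skipped", taxon, g1, g2)
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "taxon": taxon,
                    "group_a": g1,
                    "group_b": g2,
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                    "test": "wilcoxon",
                    "statistic": float(stat),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p"] < level
    return out


def compare_prevalence(
    profile: TaxonProfile,
    metadata,
    grouping: str | pd.Series,
    level: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon presence/absence chi-square tests between groups
    (Fisher's exact when a 2x2 expected cell is below 5); taxa absent
    everywhere are skipped."""
    groups = metadata[grouping] if isinstance(grouping, str) else grouping
    groups, usable = _group_vectors(profile, groups)
    present = (profile.rel_abund.loc[groups.index] > 0)
    rows = []
    for g1, g2 in itertools.combinations(usable, 2):
        m1, m2 = groups == g1, groups == g2
        n1, n2 = int(m1.sum()), int(m2.sum())
        for taxon in present.columns:
            k1 = int(present.loc[m1, taxon].sum())
            k2 = int(present.loc[m2, taxon].sum())
            if k1 + k2 == 0:
                continue
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if table.sum(axis=0).min() == 0:
                p, test = 1.0, "chi_square"
            else:
                expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
                if expected.min() < 5:
                    p, test = float(stats.fisher_exact(table)[1]), "fisher"
                else:
                    p, test = float(stats.chi2_contingency(table, correction=False)[1]), "chi_square"
            rows.append(
                {
                    "taxon": taxon,
                    "group_a": g1,
                    "group_b": g2,
                    "prevalence_a": k1 / n1,
                    "prevalence_b": k2 / n2,
                    "test": test,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p"] < level
    return out


def exclusive_taxa(
    profile: TaxonProfile, metadata, grouping: str | pd.Series, min_samples: int = 5
) -> dict[str, list[str]]:
    """Taxa present in at least ``min_samples`` samples of one group and
    in zero samples of every other group."""
    groups = metadata[grouping] if isinstance(grouping, str) else grouping
    groups = groups.reindex(profile.rel_abund.index).dropna()
    present = profile.rel_abund.loc[groups.index] > 0
    counts = present.groupby(groups).sum()
    out: dict[str, list[str]] = {}
    for g in counts.index:
        others = counts.drop(index=g)
        mask = (counts.loc[g] >= min_samples) & (others.sum(axis=0) == 0)
        out[g] = sorted(counts.columns[mask])
    return out
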