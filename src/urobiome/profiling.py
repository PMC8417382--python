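"""Rarefaction, taxonomic collapsing, and core-microbiota stratification.

Relative abundances are computed on rarefied tables (fixed 4,000-read
subsamples by default) so that mean relative abundance (MRA) and
prevalence are comparable across libraries of very different size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, TaxonomyTable, RANKS

logger = logging.getLogger(__name__)


@dataclass
class TaxonProfile:
    """Relative-abundance table at a chosen rank with MRA/prevalence."""

    rank: str
    rel_abund: pd.DataFrame  # samples x taxa, rows sum to 1 (or 0)
    rarefaction_depth: int | None = None

    @property
    def mra(self) -> pd.Series:
        """Mean relative abundance per taxon, zeros included."""
        return self.rel_abund.mean(axis=0)

    @property
    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon is present."""
        return (self.rel_abund > 0).mean(axis=0)

    @property
    def taxa(self) -> list[str]:
        return list(self.rel_abund.columns)


def rarefy(cm: CountMatrix, depth: int = 4000, seed: int = 0) -> CountMatrix:
    """Subsample every library to exactly ``depth`` reads without
    replacement (multivariate hypergeometric); samples below ``depth``
    are dropped with a warning."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    libs = cm.library_sizes
    keep = libs[libs >= depth].index
    if len(keep) == 0:
        raise ValueError(f"no sample has >= {depth} reads")
    dropped = len(libs) - len(keep)
    if dropped:
        logger.warning("rarefaction dropped %d samples below %d reads", dropped, depth)
    rng = np.random.default_rng(seed)
    sub = cm.counts.loc[keep]
    out = np.empty_like(sub.to_numpy())
    for i, row in enumerate(sub.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    frame = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    return CountMatrix(frame, cm.sample_type.reindex(keep))


def collapse_taxonomy(cm: CountMatrix, tax: TaxonomyTable, rank: str) -> CountMatrix:
    """Sum counts over ASVs sharing a rank label; unassigned ASVs pool
    into an ``unassigned`` taxon.  Total reads are conserved exactly."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    tax.check_covers(cm)
    labels = tax.rank(rank).reindex(cm.asv_ids)
    labels = labels.where(labels != "", "unassigned")
    collapsed = cm.counts.T.groupby(labels).sum().T
    return CountMatrix(collapsed, cm.sample_type)


def relative_abundance(
    cm: CountMatrix, rank: str = "asv", rarefaction_depth: int | None = None
) -> TaxonProfile:
    """Row-normalize a count table into a :class:`TaxonProfile`."""
    counts = cm.counts.to_numpy(dtype=float)
    libs = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(libs > 0, counts / np.where(libs > 0, libs, 1), 0.0)
    frame = pd.DataFrame(rel, index=cm.sample_ids, columns=cm.asv_ids)
    return TaxonProfile(rank=rank, rel_abund=frame, rarefaction_depth=rarefaction_depth)


DEFAULT_BOUNDARIES = (0.0001, 0.05)
DEFAULT_STRATUM_NAMES = ("below_core", "low_abundance", "dominant")


def core_taxa(
    profile: TaxonProfile,
    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES,
    names: tuple[str, ...] = DEFAULT_STRATUM_NAMES,
) -> dict[str, list[str]]:
    """Partition taxa into MRA strata (every taxon in exactly one).

    Default boundaries follow the published core-microbiota definition:
    dominant (MRA strictly > 5%), low-abundance ([0.01%, 5%]), and
    below-core (< 0.01%).  ``boundaries`` are ascending cut points; the
    top stratum is strictly above the last boundary, every other stratum
    is the closed-open interval ``[b_i, b_{i+1})`` (closed at its lower
    boundary, the top boundary itself falling in the stratum below).
    """
    if profile.rel_abund.empty:
        raise ValueError("empty profile")
    if list(boundaries) != sorted(boundaries):
        raise ValueError("boundaries must be ascending")
    if len(names) != len(boundaries) + 1:
        raise ValueError("need one stratum name per interval")
    mra = profile.mra
    out: dict[str, list[str]] = {name: [] for name in names}
    top = boundaries[-1]
    for taxon, value in mra.items():
        if value > top:
            out[names[-1]].append(taxon)
            continue
        k = int(np.searchsorted(np.asarray(boundaries), value, side="right"))
        out[names[min(k, len(names) - 2)]].append(taxon)
    return out
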