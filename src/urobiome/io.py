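"""Readers, writers and validated in-memory containers.

The pipeline's universal currency is the :class:`CountMatrix` — an integer
read-count table over amplicon sequence variants (ASVs) with a per-sample
type label distinguishing genitourinary specimens (``GU``) from negative
(``NC``) and positive (``PC``) sequencing controls.  Everything is plain
tab-delimited UTF-8 text; trees are newick.  In memory, samples are rows;
on disk, tables are written ASVs-as-rows (the common amplicon convention)
and the orientation is auto-detected on read via an explicit flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("GU", "NC", "PC")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """An input violated a container invariant."""


# ---------------------------------------------------------------------------
# CountMatrix


class CountMatrix:
    """Samples x ASVs integer read counts with per-sample type labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are ASVs, cells are non-negative integer
        read counts.
    sample_type : mapping or pandas.Series
        Per-sample label in ``{"GU", "NC", "PC"}`` (case-insensitive).
    """

    def __init__(self, counts: pd.DataFrame, sample_type) -> None:
        if counts.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate ASV ids")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be >= 0")
        st = pd.Series(sample_type, dtype="object")
        st = st.str.upper()
        missing = [s for s in counts.index if s not in st.index]
        if missing:
            raise ValidationError(f"samples without a type label: {missing[:5]}")
        st = st.reindex(counts.index)
        bad = sorted(set(st) - set(SAMPLE_TYPES))
        if bad:
            raise ValidationError(f"unknown sample types: {bad}")
        self.counts = counts.astype(np.int64)
        self.sample_type = st

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def type_mask(self, sample_type: str) -> pd.Series:
        return self.sample_type == sample_type.upper()

    def subset(self, samples=None, asvs=None) -> "CountMatrix":
        c = self.counts
        if samples is not None:
            c = c.loc[list(samples)]
        if asvs is not None:
            c = c[list(asvs)]
        return CountMatrix(c, self.sample_type.reindex(c.index))

    def gu(self) -> "CountMatrix":
        return self.subset(samples=self.counts.index[self.type_mask("GU")])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.sample_type.equals(other.sample_type)
        )

    def __repr__(self) -> str:
        n_gu = int(self.type_mask("GU").sum())
        n_nc = int(self.type_mask("NC").sum())
        return (
            f"<CountMatrix {self.counts.shape[0]} samples "
            f"({n_gu} GU, {n_nc} NC) x {self.counts.shape[1]} ASVs>"
        )


def read_count_table(
    path, sample_type_map: Mapping[str, str] | pd.Series, orientation: str = "asvs_as_rows"
) -> CountMatrix:
    """Read a TSV count table into a validated :class:`CountMatrix`.

    ``orientation`` declares the file layout: ``"asvs_as_rows"`` (default,
    the on-disk convention) or ``"samples_as_rows"``.
    """
    if orientation not in ("asvs_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "asvs_as_rows":
        df = df.T
    return CountMatrix(df, sample_type_map)


def write_count_table(cm: CountMatrix, path) -> None:
    """Write ASVs-as-rows TSV (transpose of the in-memory layout)."""
    cm.counts.T.to_csv(path, sep="\t", index_label="asv_id")


def read_sample_types(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].str.upper()


def write_sample_types(sample_type: pd.Series, path) -> None:
    sample_type.rename("sample_type").to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# TaxonomyTable


class TaxonomyTable:
    """ASV -> lineage (kingdom..genus); empty string marks an unassigned rank."""

    def __init__(self, lineages: pd.DataFrame) -> None:
        missing = [r for r in RANKS if r not in lineages.columns]
        if missing:
            raise ValidationError(f"taxonomy missing ranks: {missing}")
        if lineages.index.has_duplicates:
            raise ValidationError("duplicate ASV ids in taxonomy")
        self.lineages = lineages[list(RANKS)].fillna("").astype(str)

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineages[rank]

    def check_covers(self, cm: CountMatrix) -> None:
        missing = [a for a in cm.asv_ids if a not in self.lineages.index]
        if missing:
            raise ValidationError(f"ASVs missing from taxonomy: {missing[:5]}")


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable(pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False))


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.lineages.to_csv(path, sep="\t", index_label="asv_id")


# ---------------------------------------------------------------------------
# PhyloTree


class PhyloTree:
    """A rooted tree over ASVs (skbio ``TreeNode``) with validated leaves."""

    def __init__(self, tree: TreeNode) -> None:
        names = [t.name for t in tree.tips()]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate leaf labels in tree")
        defaulted = 0
        for node in tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
                if not node.is_root():  # a rootless length is conventional
                    defaulted += 1
            elif not np.isfinite(node.length) or node.length < 0:
                raise ValidationError("branch lengths must be finite and >= 0")
        if defaulted:
            logger.warning("%d missing branch lengths defaulted to 0", defaulted)
        self.tree = tree

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return float(sum(n.length for n in self.tree.traverse(include_self=False)))


def read_tree(path) -> PhyloTree:
    return PhyloTree(TreeNode.read(str(path), format="newick"))


def parse_tree(newick: str) -> PhyloTree:
    return PhyloTree(TreeNode.read([newick], format="newick"))


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# SampleMetadata


@dataclass
class SampleMetadata:
    """Per-sample covariates: gender, age (years), free-text region."""

    table: pd.DataFrame
    age_range: tuple[int, int] = (18, 120)

    def __post_init__(self) -> None:
        required = {"gender", "age"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        bad = sorted(set(self.table["gender"]) - {"female", "male"})
        if bad:
            raise ValidationError(f"unknown gender labels: {bad}")
        ages = self.table["age"]
        lo, hi = self.age_range
        if ((ages < lo) | (ages > hi)).any():
            raise ValidationError(f"ages outside plausible range [{lo}, {hi}]")

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]


def read_metadata(path, age_range: tuple[int, int] = (18, 120)) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["age"] = df["age"].astype(int)
    return SampleMetadata(df, age_range=age_range)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Reports


def write_report(report, path) -> None:
    """Serialize a report object to JSON (``.json``) or TSV (anything else).

    Any object exposing ``to_dict()`` (JSON) and/or ``to_frame()`` (TSV)
    can be written; plain dicts go to JSON directly.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
    else:
        frame = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
        frame.to_csv(path, sep="\t")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, set, frozenset)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj)}")
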