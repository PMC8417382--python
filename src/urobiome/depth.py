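"""Sequencing-depth and sample-size detection-sensitivity design.

Given a (decontaminated) count table, these tools estimate how much of
the ASV inventory survives shallower sequencing or smaller cohorts:
reads are subsampled without replacement (the same semantics as
rarefaction), samples are drawn without replacement, and sensitivity is
the fraction of the full-data reference ASV set still detected.  The
resulting curves support recommendations of the form "at least 40,000
reads and a cohort larger than 70 samples for 90% detection
sensitivity".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_BOUNDARIES = (20_000, 30_000, 40_000, 50_000, 60_000, 70_000, 80_000)


@dataclass
class SensitivityCurve:
    """Detection sensitivity along a depth or sample-size grid."""

    axis: str  # "depth" or "n_samples"
    grid: np.ndarray
    sensitivity: np.ndarray  # mean fraction of reference ASVs detected
    dispersion: np.ndarray  # Monte-Carlo SD per grid point
    reference_asv_count: int
    replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.axis: self.grid, "sensitivity": self.sensitivity, "sd": self.dispersion}
        )


def bin_by_depth(cm: CountMatrix, boundaries=DEFAULT_DEPTH_BOUNDARIES) -> pd.Series:
    """Assign every sample a raw-depth bin G1..G{n+1}.

    Bins are left-closed half-open intervals ``[b_i, b_{i+1})`` with
    open-ended first and last bins; the default boundaries are
    20k/30k/40k/50k/60k/70k/80k.
    """
    b = list(boundaries)
    if b != sorted(b) or len(set(b)) != len(b):
        raise ValueError("boundaries must be strictly increasing")
    libs = cm.library_sizes
    idx = np.searchsorted(np.asarray(b), libs.to_numpy(), side="right")
    return pd.Series([f"G{i + 1}" for i in idx], index=libs.index, name="depth_bin")


def _detect(counts: np.ndarray, min_count: int) -> np.ndarray:
    return (counts >= min_count).any(axis=0)


def depth_sensitivity(
    cm: CountMatrix,
    depth_grid,
    replicates: int = 10,
    seed: int = 0,
    min_count: int = 1,
) -> SensitivityCurve:
    """Detection sensitivity as a function of per-sample sequencing depth.

    For each grid depth ``d``, every sample is subsampled without
    replacement to ``min(d, library size)`` reads and the fraction of the
    full-depth reference ASV set still detected is recorded (mean and SD
    over ``replicates``)."""
    grid = np.asarray(sorted(depth_grid), dtype=int)
    libs = cm.library_sizes.to_numpy()
    if grid.max() > libs.max():
        raise ValueError("depth grid exceeds every library size")
    counts = cm.counts.to_numpy()
    reference = _detect(counts, min_count)
    n_ref = int(reference.sum())
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for d in grid:
        hits = []
        for _ in range(replicates):
            sub = np.empty_like(counts)
            for i, row in enumerate(counts):
                if libs[i] <= d:
                    sub[i] = row
                else:
                    sub[i] = rng.multivariate_hypergeometric(row, int(d))
            detected = _detect(sub, min_count)
            hits.append((detected & reference).sum() / n_ref)
        means.append(float(np.mean(hits)))
        sds.append(float(np.std(hits, ddof=1)) if replicates > 1 else 0.0)
    return SensitivityCurve(
        axis="depth",
        grid=grid,
        sensitivity=np.array(means),
        dispersion=np.array(sds),
        reference_asv_count=n_ref,
        replicates=replicates,
    )


def samplesize_sensitivity(
    cm: CountMatrix,
    n_grid,
    replicates: int = 10,
    seed: int = 0,
    min_count: int = 1,
) -> SensitivityCurve:
    """Detection sensitivity as a function of cohort size: for each n,
    draw n samples without replacement and record the fraction of the
    full-cohort ASV set detected in the subset."""
    grid = np.asarray(sorted(n_grid), dtype=int)
    n_total = len(cm.sample_ids)
    if grid.max() > n_total:
        raise ValueError("sample-size grid exceeds the cohort")
    counts = cm.counts.to_numpy()
    reference = _detect(counts, min_count)
    n_ref = int(reference.sum())
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for n in grid:
        hits = []
        for _ in range(replicates):
            chosen = rng.choice(n_total, size=int(n), replace=False)
            detected = _detect(counts[chosen], min_count)
            hits.append((detected & reference).sum() / n_ref)
        means.append(float(np.mean(hits)))
        sds.append(float(np.std(hits, ddof=1)) if replicates > 1 else 0.0)
    return SensitivityCurve(
        axis="n_samples",
        grid=grid,
        sensitivity=np.array(means),
        dispersion=np.array(sds),
        reference_asv_count=n_ref,
        replicates=replicates,
    )


def recommend_design(
    curves: dict[str, SensitivityCurve], target_sensitivity: float = 0.90
) -> dict:
    """Smallest grid value per curve whose mean sensitivity reaches the
    target, with a linearly interpolated value between the bracketing
    grid points (flagged ``interpolated``); unreachable targets are
    reported as unattained."""
    out: dict[str, dict] = {"target_sensitivity": target_sensitivity}
    for name, curve in curves.items():
        entry: dict = {"attained": bool((curve.sensitivity >= target_sensitivity).any())}
        if entry["attained"]:
            idx = int(np.argmax(curve.sensitivity >= target_sensitivity))
            entry["min_value"] = int(curve.grid[idx])
            if idx > 0 and curve.sensitivity[idx] > target_sensitivity:
                lo_s, hi_s = curve.sensitivity[idx - 1], curve.sensitivity[idx]
                lo_g, hi_g = curve.grid[idx - 1], curve.grid[idx]
                frac = (target_sensitivity - lo_s) / (hi_s - lo_s)
                entry["interpolated"] = float(lo_g + frac * (hi_g - lo_g))
        out[name] = entry
    return out
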