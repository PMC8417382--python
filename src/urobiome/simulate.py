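"""Synthetic genitourinary-cohort generator with planted ground truth.

The generator emulates the statistical structure of a low-biomass 16S
amplicon survey of midstream urine:

* a community of ~140 genera — six dominant genera plus a long log-normal
  tail of low-abundance genera, each genus owning 1-10 ASVs;
* urotype structure: each sample belongs to one community state type
  dominated by a single genus.  One designated genus (the *Prevotella*
  analogue) follows a single log-normal across all samples and dominates
  the baseline urotype; the other dominant genera are drawn from a
  two-component process (low baseline everywhere, boosted in their own
  urotype), producing bimodal abundance distributions;
* a strongly co-abundant three-genus trio (*Peptoniphilus*, *Ezakiella*,
  *Porphyromonas* analogues) drawn through a Gaussian copula; the trio's
  abundance scales both the total size and the Dirichlet concentration of
  the low-abundance tail, so high-trio samples are richer and more even —
  which is what couples the trio to alpha diversity downstream;
* reagent contaminants: a fixed reagent profile that makes up most of each
  negative-control (NC) library and leaks into genitourinary (GU) samples
  at a small compositional load;
* index-hopping artifacts: foreign ASVs that leak into one or two specific
  recipient samples at well under 5 per mille;
* gender and age covariates with per-genus multiplicative abundance shifts.

Everything is driven by one ``numpy.random.default_rng(seed)`` stream, so a
config is a complete, reproducible description of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CountMatrix, PhyloTree, SampleMetadata, TaxonomyTable

DOMINANT_GENERA = (
    "Prevotella",
    "Streptococcus",
    "Escherichia-Shigella",
    "Lactobacillus",
    "Gardnerella",
    "Veillonella",
)
TRIO_GENERA = ("Peptoniphilus", "Ezakiella", "Porphyromonas")

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")
_GENUS_PHYLUM = {
    "Prevotella": "Bacteroidetes",
    "Streptococcus": "Firmicutes",
    "Escherichia-Shigella": "Proteobacteria",
    "Lactobacillus": "Firmicutes",
    "Gardnerella": "Actinobacteria",
    "Veillonella": "Firmicutes",
    "Peptoniphilus": "Firmicutes",
    "Ezakiella": "Firmicutes",
    "Porphyromonas": "Bacteroidetes",
}
_REGIONS = ("Anqing", "Lianyungang", "Wuyuan")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    The defaults describe the "desk"-scale cohort (300 GU + 10 NC samples)
    used throughout the test-bench; :func:`default_cohort_config`
    rescales them.
    """

    n_gu: int = 300
    n_nc: int = 10
    n_true_asvs: int = 520
    n_contaminant_asvs: int = 30
    n_hop_asvs: int = 50
    n_genera: int = 140
    # (dominant genus, mixing weight, intensity boost in its own urotype)
    urotype_spec: tuple = (
        ("Prevotella", 0.40, 1.0),
        ("Streptococcus", 0.15, 80.0),
        ("Escherichia-Shigella", 0.12, 80.0),
        ("Lactobacillus", 0.12, 80.0),
        ("Gardnerella", 0.11, 80.0),
        ("Veillonella", 0.10, 80.0),
    )
    trio_spec: tuple = (TRIO_GENERA, 0.8)  # (genus triple, copula correlation)
    depth_distribution: tuple = (40_000.0, 0.45)  # (mean reads, log-sd)
    nc_depth_distribution: tuple = (2_500.0, 0.5)
    hop_rate: float = 4e-4  # expected hopped fraction of a recipient library
    contaminant_nc_load: float = 0.8  # expected contaminant fraction of NC reads
    gu_contaminant_load: float = 0.015  # mean contaminant fraction of GU reads
    # community-shape knobs (intensity scale; relative abundances emerge by
    # per-sample normalisation)
    prevotella_intensity: tuple = (0.30, 0.6)  # (mean, log-sd), single log-normal
    dominant_baseline_intensity: tuple = (0.025, 1.0)
    dominant_boosted_logsd: float = 0.4  # spread of the high-abundance mode
    trio_intensity: tuple = (0.02, 1.2)
    tail_total_intensity: tuple = (0.30, 0.4)
    tail_weight_logsd: float = 1.6  # spread of fixed tail-genus weights
    tail_weight_floor: float = 4e-4  # minimum tail-genus weight (pre-normalisation)
    tail_concentration: float = 25.0  # Dirichlet concentration of the tail split
    trio_tail_coupling: float = 0.5  # exponent tying tail size/evenness to the trio
    female_fraction: float = 0.637
    age_range: tuple = (45, 86)
    gender_effects: dict = field(
        default_factory=lambda: {
            "Lactobacillus": 2.0,
            "Prevotella": 1.4,
            "Streptococcus": 0.6,
            "Veillonella": 0.7,
        }
    )  # multiplier applied to female samples; male = 1
    age_effects: dict = field(
        default_factory=lambda: {"Lactobacillus": -0.04, "Gardnerella": -0.02}
    )  # per-year log-slope around age 65
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_gu", "n_nc", "n_true_asvs", "n_contaminant_asvs", "n_genera"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.hop_rate < 0.01):
            raise ValueError("hop_rate must be in [0, 0.01)")
        trio, rho = self.trio_spec
        if not (0 < rho < 1):
            raise ValueError("trio copula correlation must be in (0, 1)")
        if len(set(trio)) != 3:
            raise ValueError("trio_spec needs three distinct genera")
        weights = [w for _, w, _ in self.urotype_spec]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("urotype mixing weights must sum to 1")
        dominants = [g for g, _, _ in self.urotype_spec]
        if len(set(dominants)) != len(dominants):
            raise ValueError("urotype dominant genera must be distinct")
        if len(self.urotype_spec) + len(trio) > self.n_genera:
            raise ValueError("more urotype/trio genera than genera available")
        if not (len(self._all_genera()) <= self.n_true_asvs <= 10 * self.n_genera):
            raise ValueError("n_true_asvs must allow 1-10 ASVs per genus")

    def _all_genera(self) -> list[str]:
        named = [g for g, _, _ in self.urotype_spec] + [
            g for g in self.trio_spec[0] if g not in {x for x, _, _ in self.urotype_spec}
        ]
        n_tail = self.n_genera - len(named)
        return named + [f"Genus_{i:03d}" for i in range(1, n_tail + 1)]


@dataclass
class SimulationTruth:
    """Planted ground truth for every downstream stage."""

    contaminant_asvs: set
    hop_artifact_asvs: set
    urotype_label: pd.Series  # per GU sample: dominant genus of its urotype
    trio_genera: tuple
    genus_of_asv: dict

    @property
    def true_asvs(self) -> set:
        return {
            a
            for a in self.genus_of_asv
            if a not in self.contaminant_asvs and a not in self.hop_artifact_asvs
        }

    def to_dict(self) -> dict:
        return {
            "contaminant_asvs": sorted(self.contaminant_asvs),
            "hop_artifact_asvs": sorted(self.hop_artifact_asvs),
            "urotype_label": self.urotype_label.to_dict(),
            "trio_genera": list(self.trio_genera),
            "genus_of_asv": self.genus_of_asv,
        }


def default_cohort_config(scale: str, seed: int = 0) -> SimulationConfig:
    """Cohort-shaped defaults at three scales.

    ``tiny`` runs end-to-end in seconds, ``desk`` (300 GU + 10 NC) is the
    test-bench scale, ``full`` is the full-survey shape (1,165 GU
    samples after filtering, 63.7% female, ages 45-86, mean depth ~40k).
    """
    base = SimulationConfig(seed=seed)
    if scale == "tiny":
        # 4 NCs against 80 GUs keeps the NC-sample-count decontamination
        # clause (NC presence in >6% of all samples) out of reach of the
        # controls themselves; a smaller cohort trips it on real signal
        return replace(
            base,
            n_gu=80,
            n_nc=4,
            n_genera=40,
            n_true_asvs=120,
            n_contaminant_asvs=10,
            n_hop_asvs=10,
            depth_distribution=(20_000.0, 0.4),
        )
    if scale == "desk":
        return base
    if scale == "full":
        return replace(base, n_gu=1165, n_nc=20, n_true_asvs=1000)
    raise ValueError(f"unknown scale {scale!r}; expected tiny/desk/full")


# ---------------------------------------------------------------------------
# generator internals


def _allocate_asvs(genera, genus_mean, n_true_asvs, rng):
    """1-10 ASVs per genus, richer genera owning more, totalling n_true_asvs."""
    order = np.argsort(np.argsort(genus_mean))  # ranks, 0 = poorest
    score = 1.0 + 9.0 * order / max(len(genera) - 1, 1)
    quota = np.maximum(1, np.floor(score / score.sum() * n_true_asvs)).astype(int)
    quota = np.minimum(quota, 10)
    # largest-remainder style top-up / trim to hit the exact total
    while quota.sum() < n_true_asvs:
        room = np.flatnonzero(quota < 10)
        quota[rng.choice(room)] += 1
    while quota.sum() > n_true_asvs:
        room = np.flatnonzero(quota > 1)
        quota[rng.choice(room)] -= 1
    return quota


def _coalesce(nodes: list, rng, scale: float) -> TreeNode:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        a.length = float(rng.exponential(scale)) + (a.length or 0.0)
        b.length = float(rng.exponential(scale)) + (b.length or 0.0)
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _build_tree(genus_of_asv: dict, rng) -> PhyloTree:
    """Random coalescent with genus-level monophyly."""
    by_genus: dict[str, list] = {}
    for asv, genus in genus_of_asv.items():
        by_genus.setdefault(genus, []).append(asv)
    genus_roots = []
    for genus in by_genus:
        tips = [TreeNode(name=a, length=float(rng.exponential(0.02))) for a in by_genus[genus]]
        if len(tips) == 1:
            genus_roots.append(tips[0])
        else:
            genus_roots.append(_coalesce(tips, rng, 0.02))
    tree = _coalesce(genus_roots, rng, 0.1)
    return PhyloTree(tree)


def simulate_cohort(config: SimulationConfig):
    """Generate ``(CountMatrix, TaxonomyTable, PhyloTree, SampleMetadata,
    SimulationTruth)`` for one synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    genera = config._all_genera()
    n_genera = len(genera)
    dominants = [g for g, _, _ in config.urotype_spec]
    boosts = {g: b for g, _, b in config.urotype_spec}
    weights = np.array([w for _, w, _ in config.urotype_spec])
    trio, rho_trio = config.trio_spec
    prevotella = dominants[0]
    tail_genera = [g for g in genera if g not in set(dominants) | set(trio)]

    # fixed community parameters -------------------------------------------
    tail_w = rng.lognormal(0.0, config.tail_weight_logsd, size=len(tail_genera))
    tail_w = np.sort(tail_w)[::-1]
    tail_w /= tail_w.sum()
    # floor keeps every tail genus at core-microbiota abundance (MRA >~ 0.01%)
    tail_w = np.maximum(tail_w, config.tail_weight_floor)
    tail_w /= tail_w.sum()

    # genus expected mean intensity, for ASV allocation only
    mean_intensity = {}
    mean_intensity[prevotella] = config.prevotella_intensity[0]
    for g in dominants[1:]:
        mean_intensity[g] = config.dominant_baseline_intensity[0] * (
            1 + boosts[g] * weights[dominants.index(g)]
        )
    for g in trio:
        mean_intensity[g] = config.trio_intensity[0]
    for g, w in zip(tail_genera, tail_w):
        mean_intensity[g] = config.tail_total_intensity[0] * w

    quota = _allocate_asvs(genera, np.array([mean_intensity[g] for g in genera]), config.n_true_asvs, rng)
    genus_of_asv: dict[str, str] = {}
    asv_split = {}
    counter = 1
    for g, k in zip(genera, quota):
        ids = [f"ASV_{counter + j:04d}" for j in range(int(k))]
        counter += int(k)
        for a in ids:
            genus_of_asv[a] = g
        asv_split[g] = (ids, rng.dirichlet(np.ones(int(k))))
    true_asvs = [a for g in genera for a in asv_split[g][0]]

    contam_asvs = [f"ASV_{counter + j:04d}" for j in range(config.n_contaminant_asvs)]
    counter += config.n_contaminant_asvs
    hop_asvs = (
        [f"ASV_{counter + j:04d}" for j in range(config.n_hop_asvs)] if config.hop_rate > 0 else []
    )
    for j, a in enumerate(contam_asvs):
        genus_of_asv[a] = f"Reagent_genus_{j // 3 + 1:02d}"
    for j, a in enumerate(hop_asvs):
        genus_of_asv[a] = f"Foreign_genus_{j // 5 + 1:02d}"
    contam_w = rng.dirichlet(np.ones(config.n_contaminant_asvs))

    # per-sample genus intensities -----------------------------------------
    n_gu = config.n_gu
    gu_ids = [f"GU{i + 1:04d}" for i in range(n_gu)]
    urotype_idx = rng.choice(len(dominants), size=n_gu, p=weights)
    gender = np.where(rng.random(n_gu) < config.female_fraction, "female", "male")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n_gu)
    region = rng.choice(_REGIONS, size=n_gu)

    def _logn(mean, sd, size):
        return rng.lognormal(np.log(mean) - sd**2 / 2.0, sd, size=size)

    intensity = np.zeros((n_gu, n_genera))
    col = {g: i for i, g in enumerate(genera)}
    intensity[:, col[prevotella]] = _logn(*config.prevotella_intensity, n_gu)
    for g in dominants[1:]:
        # two distinct processes: a low baseline everywhere and a tighter
        # high-abundance mode inside the genus's own urotype -> bimodal
        base = _logn(*config.dominant_baseline_intensity, n_gu)
        boosted = urotype_idx == dominants.index(g)
        n_boost = int(boosted.sum())
        base[boosted] = _logn(
            config.dominant_baseline_intensity[0] * boosts[g],
            config.dominant_boosted_logsd,
            n_boost,
        )
        intensity[:, col[g]] = base

    # trio through a Gaussian copula with common correlation rho_trio
    cov = np.full((3, 3), rho_trio)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(3), cov, size=n_gu)
    t_mean, t_sd = config.trio_intensity
    trio_int = np.exp(np.log(t_mean) - t_sd**2 / 2.0 + t_sd * z)
    for j, g in enumerate(trio):
        intensity[:, col[g]] = trio_int[:, j]

    # low-abundance tail: total size and Dirichlet concentration both scale
    # with the trio, so high-trio communities are larger-tailed and more even
    trio_factor = (trio_int.sum(axis=1) / (3 * t_mean)) ** config.trio_tail_coupling
    trio_factor = np.clip(trio_factor, 0.1, 10.0)
    tail_total = _logn(*config.tail_total_intensity, n_gu) * trio_factor
    alpha = config.tail_concentration * np.outer(trio_factor, tail_w)
    tail_share = rng.gamma(np.maximum(alpha, 1e-12))
    tail_share /= tail_share.sum(axis=1, keepdims=True)
    for j, g in enumerate(tail_genera):
        intensity[:, col[g]] = tail_total * tail_share[:, j]

    # gender / age multiplicative shifts
    for g, mult in config.gender_effects.items():
        if g in col:
            intensity[gender == "female", col[g]] *= mult
    for g, slope in config.age_effects.items():
        if g in col:
            intensity[:, col[g]] *= np.exp(slope * (age - 65.0))

    # expand genus intensity to true-ASV probabilities
    p_true = np.zeros((n_gu, len(true_asvs)))
    pos = {a: i for i, a in enumerate(true_asvs)}
    for g in genera:
        ids, split = asv_split[g]
        for a, s in zip(ids, split):
            p_true[:, pos[a]] = intensity[:, col[g]] * s
    p_true /= p_true.sum(axis=1, keepdims=True)

    # draw libraries --------------------------------------------------------
    d_mean, d_sd = config.depth_distribution
    depths = np.maximum(
        rng.lognormal(np.log(d_mean) - d_sd**2 / 2.0, d_sd, size=n_gu), 4000
    ).astype(int)
    load = rng.beta(2.0, 2.0 * (1 - config.gu_contaminant_load) / config.gu_contaminant_load, n_gu)

    all_asvs = true_asvs + contam_asvs + hop_asvs
    counts = np.zeros((n_gu + config.n_nc, len(all_asvs)), dtype=np.int64)
    n_true = len(true_asvs)
    for i in range(n_gu):
        p = np.concatenate(
            [(1 - load[i]) * p_true[i], load[i] * contam_w, np.zeros(len(hop_asvs))]
        )
        counts[i] = rng.multinomial(depths[i], p / p.sum())

    # negative controls: reagent profile plus carryover from one GU donor
    nc_ids = [f"NC{i + 1:02d}" for i in range(config.n_nc)]
    nd_mean, nd_sd = config.nc_depth_distribution
    nc_depths = np.maximum(
        rng.lognormal(np.log(nd_mean) - nd_sd**2 / 2.0, nd_sd, size=config.n_nc), 200
    ).astype(int)
    for i in range(config.n_nc):
        donor = int(rng.integers(n_gu))
        p = np.concatenate(
            [
                (1 - config.contaminant_nc_load) * p_true[donor],
                config.contaminant_nc_load * contam_w,
                np.zeros(len(hop_asvs)),
            ]
        )
        counts[n_gu + i] = rng.multinomial(nc_depths[i], p / p.sum())

    # index hopping: each foreign ASV leaks into 1-2 recipient GU samples,
    # displacing reads from the recipient's most abundant ASV
    for j, a in enumerate(hop_asvs):
        n_recipients = int(rng.integers(1, 3))
        recipients = rng.choice(n_gu, size=n_recipients, replace=False)
        for r in recipients:
            lib = counts[r, :n_true].sum()
            n_hop = 1 + rng.poisson(config.hop_rate * lib)
            n_hop = int(min(n_hop, np.floor(0.004 * lib)))
            if n_hop < 1:
                n_hop = 1
            top = int(np.argmax(counts[r, :n_true]))
            moved = min(n_hop, counts[r, top] - 1)
            counts[r, top] -= moved
            counts[r, n_true + len(contam_asvs) + j] += n_hop

    frame = pd.DataFrame(counts, index=gu_ids + nc_ids, columns=all_asvs)
    stypes = pd.Series(["GU"] * n_gu + ["NC"] * config.n_nc, index=frame.index)
    cm = CountMatrix(frame, stypes)

    # taxonomy ---------------------------------------------------------------
    records = {}
    for a, g in genus_of_asv.items():
        phylum = _GENUS_PHYLUM.get(g)
        if phylum is None:
            h = sum(ord(c) for c in g) % len(_PHYLA)  # deterministic across runs
            phylum = _PHYLA[h]
        records[a] = {
            "kingdom": "Bacteria",
            "phylum": phylum,
            "class": f"c_{phylum}",
            "order": f"o_{phylum}",
            "family": f"f_{g}",
            "genus": g,
        }
    tax = TaxonomyTable(pd.DataFrame.from_dict(records, orient="index").loc[all_asvs])

    tree = _build_tree({a: genus_of_asv[a] for a in all_asvs}, rng)

    meta = SampleMetadata(
        pd.DataFrame({"gender": gender, "age": age, "region": region}, index=gu_ids)
    )

    truth = SimulationTruth(
        contaminant_asvs=set(contam_asvs),
        hop_artifact_asvs=set(hop_asvs),
        urotype_label=pd.Series([dominants[k] for k in urotype_idx], index=gu_ids),
        trio_genera=tuple(trio),
        genus_of_asv=genus_of_asv,
    )
    return cm, tax, tree, meta, truth
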