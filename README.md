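# urobiome

Profiling the genitourinary microbiome from low-biomass 16S amplicon data.

Urine carries very few bacteria (<10⁵ CFU/ml), so an ASV count table from
midstream urine is dominated easily by reagent contaminants and
index-hopping cross-talk. `urobiome` implements an end-to-end analysis
pipeline for such cohorts — negative-control-based contaminant removal,
rarefied core-microbiota profiling, alpha/beta diversity, urotype
(community-state-type) clustering, co-occurrence networks with keystone
detection, gender/age cohort statistics, and a sequencing-depth /
sample-size sensitivity design tool — together with a synthetic cohort
generator that plants ground truth for every stage, so the whole pipeline
is testable without access to a real cohort.

It is aimed at microbiome bioinformaticians working downstream of DADA2 /
QIIME2: the inputs are an ASV count table (TSV), a sample-type map
(GU = genitourinary specimen, NC = negative control, PC = positive
control), an ASV taxonomy table, a rooted newick tree, and per-sample
metadata.

## Methods at the core

**Decontamination.** Four rules, flags computed jointly on the unfiltered
matrix: (1) an ASV more prevalent in NCs than GUs (2×2 presence table,
chi-square with Fisher fallback, *p* < 0.5) is a contaminant; (2) an ASV
whose NC reads exceed 5% of its total reads, or present in NC samples
numbering >6% of all samples, is removed; (3) an ASV in <3 GU samples,
always below 5‰ relative abundance, is index-hopping cross-talk; (4) only
samples retaining >50% of reads survive.

**Profiling.** Each library is rarefied to 4,000 reads (multivariate
hypergeometric, seeded). Mean relative abundance (MRA) stratifies taxa
into dominant (MRA > 5%), low-abundance (0.01–5%) and below-core groups.

**Diversity.** Shannon index H = −Σ pᵢ log₂ pᵢ; Faith's PD (branch length
of the minimal rooted spanning subtree); Bray–Curtis
d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); unweighted UniFrac (unique / observed
branch length), all computed from first principles against the ASV tree.

**Urotyping.** Genera with MRA > 0.1% (others pooled) are clustered by
Ward.D2 on Bray–Curtis; k is selected by mean silhouette width with the
Calinski–Harabasz index reported; clusters are named by their dominant
genus; per-genus abundance distributions are classified unimodal
log-normal vs multimodal by a two-component Gaussian mixture (ΔBIC > 10
and >1 pooled-SD mean separation).

**Networks.** Genus–genus Spearman correlations (midranks, t-approximation
p-values, Benjamini–Hochberg across all pairs); edges need |ρ| > 0.35 and
q < 0.05; keystones are the highest-degree nodes; a designated trio is
tested for joint presence, mutual co-abundance, and Pearson association
with Shannon diversity.

**Design.** Detection sensitivity — the fraction of the full-data ASV
inventory still seen — is estimated along sequencing-depth and
cohort-size grids by seeded subsampling without replacement, yielding
recommendations of the form "≥N reads and >M samples for 90% sensitivity".

## Worked example

```python
from urobiome import *
from urobiome.simulate import default_cohort_config, simulate_cohort

cfg = default_cohort_config("desk", seed=42)   # 300 GU + 10 NC samples
counts, taxonomy, tree, metadata, truth = simulate_cohort(cfg)

filtered, report = apply_qc(counts)
print("ASVs removed:", len(report.removed_asvs()), "of", len(counts.asv_ids))
print("mean reads retained: {:.2%}".format(report.reads_retained_overall))

rarefied = rarefy(filtered, depth=4000, seed=0)
profile = relative_abundance(collapse_taxonomy(rarefied, taxonomy, "genus"), rank="genus")
print("dominant genera:", sorted(core_taxa(profile)["dominant"]))

res = discover_urotypes(profile, k_range=range(2, 11))
print("urotypes:", res.k, "->", res.dominant_genus)

net = spearman_network(profile)
print("top hubs:", list(detect_keystones(net, 3)["genus"]))
```

prints

```
ASVs removed: 81 of 600
mean reads retained: 98.50%
dominant genera: ['Escherichia-Shigella', 'Gardnerella', 'Lactobacillus', 'Prevotella', 'Streptococcus', 'Veillonella']
urotypes: 6 -> {1: 'Streptococcus', 2: 'Lactobacillus', 3: 'Veillonella', 4: 'Prevotella', 5: 'Gardnerella', 6: 'Escherichia-Shigella'}
top hubs: ['Ezakiella', 'Peptoniphilus', 'Porphyromonas']
```

The 81 removed ASVs are the 30 planted reagent contaminants, the 50
planted hopping artifacts, and one stray true ASV; the six dominant
genera, the six urotypes (one per planted community state), and the
keystone trio are all recovered from the simulated data.

The same pipeline runs from the shell:

```bash
urobiome run-all --scale desk --seed 42 --out out/
```

writing per-stage TSV/JSON reports and a `manifest.json` whose checksums
are byte-identical for identical config + seed.

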