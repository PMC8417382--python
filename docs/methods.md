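# Methods

This note records the models, conventions and numerical choices behind
`urobiome`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The decontamination model

Low-biomass specimens sit close to the reagent background: negative
controls (sterile water carried through extraction, PCR and sequencing)
capture the contaminant profile, and cross-talk between multiplexed
libraries adds spurious rare features. The four removal rules operate on
different signatures:

1. **Prevalence rule.** For each ASV the 2×2 table (GU/NC × present/
   absent) is tested for independence — chi-square without continuity
   correction, switching to Fisher's exact test when any expected cell is
   below 5. The two-sided p is combined with a one-sided direction
   condition (NC prevalence fraction strictly above GU prevalence); the
   default cutoff is the deliberately permissive *p* < 0.5, mirroring the
   prevalence-based decontamination practice for low-biomass data, where
   a false-positive contaminant call is cheap and a false negative is
   expensive. ASVs never seen in an NC are exempt. "Present" means
   count ≥ 1 (configurable).
2. **NC read-fraction rule.** Flags an ASV when NC reads exceed 5% of the
   ASV's total reads — contaminants concentrate in NCs because NC
   libraries contain little else — or when the ASV occurs in NC samples
   numbering more than 6% of all samples. The second clause is kept
   configurable and interpreted as written; note it can only fire when
   the NC count itself exceeds 6% of the cohort (see *Scales* below).
3. **Cross-talk rule.** An ASV present in fewer than 3 GU samples whose
   relative abundance (against the sample's raw library size) stays below
   5‰ everywhere it occurs matches the index-hopping signature. The
   abundance summary over occurrence samples is the maximum (the most
   conservative choice for retention); a mean option exists.
4. **Sample retention.** After removing the union of rule-1/2/3 flags,
   GU samples keeping ≤ 50% of their reads are dropped. The denominator
   is each sample's own pre-filter library size (`retention_mode=
   "per_sample"`); a cohort-average mode is provided because retention is
   sometimes quoted against the mean sequencing depth.

Flags are computed once on the unfiltered matrix and applied jointly, so
the three ASV rules commute and the audit trail (`ContaminantReport`) is
order-independent. The reported summary retention is the mean per-sample
retained fraction over kept GU samples.

## Profiling conventions

* Rarefaction draws exactly `depth` reads per sample without replacement
  (`numpy` multivariate hypergeometric), dropping shallower samples
  rather than scaling them. Default depth 4,000 reads.
* MRA is the mean of per-sample relative abundances on the rarefied
  table, zeros included. Prevalence is likewise computed post-rarefaction
  for internal consistency (pre-rarefaction prevalence differs only
  through the dropped samples and the subsampling of singletons).
* Strata: dominant is strictly MRA > 5%; low-abundance is the closed
  interval down to 0.01% (boundary values fall in the lower stratum's
  upper edge, i.e. exactly 5% is low-abundance, exactly 0.01% is
  low-abundance).

## Diversity

Shannon uses log base 2 (the QIIME2-diversity convention; the base is an
argument because conventions differ). Faith's PD is the branch length of
the union of root-to-leaf paths of observed taxa. Unweighted UniFrac
classifies each edge by whether its descendant leaves intersect either
sample's taxon set: d = unique / (unique + shared), computed for all
pairs at once by post-order accumulation into an edge × sample incidence
matrix. The root's (length-zero by convention) stem never contributes.
Bray–Curtis is computed on relative abundances, so all beta distances lie
in [0, 1].

Group comparisons of alpha values use two-sided Wilcoxon rank-sum tests.
For beta diversity, within-group pairwise distances of one group are
compared to another group's by the same test; pairwise distances are not
independent observations, so these p-values are descriptive and the code
logs that caveat. This is a declared convention, not an attempt to mimic
any particular published procedure.

## Urotyping

The genus matrix keeps genera with MRA strictly above 0.1% and pools the
rest into `Others` (rows still sum to 1; `Others` participates in the
distances so the composition stays closed). Clustering is agglomerative
with the Ward.D2 criterion — the Lance–Williams update applied to squared
dissimilarities with heights reported on the original scale — on
Bray–Curtis distances. Ward's variance interpretation formally assumes
Euclidean geometry; using it on Bray–Curtis is the standard
enterotype/urotype practice and is taken deliberately.

k is chosen as the argmax of mean silhouette width over the candidate
range, with the Calinski–Harabasz curve reported alongside (when the two
disagree, silhouette wins; ties resolve toward smaller k). Singleton
clusters contribute silhouette 0. Clusters are labelled by the genus with
the highest within-cluster MRA, or `mixed` below a 25% dominance
threshold — a declared constant, since "mixed" has no standard numeric
definition.

Modality classification fits 1- and 2-component Gaussian mixtures to log
positive abundances (zeros excluded; fewer than 50 positive observations
yields `insufficient_data`). `multimodal` requires the 2-component fit to
win by more than 10 BIC *and* component means separated by more than one
pooled SD; both margins are arguments. BIC 10 is the usual "very strong
evidence" threshold and the separation guard prevents calling two
near-coincident components a second mode.

## Networks

Spearman correlations use midranks and the large-sample t approximation
for p-values (an exact permutation option would only matter below ~30
samples). One BH family covers all genus pairs of a network build.
Edges require |ρ| > 0.35 and q < 0.05; both filters are monotone, so
tightening either yields an edge subset. Keystones rank by degree with
summed |ρ| as tie-break; "highly connected" has no formal definition, so
degree centrality is the declared choice, with strength reported.

The trio test uses the 2×2 table (genus A present) × (B and C both
present) with the same chi-square/Fisher logic — a correctly calibrated
contingency test of the triple co-occurrence pattern. A goodness-of-fit
test of the joint-presence count against plug-in independent marginals is
not calibrated and was rejected. Zeros are included in correlation inputs
(`positive_only` exists as an option).

## Depth / cohort-size design

Depth bins default to eight left-closed intervals with boundaries
20k…80k (G1 = below 20,000 … G8 = at least 80,000). Sensitivity at depth
d subsamples every library to min(d, library) without replacement and
counts the surviving fraction of the full-data ASV inventory, so the
reference point is exactly 1 by construction; cohort-size sensitivity
draws n samples without replacement. Detection means count ≥ 1 after
subsampling (configurable). Recommendations take the smallest grid value
reaching the target mean sensitivity (default 90%), with a linear
interpolation between the bracketing grid points flagged as such.

Note that the recommendation depends on the rarity structure of the
input: the synthetic cohorts below have a few hundred mostly-prevalent
true ASVs, so their detection saturates at much lower depth and cohort
size than a real survey with thousands of rare ASVs would.

## The synthetic cohort generator

The generator is a first-class, tested component; its defaults define the
study conditions of the test bench ("desk" scale: 300 GU + 10 NC samples,
~140 genera, 520 true ASVs, 30 reagent contaminants, 50 hopping
artifacts, library sizes log-normal with mean 40,000, cohort 63.7%
female, ages uniform on 45–86).

Per sample, genus-level expected abundances are built on an intensity
scale and normalised:

* One designated genus (the *Prevotella* analogue, mean intensity 0.30,
  log-SD 0.6) follows a single log-normal across all samples and
  dominates the baseline urotype.
* Each other dominant genus is a two-process mixture: a low baseline
  everywhere (mean 0.025, log-SD 1.0) and a tighter high mode (80× the
  baseline mean, log-SD 0.4) inside its own urotype — hence bimodal
  marginals whose high mode concentrates in the matching urotype.
  Urotype membership is categorical with weights (0.40, 0.15, 0.12,
  0.12, 0.11, 0.10).
* A three-genus trio is drawn through a Gaussian copula with common
  correlation 0.8 on log-normal marginals (mean 0.02, log-SD 1.2).
* The low-abundance tail (~131 genera with fixed log-normal weights,
  floored so every genus stays at core-microbiota abundance) is a
  Dirichlet split whose concentration *and* total intensity both scale
  with the trio (exponent 0.5): high-trio communities are larger-tailed
  and more even. This induces, rather than hard-codes, the positive
  association between the trio and Shannon diversity and makes the trio
  the natural network hub — the trio drives the shared factor that the
  tail genera merely follow.
* NC libraries (log-normal, mean 2,500 reads) are 80% a fixed reagent
  contaminant profile and 20% carryover drawn from one random GU donor's
  expected composition. Donor-based carryover (rather than the cohort
  mean) keeps an NC's true-ASV prevalence stochastically at or below GU
  prevalence, which is the behaviour real signal shows against controls.
  GU samples carry the same reagent profile at a small compositional load
  (Beta-distributed, mean 1.5%).
* Index hopping assigns each foreign ASV one or two specific recipient
  samples (combinatorial index-pair leakage) with Poisson read counts
  capped below 5‰ of the library, displacing reads from the recipient's
  most abundant ASV so totals are conserved. Uniform redistribution of
  reads among samples sharing one ASV pool cannot create the
  few-sample/low-abundance artifact signature at all, which is why the
  leakage is pairwise.
* Gender and age act as per-genus multiplicative intensity shifts
  (e.g. the *Lactobacillus* analogue ×2 in females with a −0.04/year
  log-slope), emulating hormone-linked trends.
* ASV structure: each genus owns 1–10 ASVs (richer genera own more) with
  fixed Dirichlet(1) internal proportions; the tree is a random
  coalescent with genus-level monophyly so phylogenetic metrics reflect
  taxonomy. Counts are multinomial at the drawn library size. One
  `numpy.random.default_rng(seed)` stream drives everything.

Free parameters without an external anchor (tail concentration 25, trio
coupling exponent 0.5, dominance boost 80, GU contaminant load 1.5%)
were fixed once by Monte-Carlo so the generator reproduces the
qualitative features it is meant to emulate — trio pairwise rank
correlations above 0.75, a trio–Shannon correlation near 0.6–0.7,
urotypes strongly dominated by a single genus, and ~98% read retention
after QC — and are exposed on `SimulationConfig`.

### Scales

`default_cohort_config` provides `tiny` (80 GU + 4 NC, quick smoke
runs), `desk` (300 GU + 10 NC, the test-bench scale) and `full`
(1,165 GU). Tiny uses 4 NCs against 80 GUs because the rule-2 NC-sample
clause fires whenever an ASV occurs in NC samples numbering >6% of the
cohort: with too few GUs per NC, trace carryover alone puts real ASVs
over that line and the decontamination (correctly, per its definition)
destroys the cohort. The tiny shape is chosen so the clause cannot be
triggered by the controls themselves, which is also the regime of the
real study design.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline is sensitive to:
dominance-driven community states, bimodal vs log-normal genus marginals,
copula-linked co-abundance, prevalence asymmetries between specimens and
controls, compositional contamination, rare-artifact signatures, and
covariate-linked shifts. It does not emulate sequencing-error processes
(chimeras, PCR bias), batch structure, subclustered community states,
thousands-strong rare-ASV inventories, or realistic taxonomies beyond
genus/phylum bookkeeping. Passing tests therefore demonstrate that the
pipeline recovers planted structure of these kinds at realistic effect
sizes — not that any particular real cohort would yield the same
numbers; headline quantities from real data (e.g. exact retained-ASV
counts) depend on the cohort and are not reproduction targets here.

## Numerical and engineering choices

* All tests of 2×2 tables share one code path (`chi-square, Fisher below
  expected-cell 5, correction-free`) so unit oracles cover every caller.
* Rarefaction, subsampling, simulation and GMM fits are seeded
  explicitly; the pipeline manifest contains no timestamps, making
  run-to-run checksums comparable.
* Ward merges inherit scipy's deterministic tie-handling; cluster labels
  are stable under sample permutation up to relabelling (tested).
* Degenerate inputs: all-zero samples are rejected by Shannon/UniFrac,
  skipped with warnings elsewhere; constant genera are excluded from
  correlation families; empty networks return empty keystone lists.

## Known limitations

* The beta-diversity group test treats pairwise distances as
  observations; a permutation procedure (e.g. PERMANOVA) would be the
  inferential upgrade but is out of scope.
* Rule-1 power is bounded by the NC count; with ~10 NCs the prevalence
  test mostly relies on the direction condition plus the permissive
  cutoff, and rule 2 carries most of the removal.
* The depth/cohort-size recommendations are only as rich as the input's
  rarity structure (see above).
* No compositionality-aware correlation (SparCC-style); Spearman on
  relative abundances is the declared, simpler choice and its
  compositional artefacts are part of the model the thresholds were
  chosen under.
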