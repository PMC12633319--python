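# Methods

This note documents the models and procedures implemented in `hgtcooc`,
the assumptions behind them, the synthetic community the package uses to
validate them, and the numerical choices that were genuinely open.

## Scientific setting

Marine prokaryotes exchange genes horizontally, and taxa that share an
environment are expected to exchange more. The confounder is phylogeny:
closely related genomes co-occur *and* retain near-identical sequences by
descent. The pipeline therefore (i) calls putative horizontal gene
transfer (HGT) only between genomes whose taxonomies diverge at the genus
level or broader, where high nucleotide identity is unlikely to be
ancestral; (ii) tests pairwise co-occurrence across metagenomic samples
against a hypergeometric null; and (iii) models the HGT indicator on
co-occurrence while adjusting for patristic distance and environmental
differences.

## HGT calling

**Cluster + reciprocal closest matches (focal route).** Protein-coding
genes from all genomes are clustered greedily, longest sequence first:
a gene joins the first existing cluster whose representative it matches
at ≥ 95% identity over ≥ 95% of both lengths with a length ratio ≥ 0.95,
else it founds a new cluster. The contract is the membership invariant,
not any particular clustering heuristic. Within a cluster, for each
genome pair at genus-or-broader divergence, a gene pair is called an
event iff each gene is the other's highest-identity partner in the
opposite genome and identity ≥ 0.95. Identity between equal-length
sequences is 1 − hamming/length (exact, because synthetic genes are
substitution-only); unequal lengths fall back to global-alignment edit
distance normalized by the longer length. Reciprocal ties are broken by
lexicographic gene id and flagged. Events are binned into recent
(identity ≥ 0.99) versus older (0.95–0.99) transfers, identity serving
as a proxy for event age. Calls on contigs < 5000 bp are removed *after*
event calling. Multiple distinct gene pairs between the same two genomes
count as multiple events.

**Region network (sensitive route).** Tabular local-alignment hits
(12-column outfmt-6) of length ≥ 500 bp and identity ≥ 95% between
different-genus genomes are intersected with gene intervals (1 bp of
overlap flags a gene; coordinates are converted to 0-based half-open at
exactly one point, inside the interval arithmetic). Where several hits
overlap the same gene for the same genome pair, the highest bit score
wins. This route deliberately ignores reciprocality: it maps a shared
transfer network, is more sensitive, and is expected to be a superset of
the cluster-RBH calls on synthetic data.

**Unassigned taxonomy ranks** compare as different from everything,
including other unassigned ranks. This is conservative: two unplaced
genomes are never treated as congeneric, so they stay out of the
within-genus exclusion and cannot be wrongly removed from calling — but
an unplaced pair can also never be excluded as same-genus, which slightly
widens the eligible set.

**Per-level rates.** Event counts per divergence level are normalized by
the number of genome comparisons at that level; both the raw rate and
the share (rate over the sum of rates) are emitted, since either
normalization is a defensible way to plot the level profile.

## Presence, prevalence and co-occurrence

A genome is present in a sample when its breadth of coverage is ≥ 0.30
(inclusive); abundance (RPKM) is zeroed where absent; samples with no
present genome are dropped; genomes present in fewer than 10 samples are
removed. For each remaining unordered genome pair with prevalences
n1, n2 in N samples and k shared samples, the p-value is the upper tail
P(X ≥ k) of the hypergeometric distribution of the overlap between a
random n1-subset and a fixed n2-subset — the observed k is *included* in
the tail (the standard over-representation convention; the convention is
not dictated by the underlying study, so it is documented here and
pinned by tests against exhaustive enumeration). Benjamini–Hochberg
correction runs jointly across all tested pairs; significance requires
adjusted p < 0.05 and a co-occurrence ratio k/(n1·n2/N) strictly above 1.
The simple overlap |A∩B|/min(|A|,|B|) is also provided; it saturates at
1.0 for nested sample sets, which is why the hypergeometric route is the
focal one.

**Size-fraction classes.** Samples filtered to ≤ 3 μm enrich free-living
cells ("small"); upper bounds ≥ 20 μm admit particle-attached cells
("less_filtered"); bounds in between belong to neither group. A genome
is assigned to a group only if strictly more than 75% of its occupied
samples are in that group *and* its median abundance over occupied
samples is highest there; otherwise it stays unclassified.

## Functional enrichment

COG letters are lifted from genes to clusters by strict majority among
annotated members (multi-letter genes count toward each letter); ties
and unannotated clusters are dropped, as are clusters carrying only
eukaryote-specific categories (A, B, Y, Z). Enrichment of each category
among clusters in ≥ 1 HGT event is tested per (identity bin, divergence
level) stratum with two-sided Fisher's exact tests — two-sided because
both enrichment and depletion are reported. The unit of observation is
the cluster, so a promiscuous cluster in many events counts once. BH
correction is pooled across all stratum × category tests (the
conservative reading of "corrected across reported tests"); a per-stratum
variant is available behind a flag. Mobile-genetic-element features
(proMGE-style gene hits; plasmid, virus and provirus contig labels) are
tested per gene and summarized as the ratio of flag proportions in HGT
versus non-HGT genes; ratios below 1 are additionally reported as the
inverse ("x-fold more likely not to be found").

## Pair-level logistic model

One row per unordered genome pair at genus-or-broader divergence: HGT
flag (≥ 1 cluster-RBH event), co-occurrence flag, patristic distance
(sum of branch lengths between tips, computed from the newick tree),
per-variable absolute difference of the genomes' median environmental
values (medians over each genome's occupied samples — absolute, because
signed differences are arbitrary for unordered pairs), and the fraction
pair category (both_small / both_less_filtered / other, the latter the
reference level). Continuous predictors are transformed with ordered
quantile normalization, the rank map r → Φ⁻¹((r − 0.5)/n) with average
ranks for ties; the offset choice is one of several standard variants,
and any rank-based inverse-normal map satisfying monotonicity would do.
Binary and categorical predictors are not transformed. The logistic fit
is plain maximum likelihood; perfect separation aborts with a diagnostic
rather than returning divergent estimates. Variance inflation factors
come from auxiliary linear regressions on the design matrix; model
comparison uses AIC on identical row sets. A coefficient β is reported
as an e^β-fold change in odds (1/e^β-fold decrease when β < 0).

## Sample-level model

Per sample, the prevalence of a feature is the proportion of present
genomes with ≥ 1 instance of it. Environmental variables are
de-duplicated by greedily keeping the first of any group pairwise
correlated at |Spearman ρ| ≥ 0.95 (constant variables are dropped), and
summarized by average-linkage hierarchical clustering on |1 − ρ|, whose
merge heights are checked to be non-decreasing.

The regression of HGT prevalence on environmental variables is a random
forest: a bagged ensemble of unpruned regression trees with mtry =
⌊p/3⌋ features per split, the regression default. The backend is
LightGBM in its random-forest mode (no boosting; bagging fraction 0.632
per tree, approximating the bootstrap), chosen for its fit speed at the
replicate counts the null scheme needs; the forest is a means to an
importance ranking, not an object of inference. Importance is
permutation importance — the increase in mean squared error when one
predictor column is shuffled — computed by the package itself in a
single stacked prediction pass; impurity importance is never used.
Significance follows the permutation-null scheme: the forest is refit B
times with the response freshly shuffled, and a variable's p-value is
the raw proportion of null importances at least as large as the observed
one. The raw proportion admits p = 0; a (b+1)/(B+1) variant exists
behind a flag but is off by default to match the stated rule. BH runs
across variables; the marginal association sign comes from Spearman
correlation with the response. Defaults are 10,000 trees and B = 1,000;
the validated fast mode (500 trees, B = 200) preserves both the null
calibration and single-signal recovery and is what the test suite and
pipeline default to.

Matched size-fraction samples are compared per feature with paired
Wilcoxon signed-rank tests (≥ 5 pairs required; all-zero differences
give p = 1). The fold change is reported both as the mean of per-pair
large/small ratios (pairs with small = 0 are excluded from the mean,
with a count) and as the ratio of means, since either summary is a
defensible reading of an "average fold increase".

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
at desk scale; defaults are 50 genomes over a nested 7-rank taxonomy
(1 domain, 2 phyla, … 10 genera, 20 species), 200 samples, 20 genes of
900 bp per genome on 10 kb contigs, and 20 planted transfers.

* **Taxonomy and tree.** Child taxa are distributed round-robin over
  parent taxa, so the hierarchy nests; the tree follows the taxonomy
  with branch lengths shrinking geometrically with depth, making
  patristic distance smaller within lower ranks in expectation.
* **Genes.** Background genes are i.i.d. uniform nucleotides, so
  cross-genus background identity sits near 25%, far below the 95%
  calling threshold; this is verified post hoc. Genes are
  substitution-only (no indels), so hamming identity over equal lengths
  is exact and no aligner is needed. Within-genus sequence similarity is
  deliberately not modelled: the focal analysis excludes within-genus
  pairs, and leaving them dissimilar keeps the exclusion rule
  load-bearing rather than decorative.
* **Planted transfers.** A donor gene is copied into a recipient of a
  different genus and mutated so realized identity hits a target drawn
  from the configured range (|realized − target| ≤ 2/gene length). Which
  pairs receive transfers follows a logistic model on z-scored niche
  overlap (weight `beta_cooc` = 2.0) and z-scored patristic distance
  (weight −`beta_phylo` = −1.5), with the intercept calibrated so
  per-pair inclusion probabilities sum to the requested event count —
  this keeps pairs on the steep part of the logistic, so the planted set
  is genuinely concentrated on co-occurring, closely related pairs
  rather than diluted by the sigmoid's saturated top. Donor and
  recipient genes are never reused across events, so no incidental
  high-identity pairs arise between genomes that share no planted
  transfer.
* **Occupancy.** Each sample has a latent position in niche space;
  presence probability decays with the squared distance to a genome's
  niche center, so similar-niche genomes co-occur. Breadth of coverage
  is Beta(6, 2.5) for present-intent cells and Beta(1.3, 10) for
  absent-intent cells, so the 0.30 threshold is exercised from both
  sides, including occasional misclassifications — as in real coverage
  data. A quarter of genomes prefer the small fraction and about an
  eighth the less-filtered fraction (roughly the classifiable split in
  ocean genome surveys); preference shifts the presence logit by +1.0 in
  matching samples and −2.5 in the other group and scales abundance by
  1.5, which is what makes the strict 75%-majority classification
  attainable for true specialists. Environmental variables read the
  niche plane at rotated angles plus noise: correlated, as field
  variables are, but not redundant. Size-fraction bounds are assigned to
  samples round-robin, so both groups are always populated.
* **Annotations.** COG letters and MGE flags are drawn independently of
  everything else — a true functional null, used to check type-I error
  control of the enrichment tests.

What the generator does **not** emulate: realistic nucleotide
composition, gene families and paralogy, recombination tracts or partial
transfers, indels, read-level noise, compositional abundance effects, or
chimeric assemblies. Passing tests therefore show that the statistical
machinery is correct and calibrated under the structural assumptions
above — not that those assumptions hold in any particular ocean dataset.

## Determinism and problem sizes

Every stochastic component runs off a single integer seed;
configurations reproduce byte-identical output files. The test suite and
the acceptance script validate at desk scale: 50-genome / 200-sample
communities, logistic recovery at 5,000 pairs over repeated seeds, the
random forest in fast mode, and exhaustive oracles where enumeration is
cheap (hypergeometric tails at N ≤ 12, Fisher tables with total ≤ 30).
These sizes were chosen so every property is checked in minutes on one
core while remaining large enough for the asymptotics they probe.

## Known limitations

* Greedy longest-first clustering is order-deterministic but, like any
  greedy scheme, can split a borderline cluster that a global method
  would merge; only the membership invariant is guaranteed.
* The hypergeometric test treats samples as exchangeable; spatial or
  temporal autocorrelation between samples would inflate significance.
* The permutation-importance p-value of 0 under the raw-proportion rule
  is a floor of 1/B in resolution; BH on such p-values is conservative
  only up to that floor.
* Patristic distances are consumed, not inferred; errors in the input
  tree propagate directly into the pair model.
* The logistic model treats genome pairs as independent observations,
  although each genome appears in many pairs; genome-level random
  effects are out of scope here.
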