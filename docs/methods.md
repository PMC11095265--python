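# Methods

This note documents the models and procedures `flagmet` implements, the
parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the numerical conventions used throughout.

## Gene panel selection

Gene copy counts are binarized to presence/absence (1 iff count > 0).
Per gene family, prevalence is the fraction of genomes of each phenotype
class carrying the gene. A gene is retained when

* prevalence among motile genomes **>** `min_prevalence_motile`
  (default 0.80), and
* prevalence among nonmotile genomes is **not >**
  `max_prevalence_nonmotile` (default 0.50).

Boundary semantics are strict on the motile side (a gene at exactly 0.80
is rejected) and inclusive on the nonmotile side (exactly 0.50 is kept),
matching the wording of the criteria; `strict=False` relaxes the motile
side to ≥. Selection may be restricted to a user-supplied candidate pool
(e.g. the flagellar-assembly families); the biological candidate list is
an input, not something the package decides. Selection is monotone in
both thresholds, and the test suite checks it against a brute-force
per-gene oracle on random matrices.

## Genome classifier

A gradient-boosted ensemble of regression trees with a binary logistic
objective (xgboost) over the panel's presence/absence features, with
motile encoded as 1.

* **Split.** 70:30 train/test, stratified by class (the training cohorts
  this method targets are imbalanced roughly 1:2, so stratification keeps
  per-class train fractions within one genome of the global fraction).
  Train size is floor(0.7·n); e.g. 1225 genomes split 857/368.
* **Boosting rounds** are chosen by k-fold cross-validation (default
  k = 5) as the round minimizing mean held-out log loss, with early
  stopping after 20 non-improving rounds.
* **Hyperparameters.** Defaults: learning rate 0.1, max depth 4,
  min child weight 1, subsample and column subsample 1.0, split-loss
  penalty (gamma) 0. Optional Bayesian optimization searches
  learning_rate ∈ [0.01, 0.3] (log scale), depth ∈ [2, 8],
  min_child_weight ∈ [1, 10], subsample and column subsample ∈ [0.5, 1],
  gamma ∈ [0, 5], budget 30 evaluations scored by CV log loss. The
  default point is always evaluated first, so tuning can never select
  something worse than the defaults on the same folds; a Matern-5/2
  Gaussian-process surrogate with expected improvement drives the search
  after an exploration phase (pure random search below 8 evaluations).
* **Decision rule.** Label motile iff probability > 0.5; a probability of
  exactly 0.5 goes to nonmotile. No threshold calibration is attempted.
* **Importance** is total loss-reduction (gain) per feature, normalized
  to sum to one over features with nonzero gain.
* **Evaluation** reports accuracy, sensitivity (motile recall) and
  specificity (nonmotile recall) from the confusion counts.

Everything is deterministic under the split seed (single-threaded
xgboost with a fixed seed).

## Community quantification

Translated-search hits (standard 12-column tabular) are filtered with
remove-strictly-below / strictly-above semantics: keep a hit iff
bit score ≥ 50, percent identity ≥ 60, e-value ≤ 0.001, and the read is
longer than 100 bp (a 100-bp read is removed; boundary-equal hits on the
other three rules are kept). Hits are then deduplicated to one best hit
per read (highest bit score, then lowest e-value, then lexicographic
protein id) before tallying — counting all hits would double-count genes
with many protein variants.

Per gene family: hit count is the number of reads whose best hit is any
variant of the family; gene length is 3 × median variant amino-acid
length, in kb; RPK = count / length_kb. The gene-set median is taken over
**all** families of the set, including zero-count ones, so the flagellar
(21-family) and marker (120-family) medians have fixed denominators and
the index scale is stable across samples. An even-sized set takes the
mean of the two central values.

The motility index is the flagellar median RPK divided by the marker
median RPK; a zero marker median raises an "insufficient marker signal"
error rather than returning a value, since a metagenome without
single-copy marker coverage cannot be normalized. The percent estimate is
slope × index + intercept with the distributed coefficients
(3650, −0.321) by default. Estimates are deliberately **not** clamped —
the intercept implies slightly negative values near index 0, and
preserving them keeps downstream averaging unbiased; clamping to
[0, 100] is opt-in and logged.

`fit_calibration` is ordinary least squares of true percent on index,
reporting Pearson r and the point count. Two points interpolate exactly
and report r = 1.0 with a warning.

## Mock metagenomes (what the simulator emulates)

The generator builds a shared protein registry (120 single-copy marker
families, 21 flagellar families; gene nucleotide lengths uniform on
300–1800 nt, shared between roles so the two sets' RPK medians are
comparable), then lays out genomes: every marker family exactly once per
genome, flagellar families present iff the genome is motile (optional
dropout/contamination rates perturb this), genes reverse-translated with
random synonymous codons, placed on random strands and separated by
random intergenic spacers of 50–200 nt.

Reads are uniform 150-bp single-end fragments at 0.5× fold-coverage — the
coverage regime of typical soil metagenomes — with reverse-complementing
probability 0.5, optional uniform substitution errors (default 0) and
constant phred+33 qualities. The read count for a member genome is
floor(abundance × total member length × coverage / read length), so an
equal-abundance mixture sequences every member at the stated
fold-coverage. A gradient design places mixtures at evenly spaced
flagellated proportions from 0 to 1 (default 14 points): motile pool
members share abundance p equally, nonmotile members share 1 − p.

The naive annotator translates each read in six frames and anchors
ungapped alignments with exact 7-aa seeds, scoring the full read/protein
overlap on the seed diagonal. Its bit score (2 × matched aa) and e-value
(10^(−matched aa / 2)) are surrogates, **not** BLOSUM-based statistics;
with the default filters a read must match ≥ 25 aa (75 bp in frame) to
survive. Real-data runs must use genuine translated-search output read
through `flagmet.io`.

What the simulator does **not** emulate: quality-dependent or indel
sequencing error, paired-end reads, genome-size variation at the Mb
scale, inter-species sequence homology (registry proteins are random, so
cross-family hits are essentially absent), horizontal transfer, and
partial flagellar operons. Passing calibration tests therefore
demonstrates the internal consistency and linearity of the index
machinery under its stated assumptions, not performance on real soil
communities — that depends on the reference database and aligner used
upstream.

Problem sizes: the regenerated calibration experiment uses a pool of 20
genomes (10 motile, 10 nonmotile) and 14 gradient points, the scale at
which the index–truth correlation is routinely ≥ 0.99 and the
self-consistency error of a refitted curve is 2–4 percentage points.

The genome-tier generator (`rule_labeled_gene_matrix`) produces binary
matrices whose labels follow a known rule (motile iff ≥ 15 of 21 panel
genes present). Per-genome gene carriage is bimodal — half the genomes
gene-rich (Beta(24, 2); motile-style, nearly complete panels, consistent
with per-gene prevalence > 80% among motile taxa), half gene-poor
(Beta(2, 8)), whose upper tail yields the hard cases: nonmotile-style
genomes conserving most flagellar genes. This gives roughly balanced
classes (so a label-permutation control lands near 50% accuracy) and a
small boundary population that keeps the classification task non-trivial.

## Phylogenetic D

For a binary trait on a rooted tree, tip values are propagated to
internal nodes by averaging the two children, and the observed statistic
d_obs is the sum over internal nodes of |difference between the two
children| (the sister-clade difference sum). Polytomies are resolved
arbitrarily to binary with zero-length branches first; d_obs does not
depend on branch lengths or tip order.

Two nulls, each simulated `n_sims` times (default 1000, minimum 100):

* **random** — trait values permuted across tips;
* **Brownian** — Brownian motion along branch lengths (missing lengths
  default to 1), thresholded by rank so each simulated trait has exactly
  the observed number of ones.

D = (d_obs − mean_brownian) / (mean_random − mean_brownian): ≈ 1 for
phylogenetically random traits, ≈ 0 for Brownian-like conservatism,
negative for stronger-than-Brownian clumping. Two one-sided empirical
p-values are reported rather than combined: p_random = P(d_random ≤
d_obs) (small ⇒ more conserved than random) and p_brownian =
P(d_brownian ≥ d_obs) (small ⇒ more overdispersed than Brownian), both
with the add-one estimator. D is invariant to uniform branch-length
scaling by construction. Calibration on simulated birth–death trees
(64 tips) puts the mean D of permuted traits within ±0.1 of 1 and of
Brownian-threshold traits within ±0.1 of 0.

## Rank conservation and enrichment

Rank conservation: per taxon with ≥ 2 genomes at a rank
(phylum … genus), the sample SD (ddof = 1) of the 0/1 trait; per rank,
the mean of those SDs. Singleton taxa are excluded; ranks absent from the
taxonomy are skipped with a warning.

Enrichment: per-genome category prevalence is category count / total
annotated genes; groups are compared per category with a two-sided
Mann–Whitney U test (scipy's exact method where applicable), reported as
log2(ratio of group means) with Bonferroni adjustment
(min(1, p × n_categories)) and a significance flag at α = 0.01.
Categories absent from both groups are reported as missing; identical
groups report p = 1. The exact p-values are checked against full
permutation enumeration on small inputs.

## Known limitations

* The distributed standard-curve coefficients apply to the reference
  protein database they were fitted with; a registry with different gene
  length distributions or variant counts needs a freshly fitted curve
  (the slope is sensitive to per-gene hit depth, as the synthetic
  gradients make obvious — a one-copy-per-genome synthetic registry
  yields a slope near 100, not 3650).
* The marker-gene normalization assumes a bacterial community; archaeal
  or eukaryotic reads dilute both medians unpredictably.
* The naive annotator is a development and calibration tool, not an
  aligner; sensitivity to diverged homologs is far below a real
  translated search.
* The classifier predicts the genomic *potential* for flagellar
  motility; regulation and conditional expression are out of reach of
  presence/absence features.
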