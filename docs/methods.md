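# Methods

## Scope and model

leafcorr implements a correlation-mapping analysis for a RIL population:
each transcript's abundance in a growth-relevant tissue is treated as a
quantitative variable and correlated with each of ~12 phenotypes over
the ~105 lines (103 RILs + 2 parents). Inference is not per-gene
hypothesis testing but *distributional*: a gene is called
trait-associated when its PCC falls outside either the observed 1 %
tails of the gene-wise PCC distribution ("top 1 %"), or the mean 1 %
tails obtained under trait permutation ("q_random", the
better-than-random criterion). The two stringencies are nested whenever
the observed tail lies outside the permuted one, which is exactly the
signature of real signal.

## Preprocessing

Canonical order: coverage filter → SNP conservation filter →
median-of-ratios size factors → asinh transform → prevalence filter →
CV filter. Each removal is recorded in a provenance log attached to the
expression matrix.

* **Coverage.** A data-driven presence cutoff in the spirit of
  replicate-agreement filtering: candidate cutoffs *s* are scored by the
  mean Jaccard similarity of the binarized (normalized count > *s*)
  presence vectors over within-group sample pairs, and the best *s* is
  applied as "keep genes exceeding *s* in at least one sample".
  Library-size (total-count) normalization is used inside this step
  because it precedes reliable size-factor estimation. A `fixed` mode
  (explicit *s*, default 0) provides determinism.
* **SNP filter.** Keep genes with at most 1.75 % exonic SNP positions
  (inclusive boundary — "no more than"). The SNP percentage is consumed
  as an annotation column; variant calling itself is out of scope.
* **Size factors.** Median-of-ratios: per-gene geometric means over
  samples are computed on genes with all-positive counts; a sample's
  factor is the median ratio to those means. Factors are defined up to a
  common scale; doubling one sample's counts doubles its factor
  *relative* to the others.
* **Transform.** asinh(count/factor): log-like for large counts, defined
  and smooth at zero.
* **Prevalence.** Genes with a nonzero raw count in fewer than 5 % of
  samples are removed (strict "fewer than"; presence is scale-invariant,
  so raw counts suffice).
* **CV filter.** The 5 % least-varying genes by CV = SD/mean of the
  *transformed* values are removed (exactly ⌊0.05·G⌋ genes; undefined-CV
  genes first; ties broken by gene id). CV is computed on the
  transformed scale, where it measures residual relative variability
  after depth removal; computing it on raw counts would mostly rank by
  abundance.

## Phenotype statistics

Per-trait mean/SD/extremes and the spread statistic
(max − min)/max × 100, reported unrounded and rounded. This formula
reproduces 13 of the 14 published integer spreads from the published
extremes; the shoot-dry-weight row (printed 63 vs computed 61.4) was
evidently computed on unrounded extremes and is not targeted. Parental
contrasts use Welch's two-sample t-test on replicate plants (the
degenerate all-equal-variance-zero case returns p = 1 for equal means,
p = 0 otherwise). The trait PCC matrix uses pairwise-complete
observations with t-distribution p-values (df = n − 2); PCA runs on the
centered, unit-variance-scaled complete-case matrix via SVD, with a
deterministic sign convention (largest-magnitude loading positive).

## Correlation stage

* Quantiles are linear-interpolation (type-7) throughout — the shared
  default of R and numpy, kept for cross-environment comparability.
* Permutations: 1,000 per trait by default; one shuffled trait vector is
  shared by all genes per replicate, so the permuted quantile reflects
  the same gene-wise dependence structure as the observed one. Each
  trait has its own stream seeded as (master seed, trait index), so
  adding a trait never changes another trait's thresholds.
* Thresholds are applied with strict inequalities; positive and negative
  sets are disjoint by construction.
* Traits phenotyped on fewer than `min_lines` (default 60) lines are
  excluded from the transcript stage — this operationalizes the
  exclusion of partially phenotyped traits (leaf number and V-stage,
  measured on 42 lines).
* Parents enter as single samples; replicate parental libraries, when
  present, should be collapsed by averaging before this stage.
* The heatmap export z-scores each gene row, clips at ±3 and orders
  columns by ascending trait value (viewer-ready, correlated block above
  the anti-correlated block).

## Network and clustering

Edges connect gene pairs with |r| ≥ 0.6 over all samples: the
absolute-value rule keeps strong anti-correlations, because
anti-correlated gene groups (e.g., genes of opposite trait association)
demonstrably belong in the same co-expression network. The sign is kept
as an edge attribute; MCL weights are |r| since the algorithm needs
non-negative mass.

MCL is implemented from scratch on a dense matrix (adequate to ~3,000
nodes): self-loops at each node's maximum incident weight, column
normalization, then repeated expansion (power 2), inflation (elementwise
power 2.0, renormalize) and pruning (entries < 1e−5 zeroed) until the
iterate changes by less than 1e−8 or 100 iterations (non-convergence
returns the current clustering with a warning flag). Clusters are read
off the limit matrix's attractors; attractors that reach each other
merge; nodes claimed by several clusters go to the largest (ties to the
lowest cluster id); unclaimed nodes become singletons. The algorithm is
deterministic and invariant to node relabeling.

## Enrichment

One-sided over-representation of category labels in a gene set against
the post-filter background, skipping categories with fewer than 5
background members, uncorrected p-values with α = 0.01 (deliberately no
multiple-testing correction: the output is a ranked shortlist for
biological interpretation, not a controlled discovery set). Two tests:
central hypergeometric, and a length-bias-aware Wallenius noncentral
hypergeometric whose odds are the mean bias weight inside vs outside the
category. Bias weights come from 20 equal-count transcript-length bins:
per-bin selected fractions, isotonic-regression smoothing (non-
decreasing in length), a pseudocount floor of half a selection per bin
(the Wallenius odds must stay positive), normalized to mean 1. This
replaces a monotone spline fit with a simpler estimator carrying the
same monotone contract. With uniform weights the Wallenius test reduces
exactly to the hypergeometric (special-cased, since the generic
integral evaluation is not exact to 1e−10 at odds = 1).

## Synthetic populations

The generator emulates the study conditions: 103 RILs + 2 parents;
three Gaussian trait blocks with the published trait means/SDs,
within-block correlations (leaf size 0.55, timing 0.75, shoot 0.70) and
cross-block correlations (+0.30 leaf–timing, +0.25 leaf–shoot, −0.50
timing–shoot) chosen to match the magnitudes of the published trait
correlation matrix; two traits phenotyped on a 42-line subset;
log-normal gene abundances (ln-mean 4.0, ln-SD 1.3, i.e. median ~55
counts), NB dispersion 0.1, 30 % library-size CV; SNP percentages from
a two-component Beta mixture with 25 % of genes above the 1.75 % cutoff
(planted genes always below it, so ground truth survives filtering);
~25 random category labels. The default 5,000 genes keeps test
turnaround fast; the full 15,051-gene scale is a single field.

Expression–trait coupling is injected on the latent NB log-mean
(log μ = b + βz − β²/2 with z the standardized trait), so count noise
attenuates the realized correlation as it would in real data. β is
solved from the target ρ by a root find on a Monte-Carlo-estimated
monotone ρ(β) curve (PCHIP interpolation over a fixed grid, 40,000
latent draws, fixed substream); planted genes share the population
median base abundance so one calibration curve serves all. Targets
beyond the noise ceiling (~0.95 at default settings) raise an error.
Accuracy: mean realized ρ within ±0.05 of target at n ≥ 2,000 over 50
planted genes (tested), within ~0.02 at study n = 105 in expectation.

What the generator does **not** emulate: linkage/eQTL genetics (no
marker map, no genetic relatedness between lines), read-level artifacts,
batch effects, count outliers, or gene–gene correlation beyond what
shared trait coupling induces. Passing tests therefore demonstrate the
statistical machinery under a faithful noise model, not robustness to
every real-data pathology.

## Problem sizes and numerical choices

The test suite and acceptance script run the calibration and recovery
analyses at 5,000 genes × 105 samples × 1,000 permutations (a few
seconds each via standardized-matrix multiplication), with smaller
fixtures (400–2,000 genes) for the unit tests. Under the signal-free
fixture the q_random selection takes 1.5–2.5 % of genes per trait and
the mean permuted q0.99 sits within 0.01 of the analytic t-based null
quantile; with 200 genes planted at ρ = 0.4 the q_random recall
exceeds 0.9 at a false-discovery proportion below 0.5 — both recomputed
by `scripts/acceptance.py` at run time.

## Known limitations

* The coverage filter is a simplified replicate-agreement criterion, not
  a reimplementation of any specific published filter; its outcome on
  real panels will differ in the margin.
* Per-gene inference (FDR-controlled p-values) is deliberately absent;
  the quantile/permutation criterion is the contract.
* MCL's dense implementation scales quadratically in nodes; beyond a few
  thousand trait-associated genes a sparse path would be needed.
* Wallenius p-values rely on scipy's numerical evaluation away from
  odds = 1; extreme odds with large counts can lose precision (clamped
  to (0, 1]).
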