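# Methods

## Problem setting

Given a cluster-annotated single-cell expression matrix and a resource of
known ligand-receptor interactions, the package scores every ordered pair of
clusters (source → target, autocrine pairs included) for every interaction,
producing per-method magnitude and specificity scores, a consensus ranking,
and several evaluations of the predictions. Interactions connect a
*transmitter* entity (ligand side, expressed by the source cluster) to a
*receiver* entity (receptor side, expressed by the target cluster); either
side may be a heteromeric complex of several gene subunits.

## Input processing

Counts are library-normalized to a fixed total per cell (default 10,000)
and transformed with ln(1 + x). All methods consume this single normalized
layer, together with per-(gene, cluster) summaries: the mean of the
normalized values (`mean_log`), the mean of their de-logged values
(`mean_lin`), the fraction of cells with a positive count (`prop`), a
one-vs-rest log2 fold change, a z-score of the cluster means, and a
two-sided Wilcoxon rank-sum p-value of in-cluster vs all other cells.

Numerical conventions:

- **log2FC** = log2((mean_lin_in + 1) / (mean_lin_rest + 1)). The
  pseudocount of 1 keeps the statistic bounded at zero expression; this is
  the convention common to single-cell toolkits.
- **z-scores** are computed across the vector of *cluster means* of a gene
  (sample standard deviation, ddof = 1), not across cells; a gene with
  identical cluster means gets z = 0 in every cluster. This matches the
  cluster-specificity semantics of the scores that consume it.
- **Wilcoxon p-values** use the exact null distribution for small tie-free
  groups and the tie-corrected normal approximation otherwise (SciPy's
  `mannwhitneyu` with automatic method selection). Raw p-values are used for
  the differential-expression filter (no multiplicity correction), exposed
  as `de_p_threshold`.
- **Heteromeric complexes** are reduced to the subunit with the minimum
  `mean_log` in the relevant cluster; `prop` takes the minimum across
  subunits. Ties between equally expressed subunits break lexicographically,
  which cannot change any downstream number. An entity with a subunit absent
  from the matrix is undetected and its interactions are filtered.
- **μ** (the LRscore regularizer) is the mean over all entries of the
  normalized layer, zeros included. The normalized layer (rather than raw
  counts) is used for consistency with every other score.

## Scoring systems

All methods share the expression filter: both entities must be expressed in
at least 10% of the cells of their respective clusters (`prop_threshold`,
inclusive boundary).

- **cellphonedb** — magnitude = (mean_log(ligand, source) +
  mean_log(receptor, target)) / 2. Cluster labels are reshuffled globally
  `n_permutations` times (default 1000) and the one-sided empirical p-value
  is the fraction of permutations whose recomputed magnitude (min-subunit
  rule re-applied per permutation) is at least the observed one. No +1
  smoothing: p = 0/N is attainable, mirroring an empirical null over exactly
  N draws. Specificity = 1 − p.
- **connectome** — requires every subunit of both entities to be
  differentially expressed (Wilcoxon p ≤ 0.05) in its cluster.
  weight_norm = mean_log(l, s) · mean_log(r, t);
  weight_scale = (z(l, s) + z(r, t)) / 2.
- **natmi** — magnitude as the product of means; specificity =
  (mean_log(l, s) / Σ_c mean_log(l, c)) · (mean_log(r, t) / Σ_c
  mean_log(r, c)). The denominators sum over *all* clusters, including
  clusters that fail the expression filter, so each entity's fractions sum
  to exactly 1; a zero denominator yields specificity 0.
- **sca** — LRscore = √(l·r) / (μ + √(l·r)) with l, r the entity cluster
  means; bounded in [0, 1) and exactly 0.5 when √(l·r) = μ. By default rows
  additionally require |log2FC| ≥ 1.5 for both entities and LRscore ≥ 0.5
  (both inclusive, both switchable). Magnitude-only: this method carries no
  cluster-pair specificity score.
- **logfc** — a single score, the mean of the two one-vs-rest log2 fold
  changes.
- **crosstalk** — the product of min-max-scaled PEM and NST components.
  PEM_gc = max(0, log10(S_gc / E_gc)) where S sums normalized expression per
  gene × cluster and E is the independence expectation from S's margins
  (PEM = 0 where S = 0); the pair PEM averages ligand (source) and receptor
  (target) PEMs. NST penalises ligand-receptor co-expression inside the
  source cluster: the mutual information (base 2) of the two genes across
  the source cluster's cells after equal-frequency binning (B = 4 bins,
  reduced with a warning for smaller clusters) is min-max scaled, and
  NST = 1 − minmax(MI) for paracrine pairs. For autocrine pairs the inverse
  transform 1 / (1 − minmax(MI) + ε) is applied and min-max rescaled across
  autocrine rows, so strong within-cluster co-expression *raises* the score
  there. Rows whose ligand or receptor PEM is 0 score exactly 0. The
  concrete binning, the pair-PEM mean and the autocrine transform are this
  package's operationalization; each is isolated behind `MethodConfig` so
  alternatives can be slotted in.

## Consensus (robust rank aggregation)

Each method ranks its surviving predictions by its recommended key
(cellphonedb: ascending p with descending magnitude as tie-break; sca:
descending LRscore; the others: descending specificity), with average-rank
tie handling. Ranks are normalized by the size of the *universe* — the union
of identities scored by any method — and identities a method filtered out
are imputed at the maximum normalized rank, 1. For sorted normalized ranks
r(1) ≤ … ≤ r(K) over K methods, rho = min_k BetaCDF(r(k); k, K − k + 1),
the smallest order-statistic tail probability against a uniform-rank null;
the reported score is min(rho · K, 1) (a Bonferroni-style correction, the
standard form of the published aggregation algorithm). Ties in normalized
ranks are average-ranked before aggregation.

## Overlap and robustness analyses

Top-k sets keep all rows whose rank does not exceed the k-th best rank
(ties included; fractional k rounds up). For cross-run comparison,
identities are (source, target, ligand, receptor) tuples after complex
dissociation, so complex-aware and simple resources share a universe.
Pairwise Jaccard matrices are summarised by the median off-diagonal index
within each group of runs.

Robustness perturbs the inputs over a manipulation grid (0–40%, 5
repetitions) and measures the fraction of each method's unperturbed
top-250 (ties included) recovered afterwards:

- *subsample_cells*: each cluster independently subsampled without
  replacement (floor of 3 cells);
- *shuffle_labels*: a random subset of cells has its labels permuted among
  themselves (cluster sizes preserved; self-assignments possible, so the
  truly mislabeled share is slightly below the nominal fraction);
- *resource corruption*: a fraction of resource records is replaced —
  resource size preserved — by spurious ordered pairs drawn from the 2000
  most variable genes (variance of the normalized layer). *Selective* mode
  never replaces records underlying the baseline top-250 (union over
  methods, so one scoring run serves all methods per perturbation);
  *non-selective* mode replaces uniformly.

Zero-manipulation runs go through the same perturbation path (all three
operations are identity maps at fraction 0); since they are
seed-independent, one run per analysis is computed and reused across
repetitions.

## Agreement with auxiliary modalities

- **Cytokine activities** — per-cluster pseudobulk profiles are
  log2(1 + summed counts), keeping a gene in a cluster's profile only when
  expressed in ≥ 10% of its cells with a summed raw count strictly above 5.
  Each profile is regressed jointly on all cytokine signature columns
  (multivariate linear model with intercept); the activity score is the
  coefficient t-value, FDR-corrected per cluster. A (cytokine, cluster) pair
  is *active* when t > 0 and FDR ≤ 0.05 (inclusive). Predictions are matched
  to cytokines by ligand symbol (an alias table may widen the match); all
  receptors of a matched ligand inherit the call.
- **Spatial colocalization** — pairwise Pearson correlations of per-spot
  cell-type proportions are z-scaled over the global off-diagonal
  distribution; a pair is colocalized at z ≥ 1.645 (inclusive), the
  one-sided 95th normal percentile. Neighborhood-enrichment z-score matrices
  are thresholded at the same value; for an asymmetric matrix an unordered
  pair is positive when either orientation reaches the threshold.
- **Rank-interval odds ratios** — after restricting predictions to keys in
  the calls' universe, each cutoff N (default grid 100–10,000) yields a 2×2
  table of (within top-N) × (positive call); the odds ratio uses a Haldane
  +0.5 correction when any cell is zero (flagged), the p-value is the
  two-sided exact test on the raw counts.
- **Receptor specificity** — protein abundances (CLR transform available as
  a helper) are z-scored per receptor across clusters; positives are
  entries at z ≥ 1.645. Each (receptor, cluster) key receives the maximum
  method specificity among matching predictions (unpredicted keys rank below
  every prediction); AUROC is computed over the full universe and AUPRC as
  the mean over 100 seeded draws with negatives downsampled to the number of
  positives, which pins the chance level at 0.5. (Average precision is
  upward-biased for small positive classes; the chance level is reached to
  within a few percent once the positive class holds a hundred or more
  keys.)

## Synthetic data

The generator emulates a droplet-style experiment: counts are negative
binomial with gene × cluster means and per-cell log-normal library factors
(unit mean, coefficient of variation `library_size_cv`). The default
scenario uses 20 clusters × 100 cells, 2000 genes, baseline mean 0.5,
dispersion θ = 2, and a 30% library-size CV — overdispersed, sparse counts
of the magnitude typical for 10x data. Twenty ligand-receptor pairs are
planted by multiplying the ligand's mean by `effect_size` (default 8) in its
source cluster and the receptor's in its target cluster; a quarter of
receptors are two-subunit complexes with both subunits elevated. The
resource adds 300 decoy interactions drawn from genes untouched by any
planting; the decoy count deliberately dwarfs the 250-interaction
robustness baseline so that selective resource corruption has replacement
capacity at the full 40% manipulation.

Auxiliary modalities carry matching planted structure: colocalized cluster
pairs share a latent factor in the spot proportions; cytokines are named
after planted ligands, with disjoint (orthogonal) 0/1 signature gene sets
whose expression is raised in the designated cluster — the signature matrix
also carries a zero-weight background gene block, without which fully
partitioned indicator signatures would be collinear with the regression
intercept; receptor abundances are elevated for planted receptors in their
target clusters. Note that z-scoring abundance across C clusters bounds a
single elevated entry at z = (C − 1)/√C, so receptor specificity plantings
need C ≥ 7 or so to clear 1.645 reliably.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, gene-gene correlation beyond the planted structure, and realistic
mean-variance trends. Passing recovery tests therefore demonstrates that
the implementations rank strong planted signal correctly under
overdispersed noise — not performance on real tissue.

## Recovery metric

A method's planted-recovery rank is measured against the shared prediction
universe (the union of identities scored by any method), with filtered-out
identities imputed at the maximum rank — the same convention the consensus
uses. This keeps the metric meaningful for heavily filtering methods: the
LRscore filters, for instance, can leave a prediction list consisting
almost entirely of planted rows, making a percentile within the method's
own output degenerate.

## Problem sizes and runtime choices

The default test scenario (2000 genes × 2000 cells, 320 interactions,
1000 permutations) scores all six methods in under half a minute on one
core. The robustness suite runs the shuffle analysis over the full 0–40%
grid with 5 repetitions and anchors the other three analyses at 0%
manipulation; differential expression is computed only for resource genes
when scoring (the full-matrix tables remain available through
`summarize_clusters`).

## Known limitations

- The crosstalk NST/PEM component is an interpretation of a qualitatively
  described score; its binning and autocrine transform are package choices.
- CellChat-style mass-action probabilities with interaction mediators are
  out of scope; externally computed rankings can join the consensus as an
  extra column.
- Gene symbols are normalized (upper-case, stripped) but not alias-mapped;
  curated inputs are assumed.
- Cluster labels are inputs; no clustering, doublet removal or integration
  is performed.
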