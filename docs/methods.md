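# Methods

## The quantities computed

**Growth Correlation Index (GCI).** For gene *g* with log-scale expression
x_gc across conditions *c* and per-condition growth rates μ_c (1/hr), GCI_g
is the Pearson correlation r(x_g·, μ). It is invariant under affine
rescaling of either side, bounded in [−1, 1], and undefined (flagged, not
silently dropped) when a gene's expression has zero variance or fewer than
three complete expression/growth pairs exist. Missing expression values are
handled pairwise-complete, with the number of pairs recorded per gene.

**Permutation null.** For each gene independently, the growth vector is
shuffled once (seeded) and r recomputed, giving one null GCI per gene.
Shuffling one side of the pairing is distributionally equivalent to
shuffling both; shuffling both with the *same* permutation would reproduce
the observed r, which is why exactly one side is permuted. A
multi-permutation variant (`n_permutations > 1`) is available when a
per-gene standard error is wanted. The mode of the observed GCI
distribution is estimated as the centre of the fullest Freedman–Diaconis
histogram bin; no kernel bandwidth needs to be chosen and the estimate is
deterministic.

**Codon usage bias.** CUB scores are geometric means of per-codon weights,
exp(mean ln w), with weights supplied as a two-column TSV and normalized to
max 1 on load (both CAI and tAI are defined relative to the optimal
codon). Policy choices, each behind a switch:

* CAI excludes stop codons always, and the single-codon families ATG/TGG
  by default (`exclude_single_codon_families=True`) — they carry no
  synonymous information.
* tAI replaces zero weights (codons with no matching tRNA) by the
  geometric mean of the non-zero weights before scoring, the standard
  convention; with the policy off, a zero-weight codon is an error.
* Codons containing ambiguous bases are skipped with a warning rather than
  failing the gene; real GenBank records contain them.

**CDS extraction and filtering.** CDS features are taken from GenBank
annotation; minus-strand features are reverse-complemented and joined
features spliced in annotation order, with 1-based inclusive source
intervals retained. The quality filter keeps a CDS iff its length is
divisible by 3, equals the summed annotated interval lengths (catching
malformed joins), and is at most 5× the median length of the full input
set — the median is computed before any removal, so the threshold does not
drift as entries are discarded.

**Condition-level analyses.** All-by-all condition correlation uses
Pearson on the stored log scale (pairwise-complete over genes); duplicate
*detection* uses Spearman, because rank correlation equal to 1 catches
duplicates that differ by a monotone transform, and an experimental
duplicate is implausible at ρ = 1 exactly. The duplicate policy defaults to
dropping *both* members of a flagged pair: when two columns carry identical
measurements but different recorded growth rates, neither can be trusted.
Per-condition predictivity is the squared Pearson correlation between
per-gene log expression and the CUB score over the gene intersection of
the two inputs (a rank-based variant is available); the growth trend on
those R² values is a two-sided Spearman test, hence invariant under any
strictly monotone transform of the growth rates.

**Condition pruning.** To build a maximally distinct condition subset, the
all-by-all Spearman matrix is recomputed each iteration, the maximum
off-diagonal pair located (ties broken by lowest column-index pair), and
one member removed by a seeded coin flip, until the target count remains.
The maximum off-diagonal correlation is non-increasing across iterations
(each step only deletes pairs), which the tests assert. The removal order
is returned as a log DataFrame.

**Nested models.** The four OLS fits share one listwise-complete gene set
so adjusted R² values are comparable; adjusted R² is
1 − (1 − R²)(n − 1)/(n − p − 1) with p the number of predictor terms (the
interaction counts as one). Predictors are left unstandardized so
coefficients stay in interpretable units; the overall F-test p-value and
per-coefficient t-tests are both emitted. The linear-vs-quadratic check on
the CUB–GCI relationship is implemented as an AIC comparison — a
reinterpretation chosen here because an information criterion gives a
single defensible decision rule for a model-form question.

**Gene sets.** Group comparisons use the pooled-variance Student t-test
(Welch behind a flag). ORA is a one-sided hypergeometric test per term over
the universe of genes with defined GCI that appear in the term mapping
(configurable), BH-adjusted across all tested terms, then filtered by the
dual threshold p ≤ 0.04 and q ≤ 0.05. Odds ratios use the cross-product
(a·d)/(b·c) with a Haldane 0.5 correction when any cell is zero (flagged in
the output); ranking takes the k = 15 largest ORs with ties broken by
ascending p then term id. The term mapping is treated as pre-propagated
input: no GO-DAG ancestor closure is performed.

## The synthetic generator

The generator emulates a microbial expression compendium with growth-rate
metadata:

    x_gc = baseline_g + b_g · μ_c + ε_gc,   ε ~ N(0, noise_sd²)

* Growth rates are uniform on `growth_range`, default (0.05, 1.5) /hr — a
  broad laboratory range from slow chemostat growth to rich-media doubling.
* Slopes b_g come from a two-component mixture: sign positive with
  probability `slope_mix` (default 0.25 — a minority of genes, e.g.
  ribosomal proteins, rise with growth), magnitude |N(`slope_mode`,
  `slope_scale`)| (defaults 0.3, 0.3 log units per 1/hr). With the default
  noise (`noise_sd` = 0.4 log units) this places the mode of the implied
  GCI distribution near −0.3, the typical shape for a transcriptome
  compendium: negative mode, long positive minority tail.
* Baselines are N(`baseline_mean`, `baseline_sd`) on the log scale
  (lognormal abundance). Because mean expression = baseline + b_g·mean(μ),
  genes with positive slopes are also somewhat more abundant on average,
  reproducing the weak positive GCI–mean-expression correlation seen in
  real compendia without an explicit coupling term.
* Replicate columns share their condition's growth rate and differ only in
  noise, exercising the replicate-averaging path.

The implied ("theoretical") GCI under this model is

    GCI_g = b_g·sd(μ) / sqrt(b_g²·var(μ) + noise_sd²)

computed with the sample variance of the drawn growth rates; at
noise_sd = 0 it degenerates to sign(b_g), which the empirical GCI matches
exactly. Coding sequences are generated with a per-gene coupling
β_g = β_max·(GCI_theoretical + 1)/2 ≥ 0: each position draws an amino acid
uniformly and then a synonymous codon with probability ∝ w^β (computed in
log space, so β → ∞ cleanly selects only optimal codons and β = 0 is
uniform within family). Labelings and term mappings with planted structure
are generated the same way for the gene-set stages.

**What the generator does not emulate:** mechanistic
transcription/translation dynamics, tRNA-pool regulation,
condition-dependent noise, batch structure, and correlated gene modules
(all genes are conditionally independent given μ). Passing tests therefore
demonstrate that the estimators recover the linear-response structure they
target — not that real compendia satisfy that structure.

## Numerical and design choices

* Absolute-abundance normalization is 6 + log_base(a/Σa) with base 10 by
  default, matching the identity 6 + log10(a/Σa) = log10(TPM); zeros are
  replaced by the global (whole-table) smallest non-zero value before the
  column sums are taken. The transform is invariant to rescaling a column
  by a positive constant.
* Replicate averaging is an arithmetic mean on the stored log scale
  (i.e. after normalization), for both expression and growth.
* Condition filters: growth missing or ≤ 0 drops the condition; alignment
  score strictly below the threshold (default 80) drops it — a score of
  exactly 80 is retained.
* Spearman-duplicate tolerance is 1 − ρ ≤ 1e−12.
* BH adjustment is delegated to statsmodels' `fdr_bh` and cross-checked in
  the tests against an independent step-up implementation.
* All stochastic steps (generator, pruning coin flips, permutation null)
  take explicit integer seeds; the pipeline derives stage seeds as fixed
  offsets from the config seed, and reruns are byte-identical (asserted on
  output checksums).

## Problem sizes

The test suite and the acceptance script run the generator at up to 5000
genes × 100 conditions; the full pipeline example uses 1000 genes across
100 conditions with duplicate replicates. These sizes put Monte Carlo error
well below the assertion tolerances (e.g. GCI recovery error scales as
1/√n_conditions) while keeping a complete run in seconds on one core.

## Known limitations

* GCI conflates measurement noise with biological growth response; the
  package reports the correlation, not a noise-decomposed estimate.
* The per-condition predictivity R² is computed on the gene intersection
  of the expression matrix and the score table; with sparse score coverage
  the profile can be noisy.
* The ORA assumes the term mapping is already ancestor-propagated; feeding
  leaf-only annotations will understate enrichment of broad terms.
* Real-genome CDS extraction trusts the annotation's `join` order; trans-
  spliced or frame-shifted CDSs (rare in microbial genomes) are filtered
  out by the interval-consistency rule rather than repaired.
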