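# Methods

## Data model and encoding

The pipeline operates on an `n × q` genotype matrix `G` of additive
codes — `G_ij` counts the minor-allele copies of SNP `j` in sample `i`
(0 = major homozygote, 1 = heterozygote, 2 = minor homozygote) — with a
binary phenotype `Y` (1 = case, 0 = control). The minor allele is
oriented per dataset after pooling cases and controls; when a file's
declared ALT/second allele turns out to be the major one, codes are
flipped (`g → 2 − g`) and the allele labels swapped, so `MAF ≤ 0.5`
always holds. Coordinates are 1-based; strand is taken as written.

Marker QC removes SNPs with MAF < 1%, missing rate > 5%, or a
Hardy–Weinberg chi-square (1 df) p-value < 10⁻³. The HWE test is the
asymptotic goodness-of-fit test of observed genotype counts against
`(1−p)², 2p(1−p), p²` and is computed **in controls only**, the standard
GWAS convention: HWE violation in controls flags genotyping artefacts,
while cases may legitimately deviate at associated loci. A config switch
(`filter_mode="association"`) applies the same p-value cutoff to a
genotypic 2×3 chi-square association test instead, for cohorts whose QC
protocol used an association screen. Degenerate (monomorphic) columns
return p = 1: equilibrium cannot be rejected. At the sample sizes this
package targets (thousands), the asymptotic test is adequate and fully
specified; the exact test is deliberately not implemented.

Missing genotypes surviving QC are imputed to the per-SNP modal code
before selection and classification. Both the plug-in information
estimators and the MLP require complete inputs, and the 5% missingness
cap bounds the distortion of modal fill; under the benchmark's 1%
missingness the effect is negligible.

Class balancing randomly downsamples the majority class to exact 50:50
**before** the stratified 70/30 train/test split, so both partitions and
all CV folds inherit the balanced design.

## Information estimators and JMI selection

All information quantities use plug-in (maximum-likelihood) cell
frequencies in bits (base 2). The alphabet is tiny — 3 genotype states ×
2 classes — so with `n` in the hundreds-to-thousands the plug-in bias is
far below the score differences that drive selection, and no bias
correction is applied. The base is irrelevant to the argmax.

A candidate SNP is scored against the selected set `D` by
`JMI(sᵢ) = Σ_{sⱼ∈D} I(sᵢ,sⱼ;Y)`, where the joint relevance
`I(X,S;Y) = I(X;Y|S) + I(S;Y)` rewards candidates that are informative
about `Y` *beyond* each already-chosen SNP — redundant candidates
contribute little conditional information and sink in the ranking. The
criterion sums over all of `D` without normalization; since `|D|` is
common to all candidates in a round, normalization would not change any
pick. The search is greedy forward selection (the standard approach for
this criterion): the first pick maximizes marginal `I(s;Y)`, each later
pick maximizes the accumulated JMI score, and ties break to the lowest
column index for determinism. The implementation updates each
candidate's running sum incrementally — one vectorized contingency pass
per admitted feature — making the trajectory `O(k)` passes over the
matrix; tests verify it against a naive implementation that re-scores
every candidate from scratch each round.

## Stability selection

The training split is partitioned into F = 5 shuffled, label-stratified
folds. For each fold, greedy JMI selection of `per_fold_k` SNPs runs on
the other four groups; the held-out group plays no role in selection.
Selections are recorded in a `q × F` binary indicator matrix, and each
SNP's weight is the fraction of folds selecting it, confining weights to
`{0, 0.2, 0.4, 0.6, 0.8, 1.0}`. The final panel keeps `W_j ≥ a`. The
threshold is a **weak** inequality so that `a = 1` means "selected in
every fold" rather than the empty set. The default `a = 0.6` demands a
majority of folds; `threshold_sweep` supports choosing `a` empirically,
and panel size is non-increasing in `a` by construction.

`per_fold_k` is a required design choice with no universal value: the
shell default of 2,000 suits chip-scale panels (hundreds of thousands of
SNPs); the desk-scale benchmark profile uses 100 on q = 5,000 so that
the threshold operates in the regime where stable signal separates from
fold-to-fold noise.

## The MLP classifier

The classifier is a fully connected feed-forward network implemented in
numpy: input (panel width) → hidden layers → 2-unit softmax head, with
inverted dropout after every hidden layer during training (the dropout
rate is the *drop* probability). A two-unit softmax with cross-entropy
is mathematically equivalent to a single sigmoid unit for binary
outcomes and keeps the output layer literal to the softmax formulation.
Training is plain minibatch backpropagation with a fixed epoch budget —
no early stopping or checkpointing — under one of four optimizers (SGD,
RMSprop, Adam, Nadam, standard update rules, β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁸). Weights initialize from seeded scaled Gaussians (He scaling
for relu, Glorot otherwise); everything downstream of the seed is
deterministic in single-threaded mode. Inputs are the raw {0,1,2} codes
(no standardization): the codes are already commensurate, small, and
centered within one unit of each other, and keeping them raw preserves
the additive dosage interpretation of the first-layer weights.

The default configuration — 5 × 512 tanh units, Adam, 200 epochs,
lr 10⁻³, dropout 0.6, batch 32 — is the best-performing point for
chip-scale panels with ~1,400 training samples. `grid_search` evaluates
an exhaustive Cartesian product over the standard domains (activation ×
optimizer × epochs × learning rate × width × dropout × batch size =
3·4·4·3·4·3·4 = 6,912 points) by mean 3-fold stratified CV accuracy,
ties resolved by enumeration order; reduced subsets of the space are
supported for desk-scale runs. The benchmark profile uses a reduced
2 × 64 network (dropout 0.2, 60 epochs): panels of tens of SNPs and
1,400 training samples cannot support half a million parameters, and the
small network trains in seconds without changing the protocol.

## Evaluation

Confusion-based metrics follow the standard definitions (README). MCC
uses the square-rooted denominator `√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` —
the only form bounded in [−1, 1]. The decision threshold for the
confusion table is 0.5 (configurable). AUC is the rank-based
Mann–Whitney estimator with average ranks, so ties contribute one half;
tests pin it to brute-force pair counting. Any metric with a zero
denominator is reported as undefined together with the reason, never as
a silent NaN or a coerced zero. `evaluate_report` refuses datasets whose
provenance shows participation in selection or training.

## Synthetic cohorts

`synthetic_data` generates case-control cohorts with known ground truth:
per-SNP MAFs drawn uniformly from `maf_range`; genotypes drawn
`Binomial(2, MAF)` (Hardy–Weinberg); optional LD as a copy-with-flip
Markov chain inside fixed-size blocks (SNP `t` copies SNP `t−1` with
probability `1 − ld_flip_prob`) — a deliberately simple dependence model
sufficient to exercise JMI's redundancy handling, not a population-
genetic simulation; disease status drawn from a logistic liability
`logit P(Y=1) = β₀ + Σ_k β_k g_k` over the causal SNPs, centered at the
mean dosage so `β₀ = 0` yields ~50% prevalence; exact case/control
quotas by rejection sampling (cap: 100 × cohort size draws), mirroring a
balanced study design; uniform missingness injected last. One seed fixes
everything, and the returned dataset carries its causal indices.

The benchmark cohort (`default_benchmark_spec`) is 1,000 cases + 1,000
controls × 5,000 independent SNPs, MAF ∈ [0.1, 0.4], 20 causal SNPs at
+0.5 log-odds per minor allele (OR ≈ 1.65 — a deliberately modest,
GWAS-realistic effect), 1% missingness.

**What the generator does not emulate:** population stratification,
relatedness, realistic LD decay, rare variants, epistasis, genotyping
batch effects. Passing benchmarks therefore demonstrates correctness of
the machinery and recovery of additive signal under clean conditions,
not robustness to confounding in real cohorts.

**Discrimination ceiling.** Because labels are random draws from the
liability, the Bayes-optimal AUC is bounded: scoring 200,000 simulated
individuals by their true liability `η = Σ 0.5·g_k` gives AUC ≈ 0.79
under the benchmark conditions. Observed pipeline AUCs (~0.68–0.70 with
the reduced MLP; a logistic model given the true causal SNPs reaches
~0.76) must be read against that ceiling, not against 1.0. The
effects-zeroed null companion lands at chance (AUC ≈ 0.5). Under the
null, the 0.6-stable panel is typically empty — stability selection
suppressing false positives, as designed — so the null run scores the
least stable (any-fold, `a = 0.2`) panel instead.

## Problem sizes and numerical choices

The test and benchmark suites use the cohort sizes above: recall runs
greedy selection at k = 100 over the full 5,000-SNP matrix; end-to-end
runs use five folds × 100 selections and the 2 × 64 MLP; oracle
equivalence uses hundreds of random tables at n ∈ [20, 60] and toys of
q = 6, n = 60 where exhaustive re-scoring is feasible. Cross-entropy
probabilities are clipped at 10⁻¹²; entropy terms use `x log x = 0` at
zero; information estimates are clamped at ≥ 0 (plug-in round-off can
dip a few ulp negative). Argmax ties anywhere break to the lowest index.
One master seed derives all stage seeds by fixed offsets so stages are
individually reproducible.

## Known limitations

- Plug-in MI is biased upward at small `n`; with q in the hundreds of
  thousands and aggressive `per_fold_k`, weakly informative SNPs can
  enter fold selections by chance. The stability threshold is the
  designed mitigation.
- Mode imputation ignores genotype uncertainty and attenuates signal at
  high missingness; the QC cap keeps this second-order.
- The simulator's LD model has no decay structure, and effect sizes are
  purely additive.
- The MLP is CPU-bound numpy; chip-scale panels with the full 5 × 512
  grid search are outside desk-scale budgets.
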