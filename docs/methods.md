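# Methods

`survtopic` predicts individual survival from bulk (or pseudo-bulk)
gene-expression profiles by first compressing the expression matrix into a
small number of "cancer topic" loadings, then fitting a survival model on
those loadings together with clinical covariates. This note documents the
models, the numerical choices, and what the synthetic cohorts used in the
test suite do and do not establish.

## Preprocessing

Expression values (log2 microarray intensities or pre-normalized mRNAseq
values; `log2` is applied on request) are standardized with a **single
global z-score**: one mean and one standard deviation (denominator
`n*p - 1`) over all `n x p` entries. Per-gene scaling would equalize every
gene's variance and destroy the information the next step needs: a gene
whose standardized values never leave the band `[-1, +1]` is considered
uninformative and removed. Clinical covariates are mean-imputed (numeric)
or mode-imputed then one-hot encoded (categorical, one column per observed
level). Everything fitted here — global moments, retained genes, imputation
values, level orders, bin edges — is frozen in a state object and replayed
verbatim on novel patients; a categorical level never seen in training maps
to an all-zero block and a warning.

## Discretized LDA (dLDA)

Topic models require non-negative integer counts, so the standardized
expression is discretized per gene: values inside `(-1, 1)` map to bin 0;
the non-trivial positive values of each gene are split into ten equal-width
bins over their training range (`bin = min(10, 1 + floor((z - min+) /
(delta+/10)))`, top edge inclusive), and symmetrically into bins −1..−10 on
the negative side. At prediction time, values outside the training range
clamp to the nearest extreme bin (±1 below the range, ±10 above); a side
never observed in training maps to ±1. A side with a single training value
(zero width) maps to bin 1.

Two encodings turn signed bins into word counts:

* **Enc_A** — one word per gene, count `|b|` (direction is discarded);
* **Enc_B** — two words per gene, `OVER-⟨gene⟩` and `UNDER-⟨gene⟩`, so +2
  becomes two OVER counts and −3 three UNDER counts.

The topic model is standard LDA fitted by batch variational EM. Topic-word
rows are point parameters initialized at `1/V` plus a seeded jitter
`U[0, 1/V²]`; the document-topic prior is symmetric Dirichlet starting at
`α = 0.1` and re-estimated by safeguarded Newton steps on the bound.
Patient loadings are the normalized variational posterior means
`γ/Σγ` (a `raw` flag exposes the Dirichlet parameters instead);
scale-free proportions make better covariates for the downstream learners.

Numerical choices that mattered in practice:

* the near-uniform initialization is a saddle point of the bound; EM
  escapes it slowly, so convergence is judged at a relative bound change of
  `1e-7` (max 500 iterations) — looser thresholds stop before the topics
  separate;
* α is held fixed for the first 25 iterations: estimated on the
  still-symmetric early loadings it diverges and freezes a degenerate
  solution;
* EM restarts 4 times from different jitters and keeps the best bound —
  on planted corpora the bound reliably distinguishes mixed-topic local
  optima from the separated solution.

Held-out documents are scored with the plug-in predictive log-likelihood
`Σ_v c_v log(θ̄ᵀ β̄[:, v])` (the ELBO proper is used only inside EM). This
is the score with the clean analytic behavior the tests check (a single
word under uniform topics scores `−log V`; an empty document scores 0).

### Choosing the encoding and the number of topics

Five-fold cross-validation (event-stratified, seeded) scores every
(encoding, K) pair by (a) the concordance of a ridge Cox model
(λ = 0.1 for fold-level robustness) on [loadings ⊕ clinical] and (b) the
held-out likelihood. The encoding with the best mean concordance wins.
For that encoding, `K̂` is the likelihood-best K, the candidate set is
every `K ≤ K̂` within one fold-SD of `K̂`'s likelihood, and `K*` is the
**smallest candidate within one fold-SD of the best candidate's
concordance**. The one-SE tolerance is essential: held-out likelihood
keeps creeping upward with superfluous topics, so `K̂` overshoots, and
concordance plateaus at the true dimensionality — an exact argmax would
pick between the true and an inflated K by noise. In-CV LDA fits use
slightly relaxed EM settings (2 restarts, E-step tolerance 1e-4) since
only the ranking matters; the final basis is refitted on all patients at
full polish.

## SuperPC+

PCA (centering only — the data are already on one global scale) on the
full filtered matrix, then each component score is tested against survival
with a univariate Cox fit; the Wald p-value is used (asymptotically
equivalent to the score test, and it reuses the fitting code). The
threshold η is chosen from {5e-4, 5e-3, 5e-2} by cross-validated
concordance of a Cox model on the selected components; component p-values
are computed once on the full training data and only the downstream Cox
fit is cross-validated. If nothing passes, the single best-p component is
kept (with a warning).

## Survival learners

All learners act on the assembled design matrix (clinical ⊕ PC scores ⊕
topic loadings), which is column-standardized with training moments stored
in the bundle (pure conditioning; Cox is scale-equivariant and the MTLR
penalty then treats features symmetrically).

**Cox / ridge Cox.** The log partial likelihood (risk set `y_k ≥ y_i`;
Breslow handling of ties) minus `λ‖W‖²` is maximized by damped Newton to a
gradient norm below 1e-8. Monotone likelihoods (separable data, λ = 0) are
detected and reported with advice to use the ridge. The ridge weight is
chosen from {0.01, 0.1, 1, 10} by cross-validated concordance (ties toward
the larger penalty). Individual curves use the Kalbfleisch-Prentice
baseline: at each distinct event time the survival factor solves
`Σ_{i∈D} e_i/(1 − α^{e_i}) = Σ_{R} e_k` with `e = exp(x'w)` (closed form
for single events, bracketed root-finding for ties); with `w = 0` this is
exactly Kaplan-Meier. `S(t|x) = S0(t)^{exp(x'w)}`.

**MTLR.** `m = floor(√n)` time points at the quantiles `i/(m+1)` of the
observed times (deduplicated). The model scores each of the `m+1` death
intervals with `f(x, k) = Σ_{ℓ>k}(w_ℓ'x + b_ℓ)` and the interval PMF is
the softmax of these scores. Uncensored patients contribute their interval
score minus the log partition function; a patient censored at `c`
contributes the log-sum of the scores of every interval consistent with
death after `c` — the exact marginalization over admissible label vectors,
computed with the same cumulative-score trick as the partition function.
The penalty `(C/2) Σ‖w_j‖²` excludes intercepts; no smoothness coupling
between adjacent time points is added. The objective is convex and
minimized by L-BFGS from `W = 0` (analytic gradient; `ftol` 1e-14); C is
chosen from {0.01, 0.1, 1, 10} by 3-fold cross-validated concordance of
curve-derived risks. Curves are the reverse-cumulative PMF, starting at
probability 1 at `t0 = 0`, and are held at their final value beyond the
last grid point (logged); the **risk score** is the negative area under
the curve up to that point (trapezoidal) — the negative (truncated)
expected survival time.

## Evaluation

**Concordance** follows the strict ordered-pair definition: pairs `(i, j)`
with `i` uncensored and `y_i < y_j` are comparable; a pair counts only if
the earlier death has strictly higher risk; risk ties score 0 by default
(a flag enables the 0.5-credit convention used by most survival packages
for cross-tool comparison).

**D-calibration.** For every uncensored patient the predicted
`P(D ≥ d_i)` is read off the curve (linear interpolation, flat beyond the
grid) and binned into G = 20 equal-width probability bins. Under a
well-calibrated model these values are uniform, so each bin should hold
`N/G` of the `N` deaths. The test statistic is the grouped
Hosmer-Lemeshow form

    HL = Σ_g (E_g − N/G)² / (N·π_g·(1−π_g)),   π_g = 1/G,

referred to chi-square with `G − 2` degrees of freedom; "pass" means
p > 0.05. The grouping terms of this statistic admit more than one reading
(group size vs. expected group count); the package uses the classical one
in which each bin is a binomial over all N deaths — the only reading whose
null distribution actually matches the stated chi-square reference (a
`N/G` group-size reading inflates the statistic G-fold and rejects
everything). Censored patients are excluded; censoring-aware variants are
out of scope.

## Synthetic cohorts

The generator emulates exactly the structure the method assumes: patient
topic proportions `θ ~ Dirichlet(0.3·1_K)`, K sparse topic distributions
over OVER/UNDER words (disjoint active-gene blocks, ~10% of genes per
topic, 70% over-expressed, 2% background mass), Poisson document lengths
(mean 100 words), and survival times with log-hazard
`θ'w_true + clinical'v_true` (topic weights spread over ±2; a weak age and
stage effect) under an exponential (or Weibull) baseline. Censoring is an
independent exponential whose rate is solved numerically so the expected
censored fraction hits the target (0.3 by default). Word counts are
inverted through the direction-aware encoding into z-like values (bin
midpoints plus jitter), leaving a deliberate gap between the trivial band
and the non-trivial magnitudes so that the planted ~85% in-band fraction
survives the pipeline's own re-standardization; real data have no such
gap, and the generator makes no attempt at probe-level noise or count
overdispersion. Passing tests on these cohorts establish that the
machinery recovers planted structure under its own assumptions — not that
those assumptions hold in any particular real cohort.

A second sampler draws death times from a fitted or constructed MTLR
model's own interval PMF (uniform within an interval; the open-ended last
interval uses an exponential tail with the mean grid spacing), which gives
an exact null for the calibration test. Because curves are held flat
beyond the last grid point, deaths in the last interval all receive the
same predicted probability; calibration nulls therefore use models with
negligible last-interval mass.

## Problem sizes in the checks

The acceptance script and heavy tests use: n = 500, p = 200, K_true = 3
cohorts for topic recovery and for the 20 selection replicates over
K ∈ {2, 3, 5} (direction-aware encoding); a train-400 / test-500 split for
the end-to-end comparison; n = 1000 for the Cox coefficient recovery and
censoring calibration; 100 replicates of n = 500 for the calibration null.
These sizes give stable estimates (held-out concordance SE ≈ 0.02) while
keeping a full run in the minutes range.

## Known limitations

* The invariant-gene filter assumes globally comparable scales; data
  normalized per-gene upstream will defeat it.
* dLDA ignores document length differences across patients (total dGEV
  count is not normalized; patients with more extreme profiles effectively
  carry more words).
* The topic count search assumes the concordance plateau marks the true
  dimensionality; on data without survival-relevant topic structure K* is
  driven by noise.
* Cox uses Breslow tie handling only; Efron is out of scope.
* D-calibration here is the uncensored-only variant; under censoring the
  observed deaths skew early, so even a correctly specified model can fail
  it on censored cohorts. Censoring-aware calibration is out of scope.
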