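# Methods

## Quantification model

Expression changes are quantified by the comparative-Ct (ΔΔCt) method.
For target gene *g* and housekeeping gene β-actin, ΔCt = Ct(g) −
Ct(β-actin) within one sample; ΔΔCt = ΔCt(post) − ΔCt(pre) across the
two sampling timepoints (before therapy and one week after it begins);
and the post/pre fold change is 2^(−ΔΔCt). The base-2 exponent assumes
100% amplification efficiency (exact doubling per PCR cycle); the
transform exposes a per-gene `base` hook, but the pipeline fixes it at 2
throughout because the published formula does. A fold below 1 means
expression fell after treatment. Because ΔCt is a within-sample
difference, any constant offset on a sample's Ct values (loading,
threshold placement) cancels — the normalization-invariance property the
test suite checks.

Ct values are accepted within a configurable plausibility window,
default (0, 45] cycles; this is a sanity screen on parsed data, not an
assay rule. Missing or undetermined Ct values are never imputed: the
record is reported unscorable. Technical replicates are an error by
default and averaged under `replicates="mean"`, since the assay
description does not mention them. Gene symbols are matched
case-insensitively after whitespace stripping, with the literature
spelling variants *GBP-1*/*GBP1* and *DEFA/DEFA3*/*DEFA1/DEFA3* mapped
to one canonical symbol each; the defensin pair *DEFA1/DEFA3* is a
single predictor variable.

## Prediction index and boundary

The index is affine in the 16 fold changes, index = β₀ + Σ β_g·fold_g.
Two printed coefficient sets exist, identical except for *IFIT5* (−1.43
in the contribution table, −1.44 in the operational formula); both are
registered, with `formula_text` the default since that is the formula
stated as the operational result. No attempt is made to recover more
than the printed two-decimal precision.

Training is a linear probability model: the dummy-coded response
(good = 0, poor = 1) is regressed by OLS on the fold changes, and the
boundary is the mean of the training dummies ((#poor)/n, kept at full
precision internally and displayed at two decimals — 5/22 → 0.23).
Thresholding the linear index at the dummy mean is only coherent for an
OLS fit, which is why the final coefficients are never taken from the
logistic model (see below). ROC-based thresholding is deliberately not
the default — the original analysis found the ROC curve unsuitable here —
but an AUC diagnostic is available in `evaluation.roc_auc`.

The published classification rule uses strict inequalities on both
sides and leaves an index exactly at the boundary undefined. This
implementation classifies the tie as *poor*: for a test whose purpose is
to trigger closer follow-up, the conservative error is the false alarm.
The rule is configurable (`tie="good"`).

Degenerate training sets (all responses equal) return the constant
model — zero slopes, intercept and boundary equal to the common dummy —
flagged `degenerate=True` rather than raising, so callers can decide.

## Stepwise gene selection

The original selection procedure is reconstructed from its narrative
description, which leaves three things open: the influence statistic,
the stopping policy, and whether the panel size was fixed at 16. The
reconstruction is therefore fully parameterized:

1. **Start** — draw `panel_size` genes (default 16) uniformly at random
   from the candidates, under one explicit integer seed (no global
   random state).
2. **Sweep** — fit a logistic regression of response on the current
   panel's fold changes; replace the minimum-influence gene with a
   candidate not yet used; repeat until every candidate has had one
   chance in the panel (or `max_sweeps`). Evicted genes do not return.
3. **Backward** — drop the minimum-influence gene one at a time down to
   a single gene, recording the AIC of the logistic fit at every panel.

Influence defaults to the largest Wald p-value (the least significant
gene is the least influential — the common stepwise convention);
`abs_z` and `aic_delta` (smallest AIC increase on dropping the gene) are
selectable alternatives. Under complete separation — routine here, since
a strongly informative 16-gene panel separates the classes — the
unpenalized logistic fit diverges, so the fitter falls back to an
L2-penalized Newton solve (ridge α = 1 on slopes, intercept
unpenalized), which keeps the Hessian nonsingular and the Wald
statistics defined; the AIC then uses the unpenalized log-likelihood at
the penalized estimate, and the fallback is flagged per step in the
trace.

The returned panel is the best-AIC panel of exactly `panel_size` genes
among those visited: the procedure's published output was a full-size
panel, and under strong separation a size-free AIC optimum legitimately
collapses to a handful of genes, which contradicts that output. The
global AIC-best panel of any size is always reported alongside
(`aic_best_genes`), and `select="aic"` makes it the return value, so the
alternative reading costs nothing to recompute. The full trace
(step, action, gene, AIC, panel) is part of the result and exportable as
CSV.

## Evaluation

The positive class is *poor* response everywhere: sensitivity =
tp/(actual poor), specificity = tn/(actual good). In the published
validation table the row and column sums coincide (both margins are 7
and 32), so 6/7 is numerically the same whether read column-wise as
sensitivity or row-wise as predictive value; this implementation
computes the column-wise (true sensitivity/specificity) quantities.
Percentages are reported at one decimal, interval bounds at three.

Confidence intervals are Clopper–Pearson exact intervals, computed from
beta quantiles (lower = Beta(α/2; s, n−s+1), upper =
Beta(1−α/2; s+1, n−s), with the s = 0 and s = n endpoints exact at 0
and 1). The original report does not name its CI method; the exact
interval was adopted because it reproduces all four printed bounds at
three decimals, which the test suite verifies against an independent
bisection inversion of the binomial tails (and against statsmodels'
beta-method interval) before anything relies on it. The
severity-stratified report orders strata mild, severe, most severe and
checks that stratum totals sum to the overall count.

## Synthetic-cohort generator

The generator emulates the assumed data-generating structure, not any
real dataset. Per patient: response ~ Bernoulli(poor fraction, default
5/22), severity ~ categorical(17/39, 18/39, 4/39); per gene, a baseline
pre-treatment ΔCt ~ Uniform(−2, 8) cycles. Good responders receive a
mean ΔΔCt of +`effect_ddct` on the 13 down-regulated genes (expression
falls, fold < 1) and −`effect_ddct` on the 3 up-regulated genes; poor
responders and the 14 decoy genes receive zero shift. Ct values are
reconstructed around a housekeeping level of 20 cycles, and Gaussian
noise of sd `ct_noise_sd` is added to every single measurement — noise
lives on the observable, so housekeeping noise propagates into ΔCt
realistically; an observed ΔΔCt then carries noise of sd
2·`ct_noise_sd`. The training/validation pair generator uses exact class
counts (17/5 and 32/7 by default) rather than Bernoulli draws,
mirroring the fixed cohort compositions of the original design.

Parameter defaults and why: `effect_ddct = 1.5` cycles (a ~2.8-fold
change; the real per-gene magnitudes are not printed, and 1–2 cycles is
a typical clearly-detectable qPCR response, large enough that the
qualitative claim — near-perfect discrimination — is reproducible in
silico); `ct_noise_sd = 0.25` cycles (a typical well-run qPCR replicate
sd); effects homogeneous across informative genes (directions are known,
magnitudes are not; a per-gene effect mapping is accepted for harder
recovery tests). A `severity_attenuation` hook can shrink the effect
with severity to mimic the observed accuracy decline in sicker patients;
it defaults to 0 because no such mechanism is stated, only the outcome.

What passing tests on this generator do and do not show: they verify
the pipeline's statistical machinery end to end (a real signal of the
assumed shape is recovered; a null signal is not), but the generator has
independent genes, uniform effect sizes, homoscedastic Gaussian Ct
noise and no batch or assay-efficiency structure, so the measured
sensitivities/specificities say nothing quantitative about real
patients.

## Problem sizes and numerics

The recovery experiments use cohorts of 200 patients (training and
validation) over 20 seeds, and the selection experiment 200 patients
with 30 candidates — sizes at which OLS/logistic fits are numerically
comfortable and sampling noise in the summary statistics is small.
OLS designs are rejected when rank-deficient (naming the collinear
genes) or when n ≤ p. Fold-change and index arithmetic is plain IEEE
double; property tests bound the reconstruction error at 1e-12 (fold
laws), 1e-9 (affinity), and 1e-8 (OLS recovery on exactly-linear data).

## Known limitations

- The stepwise reconstruction cannot replay the original selection: the
  30-gene candidate list and the influence statistic were never
  published. It reproduces the *procedure class*, with every ambiguous
  choice surfaced as configuration.
- The published coefficients are only available at two decimals, and
  the *IFIT5* discrepancy between the two printed sources is left
  unresolved (both variants are provided).
- Whether the printed boundary 0.23 is the rounded 5/22 or a stored
  full-precision value is unknowable from the report; fitted models keep
  full precision and round only for display.
- The 2^(−ΔΔCt) model assumes perfect amplification efficiency; no
  standard-curve or efficiency-corrected variant is implemented.
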