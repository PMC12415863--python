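# Methods

## The modeling problem

An anesthetic bath concentration `C` (nutmeg oil, uL/L) is the single
predictor of six physiological responses in a fish: induction time (IT, s),
recovery time (RT, s), and four hematological endpoints — white blood cell
count (WBC, 10^3/uL), red blood cell count (RBC, 10^6/uL), hemoglobin
(HGB, g/dL) and hematocrit (HCT, %).  Each (species, endpoint) pair gets its
own small feed-forward network

    F_i = g(C * W1_i + theta_i),   i = 1..H
    y   = sum_i F_i * Lw_i + theta_j

with one input neuron, H hidden neurons with transfer function `g`, and a
linear (purelin) output.  `g` is one of purelin (identity), tansig
(hyperbolic tangent sigmoid) or a logistic sigmoid.  The logistic exists in
two dialects in this package: the canonical `logsig` 1/(1+e^-x) and
`logsig_scaled` 2/(1+e^-x).  The scaled form is the formula printed with the
transcribed models (it mirrors tansig's 2/(1+e^...) layout with the inner
factor of 2 dropped); whether that is a deliberate definition or a
typesetting artifact cannot be resolved, so both are implemented: zoo
entries tagged "logsig" evaluate with `logsig_scaled` by default (fidelity
to print) with a switch to the canonical form, while training and the
architecture grid use the canonical `logsig` (comparability with standard
practice).

## Metrics

For actual values `a` and predictions `p` over N cases:

* RMSE = sqrt( sum (a-p)^2 / N ), in native endpoint units.
* MAPE = (100/N) * sum |a-p| / a, with interpretation bands
  <=10% high accuracy, (10,20]% good, (20,50)% acceptable, >=50% misleading.
  The open point at exactly 50% is assigned to "misleading" (conservative).
  MAPE is undefined if any actual value is zero; the package raises rather
  than propagating NaN.
* Two R^2 variants are always reported side by side.  `r2_conventional` is
  the textbook 1 - SS_res/SS_tot.  `r2_prednorm` is
  1 - sum((a-p)^2)/sum(p^2), a variant that appears in some applied ANN
  reports; because its denominator is the raw sum of squared predictions it
  saturates near 1 for any data far from zero and cannot rank models (at
  3% relative error it returns ~0.999 regardless of fit quality, which is
  inconsistent with published tables pairing ~3% MAPE with R^2 ~0.95 —
  those tables evidently used the conventional definition).  Model
  selection therefore uses `r2_conventional`; `r2_prednorm` is reported
  for comparability only.

Degenerate inputs (constant actuals for conventional R^2, all-zero
predictions for the prediction-normalized variant, zero actuals for MAPE)
raise typed errors rather than returning sentinels.

## Training

Gradients are exact analytic backpropagation derivatives of the batch MSE
(activation derivatives: purelin' = 1, tansig' = 1-f^2, logsig' = f(1-f),
logsig_scaled' = f(1-f/2)), verified against central finite differences in
the test suite.  Three update schemes are implemented from scratch:

* **gda** — batch gradient descent with adaptive learning rate.  After each
  epoch: a step that raises the MSE by more than `max_perf_inc` (1.04) is
  discarded and the rate is multiplied by `lr_dec` (0.7); an accepted,
  improving step multiplies it by `lr_inc` (1.05).
* **rp** — resilient backpropagation.  Each parameter carries a private
  step width Delta, grown by `delta_inc` (1.2) while the gradient keeps its
  sign, cut by `delta_dec` (0.5) with retraction of the offending step on a
  sign flip, clipped at `delta_max` (50); updates use only the gradient
  sign: w <- w - sign(g) * Delta.
* **seq** — sequential incremental training: per-sample gradient steps with
  a fixed rate `lr0`, applied in dataset presentation order; one epoch is
  one ordered pass.

The multiplicative factors above are the canonical published defaults for
these algorithms.  `lr0` defaults to 0.05 and `delta0` to 0.07, sized for
data scaled to [0, 1].  Initial weights and biases are drawn uniformly from
[-0.5, 0.5] with a required seed; everything downstream is deterministic,
so a (data, config, seed) triple reproduces a training run bit for bit.

Stopping: `goal_mse` (1e-5 on normalized targets), `max_epochs` (1000),
gradient infinity-norm below `min_grad` (1e-6), or a plateau of 50 epochs
without a relative MSE improvement of at least 1e-6.  The last two exist
because noisy data put the attainable MSE far above `goal_mse`; once a run
reaches its noise floor further epochs change nothing, and stopping there
keeps the full grid search affordable without affecting which cell wins.
No validation-based early stopping is used (none is described for the
original analysis), and there is no regularization.

## Pipeline

Inputs and targets are min-max scaled to [0, 1]; scaling parameters are
computed on the training split only and reused for the test split, so the
held-out fish never influence the fit.  The 30 fish (10 at each of 3 doses)
are split 18/12 *stratified by dose* (6 train + 4 test per dose) with a
seeded shuffle; the source design states only the 18/12 totals, but with a
single input variable an unstratified split can drop a dose level from
training entirely, which would make the fit ill-posed.

The architecture search trains every cell of H in {4..10} x
{purelin, tansig, logsig} x {gda, rp, seq} — the hidden-layer range spans
the architectures the published models use (1-4-1 through 1-10-1) — and
selects the cell with the highest test-split conventional R^2.  "Lowest
overfitting" is operationalized as a tie-break only: among (numerically)
tied cells the smaller |train R^2 - test R^2| gap wins, then the smaller H,
then grid order.  Metrics are computed on denormalized predictions in
native units.

Per-stage randomness (split shuffle, per-cell initialization) is derived
from the single run seed via `numpy.random.SeedSequence(seed, spawn_key)`,
keyed by stage, endpoint and grid-cell index, so one integer reproduces an
entire analysis.

The dose-recommendation step scans a concentration range (default step
1 uL/L) with the fitted IT and RT models and returns the lowest dose whose
predicted induction time is at most 180 s and predicted recovery time at
most 300 s — the standard acceptability criteria for a practical fish
anesthetic.  If no dose qualifies, the IT-minimizing dose is reported with
`constraints_met=False`.

## The model zoo

The 18 published trained networks (3 species x 6 endpoints) are packaged as
a string-exact transcription (`data/zoo_weights.csv`, one row per neuron)
plus metadata (`data/zoo_meta.json`).  The transcription is deliberately
uncorrected; anomalies in the printed tables are preserved and surfaced as
caveats instead of being repaired:

* the common-carp RT block is printed without a label (assigned to RT by
  the narrative architecture statement);
* three HCT blocks are printed under a second "RBC" label (resolved by the
  narrative, which assigns one block to each endpoint);
* the common-carp HCT text says 1-7-1 (and its printed bias header
  theta_8 agrees) but the block has 8 rows — packaged as the 8 printed
  rows with the conflict flagged;
* the rainbow-trout IT block skips row i=3 (7 rows vs the stated 1-8-1) —
  packaged as the 7 printed neurons, with no invented 8th;
* the rainbow-trout HGB block prints rows 8 and 9 identically;
* "trainsgd" (carp RBC) is recorded as traingda, which is how the
  narrative expands it.

The input scale of the printed weights is unverifiable: the narrative
states [0, 1] normalization, but bias magnitudes like 124.454 and -2718.79
are implausible for normalized inputs.  Every entry is tagged
`input_scale="unverified"`; `zoo_predict` defaults to feeding the raw
concentration in uL/L, offers `normalized01` as an explicit alternative,
and tags every prediction with the scale used.  Zoo outputs are faithful
evaluations of the published weights, not validated predictions.

## Synthetic data generator

The original per-fish measurements were never deposited, so the generator
emulates the study design: per species, 10 fish at each of the 3 tested
concentrations (carp 800/1200/1400, sturgeon 500/750/1000, trout
400/600/800 uL/L).  Each endpoint has a deterministic mean curve —
power decay `m(c) = baseline * (c/c_lo)^-gamma` for IT, linear increase
`m(c) = baseline * (1 + s*(c-c_lo)/(c_hi-c_lo))` for the rest — times
unit-mean multiplicative lognormal noise with coefficient of variation
0.03.  Non-positive draws are redrawn from the same seeded stream (at CV
0.03 this essentially never happens).

Defaults (documented constants, chosen once): baselines are round,
species-plausible values at the lowest dose (e.g. carp IT 160 s, RT 180 s,
WBC 120, RBC 1.4, HGB 8, HCT 30); IT decays to ~55-60% of baseline at the
top dose and RT rises 45-50%, keeping top-dose means inside the 180 s /
300 s acceptability limits; WBC rises 40% (acute stress leukocytosis) and
RBC/HGB/HCT rise 30% (catecholamine-driven splenic release and
hemoconcentration).  The hematology magnitudes are at the strong end of
the plausible acute-stress range by design: with concentration the only
predictor, held-out R^2 is bounded by the between-dose share of variance,
and reproducing the reported regime (testing R^2 >= ~0.92 alongside 2-6%
MAPE) at CV 0.03 requires the between-dose spread to be roughly 3.5x the
within-dose noise.  A generator with the same noise but ~8% hematology
shifts would cap attainable R^2 near 0.5 no matter the model.

What passing on this generator shows — and what it does not: the pipeline
recovers smooth monotone dose-response curves through 3% multiplicative
noise at n = 30 with the study's split.  Real fish add inter-individual
covariates (size, condition, temperature), measurement error structure and
possible non-monotonicity that the generator deliberately omits, so
synthetic performance is a check of the machinery, not a claim about new
animals.

## Problem sizes and numerics

The packaged analyses run at the study's own scale (30 fish, 18/12 split,
63-cell grid, 1000-epoch cap); the regime summaries aggregate 10 seeds.
Metric comparisons in tests use 1e-9 absolute tolerance or tighter where a
closed form is exact in double precision; gradient checks use central
differences at h = 1e-6 with 1e-5 relative tolerance.  Logistic functions
clip their argument at +-700 before exponentiation to avoid overflow;
training treats a non-finite loss as divergence and reports the epoch.

## Known limitations

* The published per-fish data are unavailable, so published performance
  tables are reproduced as a *regime* on calibrated synthetic data, never
  as point values.
* Single input, single output, one hidden layer only; no cross-validation
  (the source design states the sample is too small) and no uncertainty
  quantification on fitted curves.
* The zoo's input/output scale ambiguity means its absolute predictions
  should not be used operationally; the zoo exists for transcription
  fidelity and forward-pass verification.
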