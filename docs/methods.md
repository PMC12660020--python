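# Methods

## The measurement problem

A classifier trained to reproduce human scores of open-ended test items
is an error-prone measurement channel: the observable automatic score V
relates to the latent trait θ only through the manual score U it tries
to reproduce. Using the manual-score item response model directly on V
misspecifies the measurement model; the size and direction of the
resulting ability bias depend on the balance of false-positive
(ε⁺ = P(V=1|U=0)) and false-negative (ε⁻ = P(V=0|U=1)) classifications.
This package models the channel explicitly and derives the corrected
measurement models for V.

## Model structure and assumptions

The joint model factorizes P(U,V|θ) = P(U|θ)·P(V|U,·) under two
assumptions: (i) the manual score depends only on θ and the item
parameters, and (ii) the automatic score depends on the response only
through the manual score (plus, under the VER model, on θ).

- **CER**: P(V|U) is constant in θ — two rates for dichotomous items, a
  row-stochastic K×K confusion matrix for polytomous ones. The joint
  log-likelihood is additively separable into the manual-score term and
  the classifier term, so the classifier MLE is the per-item table of
  conditional proportions, independent of the IRT model. Marginalizing
  U out of a 2PL manual model yields a 4PL for V with c = ε⁺,
  d = 1 − ε⁻; for a 4PL manual model, c* = ε⁺ + (1 − ε⁺ − ε⁻)c and
  d* = ε⁺ + (1 − ε⁺ − ε⁻)d. These compositions are verified in the test
  suite against brute-force total-probability sums to 1e-12.
- **VER**: ε⁺ and ε⁻ follow logit-linear models in θ. Estimation uses
  fixed-parameter linking: person abilities are held at point estimates
  from the manual-score calibration (EAP by default, any vector
  accepted), turning the error models into manifest per-item,
  per-error-type logistic regressions — the false-positive regression on
  the manually-incorrect subsample, the false-negative regression on the
  manually-correct one. The marginal model for V is the generalized 4PL
  (G4PL), ε⁺(θ)(1−P_U(θ)) + (1−ε⁻(θ))P_U(θ), whose asymptotes vary with
  θ. It need not be monotone, and its Fisher information can locally
  exceed the manual 2PL's: θ-dependent error rates make disagreement
  between scoring methods itself informative about θ. The intercept-only
  VER fit equals the CER rates on the logit scale exactly (the MLE of an
  intercept-only logistic regression is the sample log-odds), which the
  suite asserts.

Item parameters are always taken as known from prior calibration; joint
calibration from data is out of scope, as are polytomous VER models and
multidimensional traits.

## Conditional-independence diagnostic

If ε⁻ is constant in θ, the automatic score splits the manually-correct
responders at random, so the ability distributions of the (U=1,V=1) and
(U=1,V=0) cells coincide; likewise for ε⁺ on the manually-incorrect
side. Each error type is tested with a two-sample Kolmogorov–Smirnov
test at α/2 (two tests per item, holding the item-level cumulative
type-I error at α = 0.05 by Bonferroni). Ability estimates from
identical response patterns tie exactly; the asymptotic KS distribution
with ECDF evaluation tolerant of ties is the default, the exact method
optional for small cells. An empty cell makes that error type
untestable (reported as such, never as a rejection).

## EAP estimation

Posteriors are evaluated by rectangle-rule quadrature on an equally
spaced grid: default 100 nodes on [−6, 6] with a normal prior. Two prior
conventions are supported and configurable: N(0, 1) when the prior
should match a known generating/population distribution (all simulation
work here), and a deliberately wider N(0, 4) for empirical scoring where
inward shrinkage is a concern. The logistic scaling constant D defaults
to 1.0 (logit metric) and may be set to 1.7 for the normal-ogive
approximation. On this grid the EAP integrates exactly as a weighted
sum; doubling the node count moves estimates by less than 1e-4, and the
100-node estimate agrees with a 1e5-node brute-force oracle to better
than 1e-3. EAP reliability is computed as Var(EAP)/(Var(EAP) +
mean(PSD²)) with the sample variance (ddof = 1).

Item information uses the Fisher form I(θ) = P′(θ)²/(P(θ)(1−P(θ))) with
analytic derivatives for 2PL/4PL and central differences (h = 1e-4) for
arbitrary dichotomous response models such as the G4PL; the test-level
SEM is 1/√ΣI. Where the ICC hits machine 0/1 the information is
reported as 0 with a warning.

## Synthetic-data generator

The generator emulates paired human/classifier scoring of a calibrated
dichotomous instrument:

- θ ~ N(0,1), difficulties b ~ N(0,1), discriminations
  a ~ LogNormal(0, 0.25²) — the latter an implementer choice giving a
  realistic spread of slopes (2.5–97.5% range roughly 0.6–1.6).
- Classifier error rates are halved draws from a Beta distribution
  calibrated so the 2.5th/97.5th percentiles of the rates hit
  (0.05, 0.25) in the balanced condition and (0.10, 0.40) for the
  inflated error type of an unbalanced condition (halving caps rates at
  0.5, i.e. no classifier worse than chance on either error type). The
  Beta parameters are found by two-dimensional root-finding on the
  quantile equations to 1e-6; the balanced solution is approximately
  Beta(4.83, 12.68) and the increased one Beta(4.54, 4.54) for the
  doubled rates.
- VER conditions reuse the same rate draws as logit intercepts and add
  slopes ~ N(0, 0.5²), another implementer choice: at one prior SD of
  ability it perturbs the error log-odds by ±0.5, enough to be
  detectable at realistic sample sizes without producing degenerate
  items.
- U is Bernoulli(P_2PL(θ)); V flips U with probability ε⁻ or ε⁺
  evaluated, under VER, at the person's *true* θ.

Deliberately absent from the generator (hence untested against): real
response-text features, rater disagreement on the manual score itself,
item misfit of the 2PL, missing-by-design booklet structures (the
estimation code handles missingness; the default study does not generate
it), and classifier errors correlated across items for a person. Passing
recovery tests therefore demonstrates internal consistency of the
estimators under the stated process, not robustness to those realities.

## Study driver and problem sizes

The full design crosses items {10, 20, 30, 40} × persons
{500, 1000, 2000, 4000} × error balance {balanced, fp_increased,
fn_increased} for each generating process, 100 replicates per cell, with
per-replicate seeds spawned deterministically from (seed, condition,
replicate). Per replicate the driver scores abilities by (i) 2PL EAP on
manual scores, (ii) 2PL EAP on automatic scores (naive baseline),
(iii) marginal-4PL EAP with CER-estimated rates, and (iv) under VER
conditions, G4PL EAP with error regressions fitted at the manual-score
EAP — always with the true (generating) item parameters, isolating
classifier-parameter and ability recovery from item calibration error.
Classifier intercepts are summarized on the logit scale so CER and VER
conditions are comparable; empirical rates of exactly 0 or 1 (possible
in small cells) have no finite logit and are excluded with a count.
Summaries are replicate means with Monte-Carlo standard errors.

The packaged tests and the acceptance script run single cells at
moderate scale (e.g. the 30-item × 2000-person unbalanced cells at 100
replicates, smaller cells elsewhere), which is sufficient for the
qualitative orderings and the bias magnitudes of interest; the full grid
is available through `run_study`/`autoscore-irt run-study`.

## Numerical choices and edge cases

- Error rates entering a marginal 4PL are clamped to
  [1e-6, 1 − 1e-6] so asymptotes never sit exactly at 0/1 and
  log-likelihoods stay finite; raw estimates are reported unclamped.
- A classifier with ε⁺ + ε⁻ ≥ 1 (anti-informative: the implied marginal
  ICC would decrease in θ) triggers a warning at the rate container and
  a hard error at marginal construction.
- Confusion rows with zero observations default to uniform with a
  degenerate flag (strict mode errors); optional add-α smoothing.
- Logistic error-rate fits use plain MLE (statsmodels); on separation or
  nonconvergence — expected where data are sparse at the extremes of the
  ability range — the fit is redone with a weak L2 penalty (1e-4 on the
  slope) and flagged. Error types with fewer than 10 conditioning
  observations fall back to intercept-only with a warning.
- Persons with no observed responses receive the prior mean and prior
  SD, flagged degenerate. Missing entries are handled by pairwise
  deletion per item throughout.
- Bias confidence intervals in estimate comparison use the
  paired-mean normal approximation (±1.96·SD/√n).

## Known limitations

The VER fits are sensitive to influential observations in sparse
ability regions — the penalized fallback bounds but does not remove
this. Reliable VER classifier-parameter recovery needs roughly 1000+
persons per item in our own study runs; the CER model is far less
demanding. The G4PL inherits no monotonicity guarantee, so
information-based item diagnostics should be read pointwise. No
polytomous marginal beyond the confusion-matrix form is provided, and
the framework treats manual scores as error-free ground truth — rater
error is a separate problem.
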