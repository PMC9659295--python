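# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `healthlit`, in the spirit of the model documentation
that simulation and statistics packages ship alongside their APIs.

## Scores and levels

Responses are coded 1 = "very difficult" … 4 = "very easy"; any other value
(including blanks) is treated as missing and counted in a logged warning.
Both summary scores require valid responses on at least 80% of the items
(10 of 12 for the short form), otherwise score and level are missing.

The type D score is the percentage of validly answered items rated 3 or 4.
The type P score rescales the item sum to 0–100; for incomplete rows (but
above the validity threshold) the equivalent mean-based form
`100·(mean − 1)/3` is used, because a sum-based rescaling is undefined when
items are missing.  Level percentages for the D-rules are likewise computed
over valid items, mirroring the D score's denominator.

Cut-offs are applied as the printed decimals (50, 8.334, 83.33, 66.67), not
as exact twelfths.  This is the only reading under which 10/12 = 83.333%
clears "> 83.33" and 1/12 = 8.333% stays under "< 8.334", which is exactly
what the prose glosses of the rules require ("at least 10 of 12 easy-type",
"one 'very easy' at the most").  The D-rules are evaluated in the order
excellent → sufficient → inadequate, with problematic as the residual;
the excellent and sufficient conditions genuinely overlap (e.g. twelve
"very easy" answers satisfy both) and excellent takes precedence.  The
enumeration test over all 455 complete category-count profiles pins this
arithmetic down exactly, including the witness pair showing that two
respondents with the same D score (50.0) can land in different levels
(6 easy + 6 difficult → inadequate; 6 very-easy + 6 difficult →
problematic).

## Classical block

Cronbach's α uses listwise-complete cases and n−1 variance denominators.
Polychoric (and, on dichotomized items, tetrachoric) correlations use the
standard two-step estimator: thresholds from inverse-normal cumulative
marginals, then per-pair maximum likelihood over bivariate-normal cell
probabilities on pairwise-complete observations, with the estimate capped
at |ρ| ≤ 0.999 to avoid boundary failures on degenerate tables.  Ordinal α
is the standardized-α formula applied to the latent correlation matrix.

The single-factor CFA minimises Σ_{i<j} w_ij (r_ij − λ_iλ_j)² with w = 1
(ULS) or w = the inverse approximate asymptotic variance (1−r²)²/n (DWLS).
SRMSR and the loadings are exact per their formulas.  The test statistic is
a mean-scaled approximation, T = Σ e²/avar with df = k(k−1)/2 − k, and
RMSEA/CFI/TLI are derived from it against the zero-correlation baseline;
they can differ in the second decimal from full weighted-least-squares
implementations, so conclusions about fit should rest on the target bands
(SRMSR ≤ 0.08, RMSEA ≤ 0.06, CFI/TLI ≥ 0.95), not on index values to three
decimals.

## IRT block

The PCM is estimated by marginal maximum likelihood EM.  Identification:
latent mean fixed at 0, latent σ estimated (so cross-software comparisons
can shift by a constant only); missing responses drop out of the person's
likelihood factor (ignorable missingness).  The E-step evaluates person
posteriors on Gauss–Hermite nodes scaled by the current σ; the M-step
solves one concave optimisation per item (analytic gradients) and updates
σ² as the mean posterior second moment.  Convergence: largest parameter
change < 1e-5, cap 500 iterations; the marginal log-likelihood is
non-decreasing across iterations (asserted in tests to numerical slack).

Quadrature: 61 nodes by default.  With substantially fewer nodes the
central node spacing exceeds the posterior spread of a 12-item response
pattern and the step-parameter error grows to ~5e-3; at 61 nodes doubling
the grid changes estimates by < 1e-4.  EAP person estimates integrate on
their own 101-node grid for the same reason (error < 1e-6 against dense
grid integration).  WLE solves Warm's bias-corrected score equation
Σ(x−E) + Σμ₃/(2ΣW) = 0 by bracketing and remains finite for extreme
patterns.  Reliabilities: WLE rel = 1 − mean(SE²)/var(θ̂); EAP rel =
var(θ̂)/(var(θ̂) + mean posterior variance).

The dichotomous Rasch model is estimated by conditional maximum likelihood
with elementary symmetric functions (summation algorithm); persons with
extreme raw scores carry no information and are dropped; difficulties are
sum-to-zero normalised, with standard errors from the observed information
of the reduced parameterisation.  Estimation requires well-conditioned
data in Fischer's sense, checked as strong connectivity of the digraph
with an edge i→j whenever someone scored 1 on i and 0 on j; when the check
fails the offending partition is reported.

The nominal categories model anchors category 0 at zero slope/intercept
and fixes the latent scale at N(0,1); an item's categories count as
ordered when estimated slopes increase strictly.  Categories endorsed by
fewer than 1% of respondents make that decision unstable and are flagged
rather than trusted.

The facets DIF model extends the PCM with per-group item shifts
(item + group + item×group), estimated in the same EM; the interaction τ
is identified by double sum-to-zero, so an offset injected into one group
appears as ±offset/2 in the two halves.  Wald tests for τ use empirical
Fisher standard errors (outer products of per-person numerical score
vectors) — the same device supplies standard errors for the PCM steps.

## Diagnostics

Residuals are standardized at the WLE estimates; this choice (rather than
EAP) is fixed and affects third decimals in simulations.  Infit is the
information-weighted mean square with the Wilson–Hilferty cube-root
t-statistic; because the conditional moments are evaluated at estimated
rather than true abilities, null infits sit slightly below 1 at k = 12,
so flags are taken at the elimination thresholds 0.8/1.2 (screening note
at 1.3) rather than at a tight band around 1.  aQ3 centres Yen's Q3 at its
pair mean; MADaQ3 is the mean absolute aQ3; per-pair p-values use a
Fisher-z approximation with Holm adjustment (the reference procedure's
internal choice is undocumented; this one is stated and tested).  The
IRT SRMSR compares observed item-score correlations with correlations
implied by integrating the conditional item moments over the estimated
latent distribution.

The unidimensionality procedure splits items by the sign of their loading
on the first principal component of the standardized residuals (zero
loadings join the positive set), re-estimates WLE persons per subset, and
counts persons with |t| > 1.96 for the difference; the decision uses the
5% criterion or the Agresti–Coull 95% lower bound overlapping 5%.

The global local-independence test compares observed inter-item
correlations with their expectation over binary matrices sharing the
observed row and column margins.  Margins are preserved by curveball
trades (a numba-compiled kernel); single checkerboard swaps at a few
thousand attempts mix far too slowly on a 900×12 matrix and make the test
anti-conservative, whereas the default 20 000 burn-in trades, 2 000 trades
between samples and 300 samples give a measured null rejection rate of
0.045 at α = 0.05 over 200 replications.  The observed matrix is included
in the reference set when computing p.

Because the battery runs many tests, decisions default to α = 0.001
throughout.

## Synthetic data

The generator emulates the structure the validation assumes: PCM responses
on 12 four-category items (default steps: item locations evenly spread on
[−1, 1] logits with steps at location ± 0.7, giving the centred, moderately
spread difficulty layout typical of perceived-difficulty items); a latent
trait with marginal sd 1.0 carrying a social gradient over standardized
covariates (sex 0.0, age −0.10, education +0.25, status +0.20, financial
deprivation −0.30; residual sd derived so the marginal sd matches the
configured value) — no published effect sizes exist for these populations,
so the coefficients are one-time calibration choices producing a gradient
R² ≈ 0.18, in the range typical of social-gradient findings on such
scores; special-literacy scores built to a target correlation with the
trait; and an ordinal self-perceived-health outcome (1 = very good … 5 =
very bad) from a thresholded latent index with health-literacy coefficient
−0.5, so more literate respondents report better health.

Violations are injectable and orthogonal by construction: DIF adds a fixed
logit offset to one item for one covariate group; local dependence copies
one item's response onto another with probability κ; extreme response
style shifts each person's outer steps symmetrically (changing extreme-
category usage without moving the trait — exactly the phenomenon the type
D score is meant to attenuate); missingness is MCAR applied after
generation, so switching it on never changes the underlying draws (each
generation block has its own child random stream).  Reproducibility is
exact under (config, seed).

What passing tests show — and what they do not: the generator draws from
the PCM itself, so recovery and calibration results demonstrate internal
correctness of the estimators and decision rules, not that any real survey
follows the model; real data add mode effects, non-ignorable missingness
and sampling designs the generator deliberately omits.

## Problem sizes

The test suite and the acceptance script use n = 2000 respondents for
recovery and clean-profile checks, n = 5000 for regression-structure
checks, n = 900 with 400 replications for the Andersen LR type-I rate, and
200 replications for the independence-test calibration; these sizes keep
every Monte-Carlo band used in the tests comfortably away from its
threshold while the full battery still runs in minutes on one core.

## Known limitations

- The CFA test statistic is an approximation (see above); only the bands
  are meaningful.
- Polychoric correlations carry no standard errors; downstream CFA
  weighting uses the Pearson-form approximation of the asymptotic variance.
- IRT likelihoods are unweighted; survey weights enter descriptive and
  validity analyses only.
- The facets Wald test is implemented for two groups; multi-group DIF is
  available through Andersen LR splits.
- No survey-design variance corrections: regression standard errors are
  model-based.
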