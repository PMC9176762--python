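# Methods

## The partial credit model and its estimation

The engine implements the unrestricted polytomous Rasch model (partial
credit model, PCM). Item parameters are Andrich thresholds δ_ik — the latent
locations at which adjacent categories k−1 and k of item i are
equiprobable. Estimation is by conditional maximum likelihood (CML): the
likelihood is conditioned on each person's raw total score, which removes
the person parameters exactly and yields consistent threshold estimates.
The conditional likelihood is evaluated through elementary symmetric
functions of the per-item category weights w_i[x] = exp(−Σ_{k≤x} δ_ik),
computed by the numerically stable recursive convolution over items; for
the three GCS items this is exact and cheap (the full pattern space has
only 4·5·6 = 120 cells, which the tests enumerate as an oracle).

Newton iteration is used on the threshold vector. The gradient is
"observed minus expected" cumulative step counts given totals, and the
Hessian is the sum over persons of the conditional covariance matrix of the
step indicators, assembled from one- and two-item-deleted symmetric
functions. The overall location is not identified under CML (the all-ones
direction is a null vector of the Hessian), so the step is taken through
the pseudo-inverse and solutions are centred to mean item location zero,
the usual RUMM-style identification. Convergence is declared at
max|gradient| < 1e-8 (at most 200 iterations, with step halving); if the
line search stalls at machine precision the fit is accepted when the
gradient is below 1e-5. An unobserved category makes its threshold
inestimable and raises a structured error naming item and category —
category collapsing, not imputation, is the intended remedy.

Persons with extreme totals (GCS 3 or 15) contribute nothing to the
conditional likelihood and are excluded from item calibration; the tests
verify that adding extreme rows leaves the estimates unchanged to 1e-7.
Person locations are ML estimates per raw total (a monotone root-find on
the expected-score function), with SE = 1/√(information). Extreme totals
have no finite ML estimate; they are extrapolated by solving for an
effective score ε inside the range (default ε = 0.3 score units,
configurable). The precise extrapolation used by proprietary Rasch software
is unpublished, so with-extremes reliability values are comparable only
qualitatively.

## Fit and reliability diagnostics

Standardized residuals are z_vi = (x_vi − E[X_vi|θ_v]) / √Var(X_vi|θ_v).
Item and person fit residuals apply a Wilson–Hilferty cube-root
standardization to the sum of squared residuals over the contributing
persons (items) — an approximation to the unpublished formula in commercial
Rasch software, with the same sign convention: negative values mean less
observed misfit than the model expects. The item-trait interaction χ² cuts
persons into G equal-count class intervals by estimated location
(deterministic tie-break by person index; G is configurable, default 6,
giving df = 3·(6−1) = 15 for three items) and accumulates
(ΣO − ΣE)²/ΣVar per item × interval cell.

**A structural caveat with three items.** When person locations are
estimated from raw totals, Σ_i E[X_i|θ̂_v] equals the total by
construction, so a person's three residuals sum to exactly zero and
residual variances are conditional-on-total rather than conditional-on-θ.
With only three items this effect is large: on data simulated from the
fitted model, estimated-location fit-residual means are systematically
negative (≈ −4 for items at n=500 on the test geometry) and the χ²
statistic referred to df = I(G−1) runs conservative (type-I rate ≈ 2% at
nominal 5% over 200 replicates). This is a property of the statistic, not
a bug: the same mechanism is visible in the strongly negative fit-residual
means any three-item analysis produces. The test suite therefore verifies
the residual machinery's calibration (means ≈ 0, SDs ≈ 1, z-variance ≈ 1)
against the *known* generating locations, where the standardization is
exact, and verifies the χ² type-I rate under the full pipeline within
Monte-Carlo tolerance of the nominal level. The χ² p-value is not exactly
uniform under the null in any configuration; only the rejection-rate
property is asserted.

PSI = (Var(θ̂) − mean SE²)/Var(θ̂) (sample variances, ddof 1); it can be
negative when error variance exceeds observed spread, which is exactly what
happens when extrapolated extreme-score estimates dominate. Cronbach's α is
the classical k/(k−1)(1 − Σ item var / total var). The four-sample design
re-analyses (1) all non-extreme cases, (2) a random 500 of those, (3) a
random 10% of the full cohort (floor rule) with extremes, and (4) a draw
from sample 3 sized to yield approximately 500 valid cases (the draw size
is 500 divided by sample 3's valid fraction, so its extreme count is an
order of magnitude larger than its valid count).

## Rescoring

Collapse maps are order-preserving surjective recodes merging adjacent
categories only, reflecting the ordinal structure. The published GCS
rescore is reconstructed from the rescored-threshold wording, which pins
every merge: Eye {2,3} ("opening eyes to stimulus, sound or pain"),
Verbal {3,4} ("confused or inappropriate words"), Motor {2,3,4} ("any
movement other than localizing"), giving a 0–8 rescored total. The printed
pre/post coding table is typographically ambiguous about which original
columns align with which rescored codes; the wording-based reconstruction
is treated as authoritative. The candidate enumerator produces every
adjacent-merge map touching at least one disordered threshold pair within a
merge budget; the comparison engine refits each candidate and ranks by
(disorder removed, χ², PSI, fewer merges). Candidates that still leave a
null category are legal inputs and are ranked last with the error recorded.

## The synthetic registry

The generator's defaults are the study conditions: 364,355 records, of
which 22,051 are paediatric (age < 18) and 21,101 adult records have an
incomplete GCS, leaving 321,203 complete adults. The complete-adult joint
(Eye × Verbal × Motor) table is *constructed, not sampled*: the all-minimum
and all-maximum cells are fixed at a = 8,000 and b = 264,786 (so the
non-extreme count is exactly 48,417; a is bounded by the Motor-1 marginal
11,072 and the defaults sit mid-feasible-range), the remaining mass is
IPF-fitted to the residual marginals with those two cells as structural
zeros starting from the independence seed, and the continuous fit is
integer-rounded by largest remainder under running per-axis budgets (with a
three-cell exchange repair for the rare forced-forbidden-cell case), which
preserves all three marginals exactly. Records are then materialised by
exact allocation and shuffled.

Demographics: sex ~ Bernoulli(0.559 male); adult ages from a
piecewise-linear quantile function through (0→18, 0.25→44.2, 0.5→62.7,
0.75→80.8, 1→100) years; ISS from a discrete table with quartiles
(9, 9, 17); region probabilities (Head .25, Limbs .30, Chest .18, Spine
.08, Abdomen .05, Multiple .08, Other .04, Face .02) are placeholders kept
configurable, as no injury-profile breakdown is available to calibrate
them. The 30-day mortality model is logistic in the *rescored* GCS total
(slope −0.45 per rescored point) with an additive region offset (+0.5 for
Head), and its intercept is calibrated by bisection so the expected
mortality over the generated complete-adult covariates equals 6.6% within
1e-6; outcomes are then set missing at rate 4.65%, back-derived from the
reported missing-outcome fraction of the modelling dataset. Everything is
deterministic given the seed, and the CSV round-trip is bit-exact (ages are
written at one decimal).

What the fixture does **not** emulate: inter-item association among
non-extreme responses beyond what IPF quasi-independence induces (real
sub-scores are strongly correlated, so real-data α among non-extremes is
much higher than the fixture's), correlation of age/ISS with GCS, injury
mechanisms, or pre-hospital vs emergency-department score provenance.
Passing tests on this fixture therefore demonstrate the *machinery* and the
extreme-score/targeting phenomena, not real-data effect sizes: fit
statistics, Brier values and mortality-by-threshold gradients are
qualitative signatures here, never numeric reproductions.

`GeneratorConfig.scaled(fraction)` rescales every count by largest
remainder while keeping the marginal identities and extreme-cell
feasibility; tests and the demonstration pipeline run at 1–10% scale. The
prediction acceptance experiment runs at one-tenth scale (n ≈ 30,600
modelling cases), a size at which the cross-validated fits are stable and
the comparison is well resolved.

## Prediction experiments

Sub-scores enter the logistic models as 0/1 category indicators plus the
numeric total (the total is then an exact linear combination of the
indicators; the rank-deficiency is handled by a documented tiny-ridge
fallback, penalty 1e-6, which leaves predictions unaffected — plain MLE via
statsmodels is used whenever the design permits). Experiment 2 adds age,
sex, ISS and region additively; the random forest uses nested inner 3-fold
tuning of the tree count by Brier score to avoid optimistic selection.
Models are compared on out-of-fold Brier score with an empirical standard
error (SD of per-case squared errors over √n) and logloss (probabilities
clipped at 1e-15). The Wilcoxon signed-rank test pairs per-case
squared-error differences (zeros dropped, ties mid-ranked; exact null up to
n = 25 without ties, normal approximation with continuity correction
otherwise). Note that case-level pairing at n ~ 3·10⁴ resolves arbitrarily
small systematic differences — two models whose Brier scores differ by
4e-9 can still yield p ≈ 0 — so "equivalence" is assessed by the 2-SE
Brier criterion, with the Wilcoxon p reported alongside; fold-level
differences can be passed to the same test when a coarser pairing is
wanted. The risk-difference analysis counts cases whose predicted risks
differ by more than 2.5/5/10 percentage points (rescored − original, so a
systematic direction is visible) and stratifies the ≥2.5% subset by ISS,
5-year age bin and region.

## Numerical and design notes

- Class-interval count G is a parameter (default 6). Commercial software
  adapts it internally by undocumented rules (visible as alternating
  degrees of freedom in published tables); adaptation is left to the
  caller.
- Sequential, disjoint exclusions (paediatric first, then incomplete GCS)
  are the only accounting under which the printed counts sum.
- A reported summed GCS of 3 or 15 with blank sub-scores is treated as
  complete on CSV input (the breakdown is uniquely inferable) via the
  optional `gcs_total` column.
- The pipeline expands one root seed into per-stage seeds with
  `SeedSequence([root, stage_index])`, so stages rerun in isolation
  reproduce byte-identical outputs.
- Known limitations: no DIF analysis by body region, no formal
  unidimensionality test (underpowered at three items), no entropy-based
  information comparison; the rating-scale-constrained model and missing
  responses inside estimation are out of scope.
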