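# Methods

## Model and estimation

The analysis object is a recursive path model: an observed-variable
structural equation system over eleven analysis variables (five binary
Oxford histology indicators M, E, S, T, C; three clinical mediators
UPE0c, SReGFR0c, MAPc01; two treatment indicators ST, RASB; and the
outcome SLOPE) whose directed edges form a DAG. Because the system is
recursive with uncorrelated equation errors, full-information maximum
likelihood factorizes over equations, and each equation can be estimated
by ordinary least squares of the child on its parents. We estimate on
z-scored data (sample sd, ddof = 1), so the coefficients are standardized
path coefficients; binary variables (including the endogenous ST, RASB,
MAPc01) enter linearly, i.e. the binary-outcome equations are linear
probability models — no probit/logit link is used. The test suite
cross-checks the equation-wise estimates against an independent joint
maximum-likelihood fitter (direct numerical minimization of the ML
discrepancy over Σ(θ)) to 1e-4.

Inference columns use the normal reference: SE from the OLS fit on the
z-scored data, z = SC/SE, two-sided P from the standard normal, and
95% CI = SC ± 1.96·SE. Intercepts are estimated on the raw
(pre-standardization) scale and reported separately; they play no role in
effect decomposition or fit evaluation. The delta-method correction to
standardized-coefficient SEs is second-order at this sample size and is
deliberately not applied, keeping z = SC/SE exact. Per equation we report
ε = 1 − R², the residual variance proportion.

### Derived variables

* eGFR from the Japanese adult equation
  eGFR = 194·sCr⁻¹·⁰⁹⁴·age⁻⁰·²⁸⁷ (×0.739 for women), valid for age ≥ 20;
  younger patients must supply a precomputed eGFR (the pediatric
  creatinine–height formula is not implemented).
* MAP = diastolic + pulse pressure/3; dichotomized at the retained-cohort
  mean with the measure-zero tie (MAP exactly at the mean) coded 0.
* SLOPE = OLS slope of the eGFR series on time in years; at least three
  measurements are required by default (configurable down to two); fewer
  measurements signal a missing outcome.
* UPE0 and √eGFR₀ are centered on retained-cohort means; T and C are
  binarized 0 vs ≥1.

Records are excluded by complete-case analysis: any missing required
variable (histology, UPE0, eGFR₀, MAP, SLOPE, treatment flags) excludes
the record with a single primary reason, in the fixed priority
MESTC > UPE0 > eGFR0 > MAP > SLOPE. Complete-case was chosen over the
alternative "at most one variable missing" reading because every equation
of the system needs complete rows and no imputation is in scope.

### Correlational links

The link between baseline proteinuria and baseline eGFR (and, in the
hypothetical model, MAP) is operationalized as a regression term hosted
in the UPE0c equation — matching the published coefficient-table layout,
where SReGFR0c appears as a predictor inside the UPE0c block — rather
than as a residual covariance. The link is flagged non-traversable: it
contributes to estimation and to the implied covariance, but no effect
route may cross it.

## Pruning

Starting from the hypothetical model (every histology variable pointing
at every mediator and at the outcome; mediators pointing at treatments
and the outcome; 41 directed edges plus 2 links), all terms with
P ≥ α (default 0.1) are removed and the reduced model refit. All nodes
are kept: a variable that loses its route to the outcome (as RASB does)
retains its own equation. The elimination-bias flag records whether the
surviving structure is identical at α = 0.05 and α = 0.1. Pruning is
idempotent at a fixed α by construction.

A note on recovery: with ~23 null terms in the hypothetical model, each
surviving with probability α, and the weakest generating coefficient
(|SC| ≈ 0.07, SE ≈ 0.033) retained with power ≈ 0.7 at n = 946, exact
recovery of the generating edge set in one prune is rare (a few percent
of replicates). The meaningful operating characteristics — mean recall of
generating edges above 0.85 and false retention near the α rate — are
what the simulation tests assert.

## Fit indices

With B the coefficient matrix (correlational terms included), Φ the
sample covariance of the exogenous block, and Ψ the diagonal residual
variances, the implied covariance is Σ = (I−B)⁻¹(Φ ⊕ Ψ)(I−B)⁻ᵀ, computed
in the correlation metric so all indices are invariant to affine
rescaling of inputs. The ML discrepancy F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p
gives χ² = (n−1)·F (Wishart form; the n-multiplier is available as an
option since conventions differ across software). Degrees of freedom
count covariance-structure parameters only: p(p+1)/2 moments minus free
coefficients, residual variances, and exogenous variances/covariances
(the final model: 66 − 20 − 6 − 15 = 25; means are saturated and cancel).
RMSEA = √(max(χ²−df,0)/(df·(n−1))) with a 90% CI by inverting the
noncentral-χ² CDF (Brent root-finding to 1e-10); CFI compares against the
mutual-independence baseline with free variances; SRMSR is the root mean
square of residual correlations over unique elements including the
diagonal (implied variances of endogenous variables are not constrained
to the sample variances; an exclude-diagonal option is provided because
package conventions differ). A model with df ≤ 0 is reported as saturated
(χ² = 0 convention, flagged). Sample-size adequacy uses the
20-observations-per-variable rule over the 19 dummy-level analysis
variables (minimum 380); the covariance model itself has 11 observed
variables.

## Effect decomposition

Routes from a histology variable to SLOPE are enumerated depth-first over
traversable directed edges (deterministic order: direct route first, then
lexicographic by mediators). An indirect effect is the product of the
standardized coefficients along the route; the total effect is the direct
coefficient plus the sum of the indirect products. Two modes:

* `full_enumeration` (default) — every traversable route. On a link-free
  model with uncorrelated sources, the total effect equals the
  implied-covariance simple-regression coefficient of SLOPE on the source
  (path-tracing consistency, verified to 1e-10).
* `as_published` — exactly the eleven route rows of the published
  decomposition table. That listing omits three structurally valid
  routes: T→SReGFR0c→SLOPE (product ≈ +0.122), C→UPE0c→SLOPE (≈ −0.007),
  and S→ST→SLOPE (≈ +0.016), while keeping the structurally analogous
  S→SReGFR0c→SLOPE and M→UPE0c→SLOPE. Whether that is deliberate is not
  stated in the source; the package takes no side — `discrepancy_report`
  itemizes the differences and both modes are first-class.

Reported tables round to 3 decimals; raw values are retained internally
and in the JSON artifacts. Note the published totals sum already-rounded
parts, so a rounded total can differ from the rounding of the raw total
by one step (M: raw −0.0115 → −0.012 vs printed −0.014 + 0.003 = −0.011).

## Synthetic cohorts

The generator's defaults are the published calibration: the 20 published
standardized coefficients, the published marginal prevalences
(M1 29%, E1 35%, S1 74%, T1/T2 18%/4%, C1/C2 38%/1%, ST 64%, RASB 57%)
and clinical moments (eGFR 75.6 ± 28.9 ml/min/1.73 m², UPE0 1.1 ± 2.2 g/d
as a moment-matched lognormal, MAP 90.0 ± 13.7 mmHg, slope
−0.10 ± 0.51 ml/min/1.73 m²/y) at the published cohort size n = 946.

The histology block's joint law is unreported; it is modeled as a
latent Gaussian block with off-diagonal correlation 0.2 (a
mild-dependence calibration choice, tunable), except the S–T entry, which
is pinned at 0.14: with the published coefficients this is the value at
which the implied residual proportion of the SReGFR0c equation equals the
published 0.68. Under this calibration the unit-variance construction
(each endogenous variable's residual variance is 1 minus its
linear-predictor variance, with an infeasibility error when the latter
reaches 1) implies residual proportions 0.930 / 0.680 / 0.887 / 0.898 /
0.826 / 0.953 for MAPc01 / SReGFR0c / UPE0c / ST / RASB / SLOPE, against
published error terms 0.93 / 0.68 / 0.89 / 0.88 / 0.83 / 0.95 — the ST
equation is the one entry sensitive to the unreported histology
inter-correlations.

Modes:

* `standardized_gaussian` — all variables continuous, unit variance; the
  population covariance equals the path-model implied covariance exactly
  (binary endogenous variables are simulated as continuous, matching
  their linear treatment in estimation).
* `threshold_binary` — histology latents thresholded at margin quantiles
  and re-standardized; downstream coefficients attenuate accordingly,
  which is documented behavior rather than corrected for.
* `realistic` — raw patient records: the standardized draws are mapped to
  clinical scales (ordinal T/C by double thresholds, eGFR through the
  √-scale with delta-method moments, lognormal proteinuria, MAP to
  systolic/diastolic via a drawn pulse pressure ~N(45, 8) mmHg, treatment
  flags by prevalence-quantile thresholds), ages drawn N(40, 13) truncated
  to [20, 85] years with creatinine back-solved through the adult eGFR
  equation, and an eGFR series of 4–8 visits over a uniform 24–120 month
  follow-up with N(0, 2.5) measurement noise around the linear trend.

What the synthetic cohorts do **not** emulate: informative censoring and
visit-frequency–outcome dependence, measurement error in histology
scoring (inter-observer variation), secular treatment trends, and any
nonlinearity in the structural relations. Passing tests on these cohorts
therefore validate the estimation, pruning, fit, and decomposition
machinery under the model's own assumptions, not the clinical claims on
real data. The published per-equation coefficient estimates, the printed
fit indices (RMSEA 0.05, CFI 0.93, SRMSR 0.03), and the 1130 → 946
exclusion count are properties of the undeposited patient cohort and are
not reproducible from synthetic data; the simulation checks target the
quantities the generating structure pins down (coefficient recovery
without bias, the SLOPE-equation residual proportion, fit-index
calibration under correct and misspecified structure).

## Numerical choices and problem sizes

Tolerances: z = SC/SE and path-product identities hold to 1e-10/1e-12;
the RMSEA CI inversion is verified against direct noncentral-χ² CDF
evaluation to 1e-6; collinearity is rejected at design condition number
1e8. Simulation studies use 100–500 replicates at n = 946 (coefficient
recovery 200, residual-proportion recovery 500, fit-index calibration
200, pruning operating characteristics 100) — sizes at which Monte Carlo
error is an order of magnitude below the tolerances being asserted.
Convergence checks against population quantities use a single cohort of
n = 10⁵ (max absolute covariance deviation < 0.02).

## Known limitations

Linear-probability treatment of binary endogenous variables (kept for
fidelity to the modeling approach, not statistical preference); no robust
or sandwich standard errors; no latent measurement models; no survival
outcomes; no imputation. The standardization convention behind the
published nonzero intercepts of a standardized solution is not
reconstructable, so intercepts are reported on the raw scale and excluded
from all comparisons.
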