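# Methods

## Model

Weight status is a discrete-time Markov chain on the four CDC BMI
categories (underweight, normal, overweight, obese; indices 0–3), with one
step equal to the ten-year interval separating the two weight reports.
The chain assumes:

- **Time homogeneity** — the decade matrix estimated from one observation
  window is applied to every projected decade.
- **First-order dependence** — the next category depends only on the
  current one (plus covariates in the GBM variant), not on the path.
- **A closed population** — no birth, death, immigration or aging-out
  state; projected prevalences describe the same notional population
  throughout.

These are strong assumptions at multi-decade horizons; the backward and
stationary operations are context devices, not demographic forecasts.

### Categorization

BMI = weight_kg / height_m². Intervals are half-open on the right, so
BMI = 25 is overweight and BMI = 30 is obese; this closes the gap left by
writing the categories as "25 ≤ BMI < 30" and "BMI > 30" and keeps the
four predicates an exact partition. Because surveys record no historical
height, the BMI ten years prior uses the current measured height; a
precomputed past-BMI column can be supplied instead
(`state_pairs(..., past_bmi_column=...)`) where a source has one.

### Inclusion filters

Adults (age ≥ 18, inclusive), both weights and height present, weights
within plausibility bounds (default 20–350 kg, configurable — survey
self-reports contain entry errors but no published threshold exists, so
the bounds are deliberately wide and every exclusion is counted per rule
in application order).

### Estimation

Row-wise multinomial MLE: p̂_ij = c_ij / n_i, optionally with an additive
pseudo-count a: (c_ij + a)/(n_i + 4a) for sparse subgroups (default
a = 0). An origin state with no observations has an undefined row; the
default policy makes it self-absorbing with a logged warning (alternatives:
uniform, error). Subgroup estimation stratifies the same estimator by
covariate levels; subgroups under 50 records are flagged, not dropped.

The published reference matrix is stored as the rounded whole-percent
figures (rows sum to 99–101%). Renormalization (divide each row by its
sum) is a policy flag: off for verbatim reporting and one-step checks —
where the raw products reproduce the printed percentages exactly — and on
for multi-decade projection, where a non-stochastic matrix would leak
probability mass geometrically.

### Projection

Distributions are row vectors; v_{t+1} = v_t P. Backward modeling solves
v_{t-1} P = v_t by LU solve each step. The inverse image of a
distribution need not lie in the simplex, so negative entries are clipped
to zero and the vector renormalized; the clipped mass is recorded per
step and a step clipping more than 5% (configurable) aborts with the
partial trajectory attached. The condition number of P is checked before
inverting. The stationary distribution is computed by power iteration
from uniform (tol 1e-12 on the max entry change, max 10⁶ iterations) and
cross-checkable against the unit-eigenvalue eigenvector; a repeated unit
eigenvalue (reducible chain) sets `unique=False` on the result.

### Covariate-dependent matrices

Participants are grouped by origin state; within each group a multiclass
gradient-boosted tree ensemble (xgboost, `multi:softprob`) predicts the
destination category from covariates. Stacking the four predicted rows
for one covariate profile yields a profile-specific matrix P(x).
Categoricals are one-hot encoded against a fixed vocabulary persisted in
the model archive; in strict mode unseen levels are errors, otherwise
they map to "other" where that level exists. Origin groups missing
destination classes predict zero for them (renormalized); groups with
fewer than two observed destinations fall back to their constant
empirical row, so the four-row contract always holds.

Hyperparameters (all in `GBMParams`): 200 trees, depth 3, learning rate
0.1, `min_child_weight` 10, `gamma` 3.0, single thread, seeded. The
`gamma` (minimum split loss) term is the load-bearing regularizer: without
it, boosting 200 rounds on origin groups of a few thousand records fits
split-noise in uninformative covariates and individual-profile rows can
drift several percentage points from the group rates, while `gamma = 3`
prunes those splits (profile rows track the empirical rows to within ~2
points on effect-free data) yet leaves genuine covariate signal — a
planted age effect on the obesity-transition log-odds — recoverable with
a clear margin. The cost is mild attenuation of true effects, visible in
the validation table as a small bias toward the pooled rates.

When projecting an individual profile over decades, age advances ten
years per step by default and the matrix is re-predicted each decade
(`age_advances=False` gives the static-profile variant; the choice
matters exactly when age carries signal).

**Validation against subgroups.** For each subgroup, the member-averaged
P(x) is compared with the empirical subgroup matrix. Equality is tested
jointly: the max-entry discrepancy is referred to the bootstrap
distribution of replicate max-deviations (95th percentile as the critical
value; the reported p-value is the exceedance fraction). Pointwise
per-cell 95% bands are also reported but are not the criterion — with 16
cells per matrix a pointwise rule rejects spuriously even for an ideal
estimator.

### Bootstrap

Resampling unit: the participant (the paired observation), with
replacement at the original size — preserving the within-patient coupling
of origin and destination. Each replicate re-estimates the matrix and,
for trajectories, the baseline vector from the same resample, then
projects. Intervals are percentile (2.5/97.5 at the default 95% level),
B = 1000 by default. All replicate index streams come from one seeded
generator, drawn in replicate order, so results are reproducible from
(cohort, B, seed) regardless of internal chunking.

## Synthetic data generator

The generator emulates the NHANES 2017–2020 weight-history cohort:
n = 6146; baseline state mix (87, 2058, 1376, 2625)/6146; age normal
58.39 ± 12.94 truncated at 18; 49/51 male/female; race mix White/
Hispanic/Black/Asian/Other = 37/20/27/12/4% (exact published-count
ratios); ground-truth matrix = the renormalized published matrix.
Covariate effects enter as additive shifts on destination log-odds
(multinomial-logit form), per-unit for numeric covariates (default scale:
per decade of age, centered at 58.39) and per-level for categoricals,
optionally restricted to specific origin rows — the minimal planted
structure a classifier can be tested against.

Weights are constructed from BMI: each record draws an origin BMI
uniformly inside its state's band interior (margin 0.2 BMI units; obese
band truncated to [30.2, 45]), and the destination BMI is either drawn
uniformly in the destination band (movers) or perturbed from the origin
BMI by a truncated normal with drift +1.2 and SD 3.2 BMI units (stayers).
Heights are sex-specific normals (1.76/1.62 ± 0.07 m); weight = BMI · h².
Placing weights strictly inside band interiors guarantees that
categorization recovers the intended states for 100% of records.

The drift/SD values were calibrated to the cohort's reported 10-year
weight-change distribution: they reproduce the 61% gained-weight fraction
and approximately the SD (≈14 kg vs 14.97), but the *mean* change
saturates near +1.4 kg (reported: +3.27 kg) because band-interior
placement bounds how far a within-category stayer can move. This is a
known, accepted limitation of label-faithful generation. Other realism
gaps: no measurement error or recall bias in the self-reported past
weight, no survey design (weights, strata), no correlation between
covariates and baseline state unless planted, and lab biomarkers are not
emulated. Passing tests therefore demonstrate correctness of estimation,
projection, uncertainty and effect-recovery machinery under a known
truth — not robustness to the reporting artifacts of real survey data.

## Numerical choices and problem sizes

- Row sums are enforced to 1e-9 after any renormalization; predicted GBM
  rows to 1e-6 (float32 inference).
- Backward clipping tolerance 0.05 total mass per step; stationary
  tolerance 1e-12.
- Simulation-based checks use: n = 10,000 cohorts (uniform origin mix,
  2,500 per origin) for GBM oracle-equivalence and subgroup validation;
  n = 50,000 for ground-truth recovery (max-entry error < 0.015);
  200 repetitions × B = 500 at n = 2000 for bootstrap coverage
  (nominal 95%, observed ≈ 93–95%). The uniform origin mix is used in
  these experiments because under the cohort's own mix the underweight
  origin receives ~1% of records and its binomial noise alone would
  dominate the tolerances; the NHANES-mix generator is exercised
  separately for marginals and label fidelity.
- Ties and degenerate inputs: empty cohorts are errors for estimation
  and baselines but valid (zeroed report) for filtering; B = 1 bootstrap
  gives zero-width bands; an all-self-transition cohort gives constant
  trajectories and bands.

## Known limitations

- Decade resolution is intrinsic: no sub-decade interpolation is offered
  because the chain is identified only at the 10-year interval.
- The ten-decade default horizon extrapolates far beyond a lifespan; it
  characterizes the dynamics of the fitted matrix, not a living cohort.
- Backward modeling is an approximate inverse: any clipping distorts the
  inferred past, which is why distortion is always reported.
- GBM effect estimates are attenuated by regularization; the package
  favors stable rows over unbiased effect magnitudes.
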