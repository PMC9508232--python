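# Methods

## Model and assumptions

The core model is a linear quantitative structure–permeability relationship
(QSPR) in three molecular descriptors:

    logKp = b0 + b1·logP + b2·TPSA + b3·MV + ε,   ε ~ N(0, σ²)

with logKp the base-10 logarithm of the permeability coefficient in cm/s,
logP the octanol–water partition coefficient (dimensionless), TPSA the
topological polar surface area (Å²) and MV the molecular volume (Å³). The
model assumes measurements taken under comparable experimental conditions
share one linear relationship; heterogeneity across conditions is handled by
stratification, not by covariates in the regression.

Stratification uses four experimental variables: skin source (breast,
abdomen, thigh), skin layer (epidermis, dermis, epidermis+dermis, stratum
corneum), donor concentration class (concentrated — covering "neat" and
"saturated" spellings — vs diluted), and donor temperature binned into
20–25, 26–30, 31–35 and 36–40 °C. The cross-product gives 96 scenarios; each
non-empty scenario is fitted independently, with repeat measurements of a
compound kept as separate rows.

## Temperature binning

The printed integer bin labels leave fractional temperatures undefined, so
bins are half-open on the real line: [20, 26) → 20–25, [26, 31) → 26–30,
[31, 36) → 31–35, [36, 41) → 36–40. This makes binning total over [20, 41)
and reproduces the integer labels exactly; temperatures outside [20, 41) are
counted as unassignable rather than forced into a bin.

## Fitting and diagnostics

OLS is solved by a rank-revealing SVD least-squares solve rather than
iterative optimisation; for full-rank designs this is the unique
sum-of-squared-residuals minimiser, and for rank-deficient designs it gives
the deterministic minimum-norm solution with a condition warning (condition
number above 1e10 or rank below 4). A long-hand normal-equations solve and
statsmodels OLS serve as independent oracles in the test suite.

RMSE uses divisor n (population-style root mean square of residuals), chosen
because it is consistent with the reported training-set error of the best
published model (n = 29, R² = 0.8428, RMSE = 0.30); the divisor choice is
isolated in one function.

Fits with n ≤ 4 rows (the published scenario table contains n = 2 and n = 3
entries) are flagged `underdetermined`: coefficients are still produced
(minimum-norm), R² is reported as the degenerate 1.0 when n ≥ 3 and the fit
interpolates, and as missing for n = 2, mirroring how such rows are reported
in the source table. Underdetermined models never qualify for selection.

Because R² = 1 − SSE/SST and the squared Pearson correlation of predictions
with observations coincide only on training data, `evaluate` reports both
conventions; which one a given published test-set value used is not
identifiable, so neither is privileged.

## Model selection and validation

`select_best` considers scenario models with at least `min_n = 16` rows
(the support threshold below which a scenario model is treated as anecdotal)
and returns the one with maximal R², breaking ties toward the earlier
scenario in the fixed enumeration order (sources breast < abdomen < thigh;
layers epidermis < dermis < epidermis+dermis < stratum_corneum;
concentrated < diluted; temperature bins ascending).

Train/test validation draws a random partition with |train| =
round(0.8·n) rounded half up — reproducing the published splits 36 → 29/7
and 214 → 171/43 — and redraws (up to 1000 attempts) until the test set
spans at least 25% of the full data's range in each descriptor. The 25%
spread rule is this package's concrete quantification of "the test set
covers a range of descriptor values"; it is configurable. The model is then
refitted on the training rows only and both sets are scored.

## Pooled workflow

The pooled model uses every compound once. When a compound has several
measurements, each is scored by how many of five preference criteria it
satisfies (skin source abdomen; layer epidermis+dermis; concentrated donor;
donor temperature within 30–35 °C; donor pH within 7–7.5) and the
highest-scoring record wins, ties going to the first in input order. Scoring
rather than hard filtering guarantees exactly one row per compound even when
no record matches all criteria. The pooled temperature window is 30–35 °C as
stated for this selection step, deliberately not identical to the 31–35
stratification bin; both are configurable.

Outlier removal is single-pass: fit on all rows, remove rows with
|observed − predicted| > 1.5 log units, refit once. No iterative re-removal
is performed. Both the full post-filter fit and the training-set fit of the
subsequent split are reported, since either can be quoted as the final
pooled equation.

## Published-model registry

The 27 scenario equations are packaged as a version-controlled CSV
transcription whose SHA-256 is verified at load; the n = 2 row's missing R²
and the n = 3 rows' printed R² = 1 are carried verbatim. The Potts–Guy
baseline (logKp = 0.71 logP − 0.0061 MW − 6.3) is kept in its printed form
with an explicit unit tag: its original publication used cm/h while the rest
of the pipeline is in cm/s, and no silent conversion is ever applied.

## Synthetic data

The generator emulates what the analysis assumes: descriptors uniform over
logP ∈ [−4, 5], TPSA ∈ [0, 160] Å², MV ∈ [50, 500] Å³ (independent by
default — real descriptors are correlated, but independence maximises
identifiability for recovery tests; a Gaussian-copula correlation knob is
available for stress tests), scenario assignment uniform over the configured
scenarios, temperatures uniform within each scenario's bin, and
logKp = truth + N(0, σ). Defaults are 253 compounds with 1–3 records each
(≈ 500 measurements, the scale of the real database), noise σ = 0.3 log
units (the residual scale of the best validated model), and the published
best-model coefficients as the default truth. Planted missingness blanks one
of the four stratification fields on an exact rounded fraction of records;
planted outliers add ±3 log units with random sign; both index sets are
returned as ground truth and are disjoint.

`make_table1_like` reproduces the published table's group structure exactly
(27 scenarios, group sizes 2–45, 342 rows, truth equal to each scenario's
published coefficients) for full-pipeline rehearsals at the real study's
scale.

What passing on synthetic data does not show: real permeability data have
correlated descriptors, non-Gaussian and heteroscedastic errors,
inter-laboratory offsets and uneven compound coverage, so recovery results
here bound what the pipeline can do when its assumptions hold, not what any
real dataset will yield. Because the synthetic descriptors span their full
ranges uniformly, synthetic R² values run higher than typical experimental
ones at the same noise level.

## Numerical choices and problem sizes

Exact-recovery checks use 1e-9 absolute tolerance, dual-oracle agreement
1e-8, residual orthogonality 1e-6 relative. Parameter-recovery checks run
one scenario at n = 500, σ = 0.3 over 20 seeds (median coefficients within 3
standard errors of truth; fitted RMSE in [0.25, 0.35]); the outlier-workflow
check plants 40 gross errors among 253 rows. These sizes make every check
sharp while keeping the full suite fast on a single CPU.

## Known limitations

- Descriptors are inputs; nothing is computed from structures, and no
  applicability-domain estimate is made — predictions extrapolate silently
  outside the descriptor ranges a model was trained on.
- Stratification ignores donor pH (pH enters only the pooled preference
  criteria), acceptor conditions, skin preparation and storage — covariates
  a richer model might use.
- The per-scenario models are independent fits; no partial pooling or
  hierarchical shrinkage is applied, so small-n scenarios are reported but
  flagged rather than stabilised.
- With symmetric planted outliers the pre-filter fit is nearly unbiased, so
  the post-filter refit mainly reduces variance; on a given draw it can land
  slightly farther from the generating coefficients even while residual
  recall of the planted outliers is essentially complete.
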