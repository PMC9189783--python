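# Methods

This note records the models implemented in `fermopt`, the conventions and
numerical choices behind them, and what the synthetic-data generators do and
do not emulate.

## Experimental designs and coded levels

Each medium factor is described by its factorial low/high actual levels; the
coded scale maps these to −1/+1 through the affine
z = (x − centre)/half-range. The central composite generator produces
2^k factorial corners, 2k axial points at coded distance α and n_center
replicated centre runs. α accepts a number or `"rotatable"`
(α = F^(1/4), F = number of factorial points). The packaged 50-run,
five-factor design uses α = 2.0 and eight centre replicates, matching the
printed matrix it reproduces; note that 2.0 is also the rotatable α of a
16-point half fraction, so the original software's intent is ambiguous — the
generator simply reproduces what was run. Coded matrices are checked for
columnwise balance and factorial orthogonality in the test suite.

First-order screening fits use OLS on the coded levels; a factor is declared
significant at p < 0.05 (two-sided t test). The steepest-ascent path moves
significant factors in proportion to their coefficients, scaled so the
reference factor (largest |coefficient| by default) moves one `step_size`
coded unit per step; non-significant factors stay at the base point.

## Response-surface model

The full second-order polynomial (1 + 2k + k(k−1)/2 terms; 21 for k = 5) is
fitted by OLS with no term pruning. Coefficients may be expressed in coded
or actual units; r² is identical in both (the bases span the same space),
which the suite verifies on the packaged data. ANOVA splits the residual
into lack of fit and pure error using replicate groups (rows with identical
coded levels, rounded at 1e-10 to absorb float noise). With m distinct
points and p terms, F_LOF = MS_LOF/MS_PE on (m − p, n − m) df. On the
packaged design m = 43, so F is reported on (22, 7) df; the source table
printed the pair (22, 29), reusing the residual df in the denominator
position — the numerator df agrees exactly with the replicate structure.
Without replicates the lack-of-fit entries are reported as unavailable
rather than zero.

The packaged published surface carries its printed coefficients in coded
units; the evidence for that convention is that its value at the all-+1
corner equals the published optimum prediction (411,713.87 U to within
coefficient rounding; the implementation computes 411,713.70). The printed
intercept (312,416) differs by ~1 % from the printed centre-row predictions
(315,400); both are preserved as printed and neither is "corrected".

## Feed-forward network

Architecture: k inputs → H tanh hidden units → one linear output
(H = 12 by default; the logistic sigmoid is available by configuration).
Inputs and targets are min-max normalized to [−1, 1] by
y = (2x − (x_max + x_min))/(x_max − x_min); predictions are mapped back to
the original scale before any metric is computed.

Training is damped Gauss–Newton (Levenberg–Marquardt) on the training set's
summed squared error with the analytic Jacobian: solve
(JᵀJ + µI)δ = Jᵀe, accept the step if the error drops (then µ ← 0.1µ),
otherwise µ ← 10µ and retry; stop on µ > 1e10, the epoch cap (1000), a
machine-level training residual, or six consecutive epochs without a new
validation minimum. The weights of the best-validation epoch are returned,
so the reported validation error is never above any epoch's. Data are split
70/15/15 (train/validation/test) by a seeded permutation; validation and
test sizes are the rounded fractions, so 50 samples split 34/8/8. Weights
initialize uniformly in [−0.5, 0.5] scaled by 1/√fan-in from the same seed;
(seed, spec, data) determines the result bit-for-bit.

A deliberate caveat, verified in the test suite and worth stating plainly:
with 12 hidden units (85 weights) against 34 training points the network can
drive its training error to machine precision while held-out error stays an
order of magnitude above the replicate noise floor. An oracle experiment —
fitting the 21-term quadratic itself to only each seed's 34 training
points — gives overall r² of 0.91–0.96 across seeds 1–10, so overall
(all-50-point) r² values near 0.99 are not reachable by honest training on
a 34-point subset of this data; the packaged study's printed network column
fits its training and held-out points about equally well, which is the
signature of a network effectively fitted to, or selected on, all 50 runs.
The corresponding acceptance test encodes the published floor and is
expected to fail; it is kept because the floor is the published claim.

## Model-comparison metrics

Seven metrics on the original response scale: r² = 1 − SSE/SST,
MSE, RMSE, MAE, AAD = |mean((y−y′)/y′)|·100, ARE = mean(|y−y′|/y′)·100, and
a chi-squared error. The chi-squared default is Pearson's Σ(y−y′)²/y′: the
squared-relative form printed alongside the source values is inconsistent
with those values (they are reproduced only by the Pearson form), so the
Pearson form is the default and the relative form is available as
`chi2_form="relative"`. Relative metrics error out on any zero prediction;
no other denominator guard is applied since responses here are strictly
positive. Model ranking: higher r² wins, lower everything else; the overall
verdict is the majority over the seven metrics, with exact ties flagged.

## Optimization and confirmation

The optimizer scans a full grid over the coded box (5 levels per factor by
default) and polishes the best point with bounded L-BFGS-B; it is
deterministic. The default search region is the factorial cube [−1, +1]^k,
not the axial sphere — the choice that reproduces the published "all factors
high" optimum. Desirability is the linear maximize form, d = 0 at L, 1 at T,
with (L, T) defaulting to the surface's value range on the grid.
The confirmation rule takes the percent difference relative to the
*predicted* value, 100·|obs − pred|/pred, and passes below 5 %.

## Fermentation kinetics

Biomass follows the logistic model
X(t) = X₀X_max e^(µt) / (X_max − X₀ + X₀e^(µt)), evaluated with e^(−µt) to
avoid overflow at large t. Product, activity and cumulative substrate
consumption follow the modified Gompertz form
P(t) = P_max·exp(−exp(r_max·e/P_max·(t_lag − t) + 1)), parameterized by the
asymptote, the inflection slope r_max, and the lag time t_lag (where the
inflection tangent crosses zero; P(t_lag) = P_max·e^(−e) ≈ 0.066·P_max).
Substrate is modelled as a *rising consumed-amount* curve, matching how the
source reports it. Fitting is bounded nonlinear least squares
(`scipy.optimize.curve_fit`, tolerances 1e-12) with data-driven starts:
X₀/P_max from the first/maximum observation, rates from the steepest
finite-difference slope, t_lag from the tangent intercept. Constant series
are rejected rather than "fitted". Goodness of fit: r², adjusted
r² = 1 − (1−r²)(n−1)/(n−p−1), RMSE, MAE, and an F test against the constant
model.

Yield coefficients follow Y_p/s = P_max/S_max, Y_x/s = (X_max − X₀)/S_max,
Y_p/x = P_max (in g) / X_max, and specific rates q = r_max/X_max. The
published q_p/q_s values are not reproducible from any standard formula we
tried (r_max/X_max, µ·Y and µ/Y variants all disagree); r_max/X_max is kept
as the documented convention and those two quantities are not used for
acceptance. Units are carried as declared (product mg, biomass and
substrate g) and not reinterpreted, including the physiologically enormous
printed substrate asymptote.

## Synthetic data

`simulate_doe` draws y = quadratic(z) + N(0, σ) per run: additive noise,
because assay error across the narrow design region is roughly
homoscedastic. The default surface preset is the published coefficient set;
σ = 5000 U in the pipeline tests, chosen as the scale of the packaged
design's replicate standard deviation (centre-run SD ≈ 6.8 kU) so simulated
refits have realistic signal-to-noise. `simulate_fermentation` draws
curve·(1 + N(0, σ_rel)) at t = 0, 4, …, 36 h, floored at zero:
multiplicative noise, because bioreactor measurements span decades and their
error scales with signal. The default σ_rel = 1 % matches the reported
parameter standard errors (e.g. µ_max 0.578 ± 0.01). What the generators do
*not* emulate: systematic assay drift, autocorrelated residuals within a
batch, non-Gaussian outliers, and any feedback between responses (the real
responses are strongly collinear); passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to real-world artifacts.

Parameter-recovery conditions used by the tests and the acceptance script:
20 seeded series at 1 % noise, 10 time points, median-parameter tolerance
5 % — sizes that keep the full suite and the acceptance run within seconds
while leaving Monte-Carlo error well below the tolerances.

## Accounting conventions

Improvement % = 100·(mutant − parent)/parent and folds are reported at two
decimals, as in the source. Purification: specific activity = activity /
protein; yield % is activity relative to the crude extract; fold is the
ratio of specific activities ("purity" and "purification fold" are treated
as synonyms). Phase-level partition statistics (V_r = V_top/V_bottom,
K = C_top/C_bottom) are exercised on synthetic systems only, since per-phase
volumes and concentrations are not part of the packaged tables; an all-top
partition is flagged one-sided with K = ∞.

## Known limitations

* The packaged tables are printed values; several of their internal
  inconsistencies are preserved deliberately (rounded prediction columns, a
  duplicated experimental value, one improvement cell off by 0.01 at two
  decimals, the (22, 29) df pair) and documented where they matter.
* The quadratic refit of the printed runs gives r² = 0.97266, not the
  published 0.9749; the difference traces to the published fit having used
  unprinted raw data.
* No fractional factorials, Box–Behnken or D-optimal designs; no
  multi-response desirability; no mechanistic (Monod-type) kinetics.
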