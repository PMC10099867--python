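# Methods

## Rate laws and conversions

Soil-respiration temperature responses use the exponential model
`ln R(T) = ln R0 + b·T` with T in °C; `Q10 = exp(10·b)`. Chemical reactions
use the Arrhenius law `ln k(T) = ln A − Ea/(R·T_K)`. The two meet in
`q10_from_ea`, which evaluates a reaction's Q10 between two temperatures
(default 20–30°C, the conventional interval for quoting chemical Q10 values):

    Q10 = [exp((Ea/R)·(1/T_low − 1/T_high))]^(10/(T_high − T_low))

with the outer exponent reducing to 1 for a 10°C gap. Eyring-derived slopes
are converted with `Ea = ΔH‡ + R·T` at the record's reference temperature.

Units and constants: energies are kJ·mol⁻¹ at every interface; the gas
constant is fixed at 8.314 J·mol⁻¹·K⁻¹; °C→K conversion uses 273.15; the
half-life year is the Julian year (3.15576×10⁷ s) — at two significant
figures the reported half-lives are insensitive to the year convention.
Rate constants are carried in natural-log space end to end: uncatalysed
rates reach ~1e-20 s⁻¹ (ln k ≈ −45), and exponentiating only at the edges
(half-lives, rate enhancements) avoids underflow.

## Correlation sweep and the sign-flip temperature

`correlation_sweep` reconstructs each record's ln rate on an inclusive °C
grid (default 0–60°C, 1°C steps) and correlates Q10 against it. Pearson
correlation is the default and the tested path, with the p-value from the
two-sided t-test on n−2 degrees of freedom; Spearman is available as an
option. No multiple-testing correction is applied across grid points — the
sweep is a descriptive profile, not a family of hypotheses. Q10 itself (not
b) is the correlated variable; because Q10 = e^(10b) is monotone but
nonlinear in b, the sweep with b instead would differ slightly, though the
sign-flip location is governed by the same covariance geometry.

The flip temperature uses the closed form
`T0 = −cov(Q10, ln R0)/cov(Q10, b)` (sample covariances); it is the exact
root of the sweep's numerator, so r(T0) = 0 up to rounding. When
cov(Q10, b) = 0 the correlation never changes sign and `None` is returned
with a warning.

Determinism: records are internally sorted by (Q10, ln R0) before the
correlation sums, so a permutation of the input rows yields bit-identical
results; the jackknife likewise sorts its (x, y) pairs canonically before
the leave-one-out sums.

## Jackknife CQT test

`cqt_test` builds each uncatalysed reaction's ln k_non profile over 0–200°C
(1°C steps — the sweep convention carried over, since only the range, not
the increment, is conventionally fixed) anchored exactly at its 25°C rate.
At each temperature it jackknifes the Pearson correlation of Ea against
ln k_non(T): the n leave-one-out coefficients give
`r_mean = mean(r_i)` and `se = sqrt(((n−1)/n)·Σ(r_i − r_mean)²)`, the
standard jackknife standard-error formula. The catalysed profile pairs each
catalysed Ea with its partner's ln k_non via an explicit `pair_id`; a
dangling pair is an error listing the offenders, never a silent drop. When
a record carries both Ea and ΔH‡ and they disagree by more than
0.5 kJ·mol⁻¹ (enough to cover RT rounding differences), a consistency
warning is emitted and the directly reported Ea wins.

n ≥ 4 is required so that every leave-one-out subset still has three
points; a zero-variance subset raises an error naming the omitted index.

## Synthetic data

The generators produce data with the statistical *structure* the analyses
assume; they are not fitted to any real compilation, and passing tests show
the pipeline behaves correctly on that structure, not that any particular
field dataset has it.

**Incubations** — (b, ln R0) bivariate normal. Defaults: n = 113 (a typical
compilation size), mean_b = 0.09 °C⁻¹ (Q10 ≈ 2.5, the middle of commonly
reported soil Q10 values), sd_b = 0.02, mean ln R0 = 0 with sd 1 (about a
factor-of-e spread in baseline rates), rho = −0.7. With these moments the
implied sign-flip temperature ≈ −rho·sd_lnr0/sd_b ≈ 35°C, comfortably
inside the 0–60°C sweep. Real compilations differ in ways the generator
ignores: heteroscedastic fits, dataset-level clustering, non-normal tails.

**Noise artefact** — repeated noisy measurement of one true curve
(default Q10 = 2.5), additive Gaussian noise on ln rate (multiplicative
lognormal on the rate, matching how log-linear fits treat residuals),
measurement grid 4–28°C every 4°C, a common laboratory incubation range;
a 10–30°C preset grid is equally valid and the effect only needs mean(T) > 0.
OLS refitting then anticorrelates slope and intercept because
cov(b̂, ln R̂0) = −T̄·var(b̂); a grid centred on 0°C makes the artefact
vanish, which the tests verify.

**Reactions** — uncatalysed Ea ~ Uniform over a preset range (A: 35–199
kJ·mol⁻¹, the full uncatalysed span; B: 90–200 kJ·mol⁻¹, the narrower span
typical of the enzyme-paired subset — both presets are exposed because the
two spans describe different subsets, and no single range fits both), with
pre-exponential ln A ~ Normal(ln 1e10, 2) in s⁻¹ chosen so generated 25°C
rates cover the characteristic 1e-3 … 1e-20 s⁻¹ span of uncatalysed
biological reactions (a design target, not an estimate of any compilation).
Setting ln_a_sd = 0 makes Ea and ln k25 exactly collinear — the designed
positive control where the CQT correlation is −1 with zero jackknife spread
at every finite temperature. Catalysed Ea ~ Uniform(40, 70) kJ·mol⁻¹, drawn
independently of everything else and linked injectively to distinct
uncatalysed records (hence n_cat ≤ n_non); independence makes "no
correlation at any reference temperature" the correct outcome, and the
tests bound the sampling noise at n = 200.

All generators are pure functions of their config: the same seed gives
bit-identical output (numpy `default_rng`).

## Numerical choices and edge cases

- Grids are inclusive of both endpoints; grid length is computed with a
  rounded division so fractional steps do not drop the last point.
- At a temperature where all reconstructed ln rates coincide (curves
  crossing in a single point), the sweep records NaN rather than failing.
- `crossover_temperature` distinguishes parallel-distinct curves (`None`)
  from identical curves (`IdenticalResponsesError`), since "everywhere
  equal" has no single cross-over.
- CSV serialization uses 16-significant-digit scientific notation so a
  write/read cycle preserves all numeric fields to at least 15 significant
  digits, including ln k ≈ −45.
- Leave-one-out correlations are computed from explicitly materialised
  (n, n−1) subset matrices rather than sum downdating; for n ≤ a few
  hundred this is fast and avoids catastrophic cancellation near |r| = 1.

## Problem sizes

The test suite and the reproduction script use n = 500 incubations for the
sweep, 200 refits for the noise simulation, 56 reactions for the positive
control and 200 pairs for the independence control, and n = 5000 for
generator moment recovery — sizes at which the sampling-error envelopes
asserted in the tests (e.g. |r| < 0.15 for the independence control) hold
with wide margin, while the whole suite runs in seconds.

## Limitations

- Constant-Q10 / constant-Ea (linear Arrhenius) kinetics only: no
  temperature-dependent activation energies, tunnelling, diffusion limits
  or other non-Arrhenius behaviour.
- The incubation analysis starts from fitted (Q10, ln R0) pairs; refitting
  raw respiration time series is out of scope (only the noise simulator
  fits lines, from its own generated data).
- Unweighted pooling across sources; no mixed-effects structure.
- Catalysed reactions contribute only their Ea; their absolute rates (and
  hence temperature profiles of k_cat) are not modelled.
- Physical protection of soil carbon (adsorption/desorption on mineral
  surfaces) is outside the model entirely: the toolkit addresses chemical
  recalcitrance only.
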