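# Methods

## Model

Each of `K_tot` studies compares a treated arm (arm 1) with a control
arm (arm 2).  Arm counts are modelled as `Y_ij ~ Poisson(N_ij *
lambda_ij)` with a log-linear rate `lambda_i1 = lambda_i2 * exp(xi_i)`,
so both the baseline rate `lambda_i2` and the log relative risk `xi_i`
vary across studies.  Conditioning on the study total `Y_i. = Y_i1 +
Y_i2` eliminates the baseline rate:

    Y_i1 | Y_i. ~ Binomial(Y_i., expit(logit(pi_i) + S_i)),

where `pi_i = expit(xi_i)` is the *treatment contrast* and `S_i =
log(N_i1 / N_i2)` the design offset.  A double-zero study (`Y_i. = 0`)
contributes a degenerate conditional law and is removed; no continuity
correction is offered for such studies because, under the conditional
argument, they carry no information about the relative risk.  The
remaining `K` studies are the analysis set.

The contrasts are random effects, `pi_i ~ Beta(alpha0, beta0)` with
`alpha0, beta0 >= 1`.  In mean/variance coordinates `(mu0, v0)` the
restriction is `v0 <= v_sup(mu0) = mu0(1-mu0) * min(mu0/(1+mu0),
(1-mu0)/(2-mu0))`, which forces unimodality so that `mu0` is an
interpretable, identifiable centre.  Without it, shapes below 1 put
mass at the endpoints: Beta(0.001, 0.004) has mean 1/5 yet leaves a 26%
chance that six studies all show essentially no treated-arm events — a
paradox the constraint removes.  The target of inference is `mu0`;
`mu0 = 0.5` is no effect and `mu0/(1-mu0)` the relative risk.

## Test statistic

A Wald statistic `T(mu) = (point - mu)^2 / Var(point)` built from
method-of-moments estimators; moments avoid the iterative fitting that
would make the Monte-Carlo inner loop expensive.

*Balanced designs.*  `mu_hat` is the mean of the raw fractions
`Y_i1/Y_i.`.  For the variance-related moments every count carries a
continuity correction (`+0.5` to events, `+1` to totals) so that
studies with `Y_i. = 1` or all-zero treated arms still contribute;
`v_hat` is truncated at zero.  The variance of the point estimate uses
corrected totals throughout,

    Var = K^-2 * sum_i [ mu_hat(1-mu_hat)/(Y_i.+1) + (1 - 1/(Y_i.+1)) v_hat ],

a deliberate resolution of an ambiguity: with raw totals a study with
`Y_i. = 1` would zero out its heterogeneity term and inflate the
binomial term erratically in sparse data.  The correction shifts the
statistic slightly for observed and simulated data alike, so the
exactness of the test is untouched.

*Unbalanced designs.*  The larger arm is notionally down-sampled to the
smaller arm's size.  The retained event count `l` follows a
hypergeometric law; every balanced-design moment sum is averaged over
the support with those weights.  An outcome that would make the
resampled study double-zero (possible when the fixed arm has zero
events) is excluded and the weights renormalised, mirroring the
filtering applied to observed data.  Both imbalance directions are
handled: whichever arm is larger is resampled, the other arm's events
stay fixed, and the contrast ratio is always treated events over total
events.  This weighted estimator reduces *exactly* to the balanced one
when every support is a singleton.  The double-zero renormalisation
biases the point estimator away from 0.5 in sparse unbalanced data;
that costs efficiency, not validity, because the identical statistic is
applied to observed and simulated data.

The point estimator deliberately uses raw (uncorrected) count ratios in
both the balanced and weighted forms, keeping the two structurally
parallel; the corrections enter only the second-moment sums.

Degenerate edge: if every simulated treated count is zero, the moment
variance collapses; `mu(1-mu)` is floored at machine epsilon inside
`Var` so the statistic stays defined (it becomes astronomically large,
i.e. such replicates are maximally extreme, which is the conservative
direction).

## Exact test and profiling

The p-value at `(mu, v)` is Monte-Carlo: draw `m` synthetic datasets
from the conditional model with the observed totals, sizes and offsets,
recompute the same estimator pipeline and statistic on each, and report
the fraction of simulated statistics `>=` the observed one (ties count
as extreme — the conservative rule).  The nuisance variance is profiled
by evaluating at the boundary `v_sup(mu)`: empirically the statistic's
tail probability increases with `v` (first-order stochastic dominance),
so the supremum over `v` sits at the largest admissible variance.  The
dominance is an empirical regularity, not a theorem; the grid search's
correction pass exists precisely because it can fail locally.

## Confidence interval

The `(1-alpha)` interval is the set of grid values of `mu` (step `s`,
default 0.001 on the contrast scale) whose profile test is not rejected
at level `alpha`:

1. **Initialise** — asymptotic Wald bounds `point ± z_{1-alpha/2} *
   sqrt(Var)`, widened by 50% of their half-width (so the walk usually
   starts just outside the exact interval), snapped to the grid,
   clipped to `[s, 1-s]`.
2. **Iterate** — walk each bound outward one grid step at a time until
   the profile p-value drops below `alpha`; if the starting point is
   already rejected, walk inward toward the point estimate first.
3. **Correct** — probe `correction_span` (default 10) further grid
   points beyond each provisional limit and extend to the outermost
   non-rejected point.

The search is local: it reports the connected acceptance region around
the point estimate.  With very sparse data the Wald ordering can also
accept extreme contrasts far from the point estimate (nearly all
simulated datasets there are degenerate and count as extreme); the
diagnostics retain every evaluated `(mu, p)` pair so the surface can be
audited or extended.  When the walk reaches the grid edge the interval
is clipped and flagged.

Defaults: `m = 2000` Monte-Carlo replicates per grid point (standard
error ~0.005 on a p-value near 0.05), `s = 0.001`, `alpha = 0.05`,
correction span 10.  The reported `p_at_null` is the profile p-value at
`mu = 0.5`.

### Randomness and reproducibility

All draws flow from one integer seed.  Each `(mu, v)` grid point gets
its own deterministic substream keyed by `(seed, round(mu*1e9),
round(v*1e12))`, so p-value surfaces are reproducible point-by-point
and re-evaluations are bit-identical.  Within a point, study-level
draws are generated in a canonical sorted arrangement of the studies
and mapped back, making every p-value — and hence the interval —
invariant to the order of the input rows.  Beta sampling degenerates to
a point mass at `mu` when `v < 1e-10` (the shapes overflow otherwise);
sampled treated counts are clipped to the feasible range `[max(0, Y_i.
- N_i2), min(Y_i., N_i1)]`, which is only reachable when a study total
exceeds an arm size — practically impossible at rare-event rates.

## Synthetic-data generator

Arm rates are `lambda_i1 ~ Gamma(alpha0, rate = alpha0/r0)` and
`lambda_i2 ~ Gamma(beta0, rate = alpha0/r0)`; the shared rate parameter
makes the implied contrast exactly Beta(alpha0, beta0) while the
treated arm has mean event rate `r0` and the control arm `r0 *
beta0/alpha0`.  Counts are Poisson with mean `n * lambda`, truncated at
the arm size (vanishingly rare below `r0 = 0.03`; counted when it
happens).  The three primary heterogeneity settings are Beta(1.45,
1.45), Beta(5.5, 5.5) and Beta(145, 145) for the null (contrast
variance about 0.064, 0.021 and 0.001), with protective counterparts
Beta(1.10, 1.65), Beta(4.20, 6.30), Beta(110, 165), all with mean 0.4
(relative risk 0.67).

Arm-size pairs are sampled with replacement from a user-supplied pool,
or from a synthetic source: base size log-uniform on [60, 700],
imbalance ratio from {1, 1.6, 2}, larger arm assigned to either side
with equal probability.  The packaged example tables are *synthetic
stand-ins* shaped like published rare-event meta-analyses (study
counts, two very large trials, event rarity); they are regenerated by
`scripts/make_synthetic_fixtures.py` and reproduce no published
analysis.  Real meta-analyses differ from all of these generators in
ways the tests therefore do not probe: correlated arm sizes and event
rates, non-Poisson overdispersion within arms, selective reporting.

The operating-characteristic harness measures the rejection rate of the
profile test at a hypothesised contrast (type-I error or power),
coverage and length under full test inversion, and the double-zero
prevalence.  Replicates in which fewer than two studies survive
double-zero filtering are counted and redrawn (the moment estimators
need `K >= 2`).  Coverage at the null is scored through the profile
test (the interval contains `mu` iff the test at `mu` accepts, up to
grid resolution), which keeps the replication affordable: the default
check uses 300 replicates of 12 studies with `m = 500`, where the
measured rejection rate at the generating point is well below the
nominal 0.05 — the procedure is conservative by construction but not
vacuously so (coverage sits in the 97–99% range, not at 100%).

## Numerical choices

- Hypergeometric weights come from `scipy.stats.hypergeom`; supports
  are enumerated exactly, weights renormalised after the double-zero
  exclusion, and weight sums are unit to 1e-10 or better.
- `expit`/`logit` are evaluated through `scipy.special` (log-space
  safe); Beta draws are clamped away from exactly 0 and 1.
- Boundary shapes: at `v = v_sup(mu)` the algebra yields the smaller
  shape equal to 1 up to last-ulp noise; shapes within 1e-12 of 1 are
  snapped to exactly 1, and the profile search evaluates at the
  boundary (shapes `>= 1` rather than `> 1`): the closure of the
  parameter space is used because the supremum is attained there.
- Grid snapping uses rounding to the nearest multiple of `s`; all
  endpoints are exact grid multiples.

## Limitations

- The confidence set is reported as the connected interval around the
  point estimate; disconnected acceptance regions (a rare-event
  phenomenon of the Wald ordering at extreme `mu`) are visible only in
  the diagnostics.
- Coverage is guaranteed only up to Monte-Carlo error in the p-values;
  near-threshold endpoints move by a grid cell or two across seeds.
- Person-time (incidence-rate) inputs and multi-arm studies are out of
  scope; the harness calls external comparator methods only through a
  user-supplied hook.
- Runtime grows linearly in grid points walked times `m`; the
  implementation vectorises all `m` replicates per grid point, so
  full-scale analyses (`m = 2000`, `s = 0.001`) complete in minutes on
  one core.
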