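# Methods

## Model

Each arm of a two-arm trial with a dichotomous endpoint is reduced to
three counts: observed events `X_o`, observed non-events `n_o − X_o`,
and the number of patients lost to follow up `n_l`. Arms are modelled
independently, and within an arm:

- `X_o | p_o ~ Binomial(n_o, p_o)` with the non-informative Jeffreys
  prior `p_o ~ Beta(1/2, 1/2)`, so `p_o | X_o ~ Beta(X_o + 1/2,
  n_o − X_o + 1/2)`;
- `p_l | p_o ~ Beta(s·p_o + 1, s − s·p_o + 1)` — a prior for the
  lost-patient incidence whose mode is exactly `p_o`, with dispersion
  controlled by `s ≥ 0`;
- `X_l | p_l ~ Binomial(n_l, p_l)`.

The two limits of `s` have closed-form predictives and are dispatched
to them directly rather than approached numerically: `s → ∞` pins
`p_l = p_o` (missing at random) and gives
`X_l | X_o ~ BetaBinomial(n_l; X_o + 1/2, n_o − X_o + 1/2)`; `s = 0`
makes `p_l ~ Uniform[0,1]` independent of `p_o` (a strong
not-missing-at-random stance) and gives `X_l ~ Uniform{0, …, n_l}`.

The null hypothesis is equality of the two arms' *overall* incidences
(observed and lost pooled). Significance of any concrete table is
assessed by the two-sided Fisher exact test at `alpha = 0.05` by
default; the test and threshold are parameters, not assumptions of the
method.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `s` (per arm) | solved | dispersion of the lost-incidence prior; larger = closer to missing at random |
| `multiplier` | 1.3 | right-endpoint target of the default `s` rule |
| `interval_mass` | 0.75 | equal-tail mass used by the default `s` rule |
| `q` | 0 | sufficiently-likely threshold; HDR level is `1 − q` |
| `alpha` | 0.05 | significance threshold, compared strictly (`p < alpha`) |
| `method` | quadrature | `quadrature` (deterministic) or Monte-Carlo sampling |
| `n_samples` | 100 000 | Monte-Carlo sample size |

**Default `s` rule.** `s` solves: the `(1 + interval_mass)/2` quantile
of `Beta(s·p̂ + 1, s − s·p̂ + 1)` equals `multiplier · p̂`, where `p̂`
is the arm's observed incidence (plug-in; the interval is evaluated
under the conditional prior at `p_o = p̂`, not under the marginal of
`p_l` — this reading reproduces the published solved values, e.g.
136.2 at `p̂ = 0.131`). The quantile decreases monotonically from the
uniform quantile at `s = 0` towards `p̂` as `s → ∞`, so the root is
bracketed by doubling and refined with Brent's method (`xtol 1e-9`);
the rule has no root when `multiplier·p̂` falls outside
`(p̂, (1+interval_mass)/2)`, which is reported as an error — the
multiplier/incidence combination is incompatible, common for very high
observed incidences.

## Posterior predictive computation

The predictive `P(X_l = k | X_o)` mixes the conditional beta-binomial
`BetaBinomial(k; n_l, s·p_o + 1, s(1−p_o) + 1)` over the Jeffreys
posterior of `p_o`. The default path evaluates this one-dimensional
integral deterministically: substituting `p_o = F⁻¹(u)` (the posterior
quantile function) turns it into an integral of a smooth bounded
function over the unit interval, which a 501-node Gauss–Legendre rule
handles uniformly — including the `X_o = 0` / `X_o = n_o` cases where
the posterior density itself has an integrable endpoint singularity.
Against a 2001-node rule the pmfs agree to ~1e-8 per cell, and against
a 2×10⁶-sample Monte-Carlo run to within sampling error (~4e-4).

The sampling path (`p_o | X_o → p_l | p_o → X_l | p_l`, parameters then
discarded) is retained for fidelity to the model's definition and as a
cross-check; it requires an explicit seed — there is no wall-clock
seeding anywhere in the package.

The joint predictive over `(X_l^C, X_l^T)` is the outer product of the
marginal pmfs (between-arm independence). Imputation takes the joint
mode; masses within a relative `1e-9` of the maximum count as tied
modes, since quadrature round-off can split exact analytic ties.

## Significance grid

Every lost-outcome pair `(k_C, k_T)` defines an augmented 2×2 table
(observed outcomes unchanged, `k` events among each arm's lost
patients). The grid is evaluated exhaustively — no pruning — with the
hypergeometric point masses computed from a log-gamma lookup table over
the integers up to the total sample size; this is exact and evaluates
the largest worked grid (65×96 tables, n ≈ 1 900) in under a second.
The two-sided p-value sums all tables no more probable than the one
observed, with a `1 + 1e-7` relative slack on the comparison to guard
floating-point ties (the convention of the mainstream exact-test
implementations). Degenerate tables with an empty arm or an empty
event/non-event margin return `p = 1`. The scalar test used for single
tables takes the independent `scipy.stats.hypergeom` route, and both
are verified in the test suite against a brute-force enumeration from
first principles.

The risk difference is reported as control minus treatment incidence,
with arms in input order.

## Highest density regions and the index

`hdr(joint, q)` accumulates cells in decreasing mass order until the
cumulative mass reaches `1 − q`, then also includes every cell tied
(relative `1e-12`) with the last one admitted. Tie inclusion makes the
region deterministic, slightly conservative (it may over-cover), and
preserves nesting in `q`. `q = 0` returns the full support explicitly
— the round-off of summing thousands of tiny masses must not drop
far-tail cells — and `q = 1` degenerates to the mode set.

The fragility index at threshold `q`: candidate cells are the HDR
members whose augmented-table significance differs from the
**observed-patients baseline** conclusion (either direction of change
counts). If no candidate exists the index is infinite — a valid
result, serialised as `fi = null` with an explicit `"infinite": true`
flag. Otherwise, for each imputed mode the minimum L1 distance to a
candidate is found (each unit = one lost patient's outcome modified
from its imputation), and the median over modes is reported, possibly
half-integer for an even number of tied modes, unrounded.

Diagnostics computed alongside: the reversal probability (predictive
mass on reversing cells; zero exactly when reversal is impossible), the
largest `q` whose HDR still contains a reversing cell (equivalently one
minus the smallest tie-inclusive coverage over reversing cells), and
the minimal coverage needed to include any given cell.

## Synthetic data generator

`simulate.GeneratorConfig`/`generate_trial` draw trials from exactly
the analysis model above — binomial observed counts at a specified true
incidence, beta-dispersed lost incidence at a specified `s`, binomial
lost counts — returning both the summary a trialist would see and the
held-out realised lost event counts. It deliberately adds **no**
missingness mechanisms beyond the model (no covariate-driven dropout,
no informative censoring outside the `s`-dispersion): the property it
supports is calibration *under the assumed model*, i.e. that posterior
HDRs built from a generated summary cover the realised lost-outcome
pair at or above the nominal `1 − q` (over-coverage comes from tie
inclusion and discreteness). Passing calibration therefore says the
machinery is self-consistent; it says nothing about whether a real
trial's missingness resembles any particular `s`. That judgement —
and sensitivity to it — remains the analyst's, which is why `s` is
exposed per arm.

The calibration experiment in the test suite uses 80 observed + 6 lost
patients per arm and 1 000 replicates: large enough for stable coverage
estimates, small enough to keep the default test run fast.

## Numerical and design choices

- Quadrature is the default everywhere a predictive is needed;
  Monte-Carlo never runs implicitly. Two identical quadrature runs
  produce byte-identical report JSON.
- The equal-tail `s` rule uses the plug-in `p̂` (see above).
- `alpha` comparison is strict, so `p = alpha` exactly is *not*
  significant.
- Mode ties: relative `1e-9`; HDR boundary ties: relative `1e-12`.
- The reversal reference is always the observed-patients-only test,
  never the imputed table — this is the only reading under which "the
  expected outcomes themselves reverse significance" yields index 0.
- Reported `q`-type quantities (smallest reversing region, minimal
  coverages) are exact under quadrature; published counterparts derived
  by posterior sampling can differ in the third decimal. For the EXCEL
  example the exact smallest reversing region is `q = 0.248`
  (independently confirmed by 2×10⁶-sample Monte Carlo), with the
  published 0.251 inside the expected sampling band; the index at that
  boundary is 13 either way.

## Limitations

- Only 2×3 summaries are consumed; patient-level data, covariates and
  time-to-event endpoints are out of scope (trials analysed by survival
  methods must be coerced to a dichotomous endpoint first).
- Only the two-sided Fisher exact test is implemented; the grid
  machinery is test-agnostic in principle but no other test is wired
  in or validated.
- One prior family for `p_l | p_o` (mode-at-`p_o` beta); alternative
  skewed priors and covariate-informed imputation are not provided.
- Multiple imputation and clinical (rather than statistical)
  significance variants of the index are out of scope.
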