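# Methods

## Model

A reaction time to a crossmodal (visual–auditory) stimulus is the sum of
two stages, `RT = W1 + W2`.

**First stage — peripheral race.** The modality-specific peripheral
processing times are independent exponentials, `V ~ Exp(λ_V)` and
`A ~ Exp(λ_A)` (rates in 1/ms; the mean peripheral duration `1/λ` is the
handle through which stimulus intensity acts). The exponential choice is
a tractability assumption; combined with a Gaussian second stage the
total RT is a mixture of ex-Gaussians, an empirically reasonable RT
shape. Under CSP the first stage lasts `min(V, A)`; under FAP it lasts
the target's peripheral time (the non-target never drives the overt
response).

**Window rule.** Integration is triggered only when the peripheral
terminations fall within the window of width `ω`: `|V − A| < ω` (CSP);
for FAP additionally the non-target must win the race, so with a visual
target `A < V < A + ω`. All comparisons are strict; ties are
measure-zero and count as non-integration in the simulator. The FAP
event is a subset of the CSP event, which forces
`Pr(I_FAP) ≤ Pr(I_CSP)` and, under matched rates, the exact identity
`Pr(I_CSP) = 2·Pr(I_FAP)`.

**Second stage.** `E[W2] = μ` without integration; integration shifts
the mean by `−Δ` (facilitation for `Δ > 0`, inhibition for `Δ < 0`).
Expected crossmodal RT is `E[W1] + μ − Pr(I)·Δ`; unimodal RT is
`1/λ + μ` by context invariance (the peripheral marginals do not depend
on which stimuli are present). Percent crossmodal response enhancement
(CRE) compares the crossmodal mean against the fastest relevant unimodal
mean: the faster of the two for CSP, the target modality for FAP. The
CSP numerator contains the statistical-facilitation term
`min(1/λ_V, 1/λ_A) − 1/(λ_V+λ_A)`, which shrinks as intensity grows —
the source of inverse effectiveness under CSP; FAP, lacking that term,
shows the opposite intensity trend.

FAP with an auditory target is obtained by swapping `(λ_V, λ_A)` in the
visual-target formulas; this symmetry is exploited throughout
(`TwinParams.target_rates`).

## Optimal window

Integration is modeled as a decision about the cause of the two signals
given their arrival-time difference `t`. Under separate sources `t` is
uniform on the observation interval `(t0, t1)` of length `s`; under a
common source the signed difference `V − A` is asymmetric-Laplace (FAP)
and the absolute difference `|V − A|` a two-component exponential
mixture (CSP), both induced by the peripheral exponentials. Integration
maximizes the expected payoff exactly when the likelihood ratio
`L(t) = f(t|common)·s` exceeds the threshold
`[(1−p)/p]·[(u20−u21)/(u11−u10)]`.

Matched rates plus a unit utility ratio give closed-form windows
(symmetric `±(1/λ)·ln(λsp/(2(1−p)))` for FAP; `[0, (1/λ)·ln(λsp/(1−p)))`
for CSP) with existence thresholds `p ≥ 2/(λs+2)` and `p ≥ 1/(λs+1)`
respectively. Nonexistence is returned as an empty-window value, not an
exception, so prior sweeps can cross the threshold; only `cre_optimal`
raises, since the substituted enhancement formula presumes a window.

Design choices where the formulation leaves room:

- **Interval conventions.** Only `s = t1 − t0` enters the formulas, so
  the defaults are anchored conventionally: FAP uses the symmetric
  signed-difference interval `(−s/2, s/2)`, CSP the absolute-difference
  interval `(0, s)`. Window bounds exceeding the interval are clipped
  and flagged (`TimeWindow.clipped`).
- **Width as ω.** The FAP decision window spans negative and positive
  differences while the FAP integration event is one-sided; following
  the substituted enhancement expressions, the scalar width `ω_opt` is
  fed directly into `Pr(I_FAP)` as `ω`.
- **Generalization.** `optimal_window_numeric` extends the rule to
  unmatched rates and arbitrary payoffs by root-finding `L(t) = θ` on
  each monotone branch of the unimodal likelihood ratio (geometric
  bracket growth from 1 ms, Brent's method, `xtol = 1e−12` ms); it
  agrees with the closed form to well below the 1e−6 ms the tests
  demand. `optimal_window_closed_form` itself accepts any payoff matrix
  by folding the utility ratio into the threshold, which reduces to the
  unit-ratio expressions when that ratio is one.

## Simulator

`simulate_trials` draws, per trial, `V`, then `A`, then the second stage
(a single seeded `numpy.random.Generator`; the stream order is part of
the reproducibility contract). The effective auditory arrival is
`A + soa` (positive SOA delays the auditory stimulus); the window rule
is applied to the shifted times. `W2 ~ Normal(μ − Δ·1{integrated}, σ)`,
truncated below at 0 with the truncation count logged — RTs must be
non-negative, and at the default `σ` the truncated mass is ≈ 0 (it
matters only for deliberately extreme settings). `σ = 0` is supported so
sample means can be checked against the closed forms exactly;
`summarize` computes plug-in proportions, means, and CRE from sample
means, with binomial/normal standard errors and a first-order propagated
error for CRE.

Defaults: `σ = μ/10` (10 ms at the reference `μ = 100 ms`) — the model
leaves the second-stage spread unspecified; this keeps negative-mass
negligible while producing realistic RT dispersion. It affects only
trial-level spread, never a mean or enhancement prediction.

**What the simulator does and does not emulate.** It generates data
exactly from the model's assumptions: independent exponential peripheral
times, context invariance, a window-gated Gaussian second stage. Real RT
data additionally contain anticipations, omissions, outliers, sequential
effects, and parameter drift, none of which are modeled. Agreement
between simulator and closed forms therefore validates the
implementation's internal consistency, not the model's fit to any
empirical data set (no fitting procedure is provided or in scope).

## Parameters at a glance

| parameter | meaning | units | default |
|---|---|---|---|
| `lambda_v`, `lambda_a` | peripheral rates (1/mean duration) | 1/ms | — |
| `omega` | integration-window width | ms | — |
| `delta` | second-stage facilitation (−inhibition) | ms | 0 |
| `mu` | baseline second-stage mean | ms | 100 |
| `sigma` | second-stage SD (simulation only) | ms | 10 |
| `soa` | auditory onset delay (simulation only) | ms | 0 |
| `p_common` | prior of a common source | — | — |
| `t0`, `t1` | observation-interval bounds | ms | ±s/2 or (0, s) |
| `u11, u10, u21, u20` | payoff matrix | utility | 1, 0, 0, 1 |

Reference settings used by the figure-level tables: matched
`1/λ ∈ {20, 40, 60, 80, 100} ms`, `μ = 100 ms`, `Δ = 20 ms`, window grid
1–500 ms (the upper end is a documented choice; the curves are monotone
beyond it) for the intensity sweep; `λ = 0.03/ms`, `s = 1000 ms`, prior
grid 0.005–0.995 (step 0.005) for the optimal-window sweep.

## Numerical notes and problem sizes

- Closed forms use `expm1` to avoid cancellation at small `λω`.
- Matched-intensity identities are only applied when
  `|λ_V − λ_A|/max ≤ 1e−12` (`matched_rate`); otherwise the general
  two-term formulas run.
- Closed-form operations reject `soa ≠ 0` explicitly rather than
  silently ignoring it.
- Monte Carlo validation runs at `n = 10^6` trials per condition on a
  20-point parameter grid with a 4-standard-error criterion; routine
  unit tests use `n = 2×10^5`. All seeds are fixed in the tests.
- Degenerate inputs: `ω = 0` yields zero integration; `Δ = 0` removes
  the interaction term (FAP enhancement exactly 0); nonpositive rates,
  `μ ≤ 0`, `σ < 0`, and degenerate payoffs (`u11 = u10`) are rejected at
  construction.

## Known limitations

- No closed forms for `soa ≠ 0`; the simulator accepts an SOA shift but
  analytic predictions are defined at simultaneity only.
- No fitting of `(λ, ω, Δ, μ)` to empirical RT data.
- Peripheral distributions other than the exponential (e.g. gamma) are
  not implemented; several predictions (inverse effectiveness, the
  optimal-window forms) are derived under the exponential assumption.
- The decision layer uses temporal disparity as the only evidence;
  spatial disparity and trial-by-trial window adaptation are out of
  scope.
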