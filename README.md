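# twinrt

Closed-form predictions, Bayesian optimal time windows, and Monte Carlo
simulation for the **time-window-of-integration (TWIN)** model of
multisensory reaction times.

## The problem

Responses to an audiovisual stimulus pair are typically faster than to
either stimulus alone. How much faster depends on the instruction given
to the participant:

- **CSP** (crossmodal signals paradigm, a.k.a. redundant target
  paradigm): respond as soon as *any* stimulus is detected;
- **FAP** (focused attention paradigm): respond only to a designated
  target modality and ignore the other.

The TWIN model explains crossmodal interaction in both regimes with one
mechanism. A reaction time decomposes into two stages,
`RT = W1 + W2`: a peripheral race between independent exponential
processing times `V ~ Exp(λ_V)` and `A ~ Exp(λ_A)` (first stage),
followed by a compound integration/response stage with baseline mean `μ`
(second stage). Multisensory integration is triggered only when the
peripheral terminations fall within a temporal window of width `ω` —
`|V − A| < ω` for CSP, and for FAP additionally the non-target must win
the race (`A < V < A + ω` with a visual target). Integration shortens
the second stage by `Δ > 0` (facilitation) or lengthens it (`Δ < 0`,
inhibition). This yields closed forms for

- the probability of integration, e.g.
  `Pr(I_FAP) = λ_A/(λ_A+λ_V) · (1 − e^{−λ_V ω})`, and under matched
  intensities (λ_V = λ_A) the identity `Pr(I_CSP) = 2·Pr(I_FAP)`;
- expected crossmodal RT, `E[RT] = E[W1] + μ − Pr(I)·Δ`;
- percent crossmodal response enhancement (CRE), the relative RT gain
  over the fastest relevant unimodal condition — reproducing *inverse
  effectiveness* (enhancement shrinking with stimulus intensity) for
  CSP but not FAP.

A decision-theoretic layer treats integration as a choice about whether
two signals share a common source, given their arrival-time difference,
a prior `p` for a common source, and a payoff matrix. Integrating is
optimal exactly where the likelihood ratio of the arrival-time
difference exceeds the payoff-weighted prior odds; the resulting set of
differences is the *optimal time window*, with closed-form width
`ω_opt = (2/λ)·ln(λsp/(2(1−p)))` for FAP and `(1/λ)·ln(λsp/(1−p))` for
CSP (`s` = observation-interval length). The window vanishes below a
threshold prior, and the enhancement at `ω_opt` for CSP approaches twice
the FAP value at high intensity.

A seeded trial-level simulator implements the same two-stage process and
recovers every closed form, serving as the package's independent check.

Intended users: researchers in multisensory perception and
computational cognitive modeling who want the model's quantitative
predictions, sweep tables, or synthetic trial data.

## Worked example

```python
import twinrt as t

# matched intense stimuli: mean peripheral time 1/λ = 20 ms,
# window ω = 100 ms, baseline μ = 100 ms, facilitation Δ = 20 ms
p = t.TwinParams(lambda_v=0.05, lambda_a=0.05, omega=100, delta=20, mu=100)

t.pr_integration(p, t.CSP)          # 0.9933
t.pr_integration(p, t.FAP_VISUAL)   # 0.4966  (exactly half)
t.expected_rt_crossmodal(p, t.CSP)  # 90.13 ms
t.expected_rt_unimodal(p, "visual") # 120.0 ms
t.cre(p, t.CSP)                     # 24.89 %
t.cre(p, t.FAP_VISUAL)              #  8.28 %

# optimal window at λ = 0.03/ms, prior p = 0.5, interval s = 1000 ms
w = t.optimal_window_closed_form(
    0.03, t.DecisionContext.for_fap(0.5, 1000.0), t.FAP_VISUAL)
(w.lower, w.upper, w.width)         # (-90.27, 90.27, 180.54) ms

# simulate and recover the CSP enhancement
trials = t.simulate_trials(p, t.CSP, 100_000, seed=1)
trials["integrated"].mean()         # 0.9939
```

The integration probabilities show the factor-of-two law; the simulated
proportion sits within Monte Carlo error (±0.0002) of the closed form;
the CSP enhancement (24.89 %) exceeds the FAP one (8.28 %) because CSP
adds statistical facilitation from the race to the interaction effect.

## Command line

```sh
twinrt predict --config config.yaml --out predictions.csv
twinrt optimal-window --config config.yaml --out windows.csv
twinrt figure1 --out cre_by_intensity.csv   # CRE(ω) at five intensities
twinrt figure2 --out window_by_prior.csv    # ω_opt(p), both paradigms
twinrt simulate --config config.yaml --seed 1 --n 1000000 --out trials.csv
```

A config file holds `params:` (TwinParams fields), optionally
`decision:` (prior, observation interval, payoffs) and `sweep:`
sections; see `twinrt.config` for the schema. Every output CSV gets a
`.meta.json` sidecar echoing the fully resolved configuration.

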