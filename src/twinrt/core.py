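"""Closed-form TWIN predictions.

With independent exponential peripheral processing times V ~ Exp(λ_V) and
A ~ Exp(λ_A) and window width ω, the probability that the window condition
holds has an explicit form per paradigm; plugging it into the two-stage
decomposition RT = W1 + W2 gives the expected crossmodal reaction time and
the percent crossmodal response enhancement (CRE).

All closed forms are derived at simultaneous onsets; operations raise
:class:`~twinrt.params.SOANotSupportedError` when ``soa != 0``.
"""

from __future__ import annotations

import math

from .params import Modality, Paradigm, TwinParams

__all__ = [
    "pr_integration",
    "expected_rt_crossmodal",
    "expected_rt_unimodal",
    "cre",
]


def pr_integration(params: TwinParams, paradigm: Paradigm) -> float:
    """Probability that multisensory integration is triggered.

    CSP: both terminations within ω of each other, Pr(|V−A| < ω)
        = λ_A/(λ_A+λ_V)·(1−e^{−λ_V ω}) + λ_V/(λ_A+λ_V)·(1−e^{−λ_A ω}).
    FAP (target modality T, non-target N): the non-target must win and the
    target terminate inside the window, Pr(N < T < N + ω)
        = λ_N/(λ_N+λ_T)·(1−e^{−λ_T ω}).

    Under matched rates λ_V = λ_A = λ this reduces to 1−e^{−λω} for CSP,
    exactly twice the FAP value.
    """
    params.require_simultaneous()
    lam_t, lam_n = params.target_rates(paradigm)
    total = lam_t + lam_n
    fap_term = (lam_n / total) * -math.expm1(-lam_t * params.omega)
    if paradigm.is_fap:
        return fap_term
    return fap_term + (lam_t / total) * -math.expm1(-lam_n * params.omega)


def expected_rt_crossmodal(params: TwinParams, paradigm: Paradigm) -> float:
    """Expected crossmodal reaction time E[RT_VA] in ms.

    E[RT_VA] = E[W1] + μ − Pr(I)·Δ, where the first stage is the race
    winner min(V, A) for CSP (mean 1/(λ_V+λ_A) for independent
    exponentials) and the target peripheral time for FAP (mean 1/λ_target).
    """
    params.require_simultaneous()
    lam_t, lam_n = params.target_rates(paradigm)
    e_w1 = 1.0 / lam_t if paradigm.is_fap else 1.0 / (lam_t + lam_n)
    return e_w1 + params.mu - pr_integration(params, paradigm) * params.delta


def expected_rt_unimodal(params: TwinParams, modality: Modality | str) -> float:
    """Expected unimodal reaction time, 1/λ_modality + μ (ms).

    No integration is possible with a single stimulus, and by context
    invariance the peripheral marginal is the same as in the crossmodal
    condition, so neither ω nor Δ enters.
    """
    return 1.0 / params.rate(modality) + params.mu


def cre(params: TwinParams, paradigm: Paradigm) -> float:
    """Percent crossmodal response enhancement.

    CRE = 100 · (fastest relevant unimodal mean − crossmodal mean) /
    (fastest relevant unimodal mean); the reference is the faster of the
    two unimodal means for CSP and the target-modality unimodal mean for
    FAP. In model terms:

    CSP: 100·[min(1/λ_V, 1/λ_A) − 1/(λ_V+λ_A) + Pr(I_CSP)·Δ]
             / [min(1/λ_V, 1/λ_A) + μ]
    FAP: 100·Pr(I_FAP)·Δ / [1/λ_target + μ]

    The CSP numerator splits into pure statistical facilitation (minimum
    of two racers, present even at Δ = 0) plus the interaction term; FAP
    has no statistical facilitation because the first stage is the target
    time itself. Negative values (inhibition, Δ < 0) are returned as-is.
    """
    params.require_simultaneous()
    pr_i = pr_integration(params, paradigm)
    if paradigm.is_fap:
        lam_t, _ = params.target_rates(paradigm)
        return 100.0 * pr_i * params.delta / (1.0 / lam_t + params.mu)
    fastest = min(1.0 / params.lambda_v, 1.0 / params.lambda_a)
    stat_fac = fastest - 1.0 / (params.lambda_v + params.lambda_a)
    return 100.0 * (stat_fac + pr_i * params.delta) / (fastest + params.mu)
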