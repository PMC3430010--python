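"""Bayesian decision-theoretic optimal time windows.

Whether two near-simultaneous signals should be integrated is framed as a
decision about their cause: a common audiovisual event (C = 1) or two
unrelated sources (C = 2). The only evidence is the arrival-time
difference t of the peripheral processes. Under a common source the
difference V − A of two independent exponentials follows an asymmetric
Laplace law (FAP, signed differences) and |V − A| a mixture of
exponentials (CSP); under separate sources the difference is uniform on
the experimenter-bounded observation interval (t0, t1). Integration is
optimal — maximizes the expected payoff — exactly when the likelihood
ratio L(t) = f(t|C=1)/f(t|C=2) exceeds the payoff-weighted prior odds.
The set of differences passing that rule is the optimal time window; its
width plays the role of ω in the integration-probability formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy.optimize import brentq

from .params import Paradigm, Regime, TwinConfigError

__all__ = [
    "DecisionContext",
    "TimeWindow",
    "NoOptimalWindowError",
    "density_separate",
    "density_common",
    "likelihood_ratio",
    "posterior_common",
    "decision_threshold",
    "optimal_window_closed_form",
    "optimal_window_numeric",
    "cre_optimal",
]

_BISECT_XTOL = 1e-12  # ms; root location for the numeric window solver


class NoOptimalWindowError(ValueError):
    """Raised when a computation presumes an optimal window that does not
    exist (the prior is below its existence threshold)."""


@dataclass(frozen=True)
class DecisionContext:
    """Prior, observation interval, and payoff matrix of the integration
    decision.

    Parameters
    ----------
    p_common
        Prior probability Pr(C = 1) that the two signals share a source.
    t0, t1
        Bounds of the observation interval (ms), the range of arrival-time
        differences the trial design permits. FAP reasons about signed
        differences and needs t0 < 0 < t1; CSP about absolute differences
        and needs 0 <= t0 < t1. Only the length s = t1 − t0 enters the
        optimal-window formulas.
    u11, u10, u21, u20
        Payoffs for (common source, integrate), (common, not integrate),
        (separate, integrate), (separate, not integrate). Correct
        decisions must pay more than their errors: u11 > u10, u20 > u21.
    """

    p_common: float
    t0: float
    t1: float
    u11: float = 1.0
    u10: float = 0.0
    u21: float = 0.0
    u20: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_common <= 1.0):
            raise TwinConfigError(
                f"p_common must lie in (0, 1], got {self.p_common!r}"
            )
        if not self.t0 < self.t1:
            raise TwinConfigError(f"need t0 < t1, got ({self.t0}, {self.t1})")
        if not self.u11 > self.u10:
            raise TwinConfigError("degenerate payoffs: need u11 > u10")
        if not self.u20 > self.u21:
            raise TwinConfigError("degenerate payoffs: need u20 > u21")

    @property
    def s(self) -> float:
        """Length of the observation interval (ms)."""
        return self.t1 - self.t0

    @property
    def utility_ratio(self) -> float:
        return (self.u20 - self.u21) / (self.u11 - self.u10)

    def validate_for(self, paradigm: Paradigm) -> None:
        if paradigm.is_fap:
            if not (self.t0 < 0.0 < self.t1):
                raise TwinConfigError(
                    "FAP uses signed arrival-time differences; the "
                    f"observation interval must straddle 0, got "
                    f"({self.t0}, {self.t1})"
                )
        elif self.t0 < 0.0:
            raise TwinConfigError(
                "CSP uses absolute arrival-time differences; need t0 >= 0, "
                f"got t0 = {self.t0}"
            )

    @classmethod
    def for_fap(cls, p_common: float, s: float = 1000.0, **payoffs) -> "DecisionContext":
        """Symmetric signed-difference interval (−s/2, s/2)."""
        return cls(p_common, -0.5 * s, 0.5 * s, **payoffs)

    @classmethod
    def for_csp(cls, p_common: float, s: float = 1000.0, **payoffs) -> "DecisionContext":
        """Absolute-difference interval (0, s)."""
        return cls(p_common, 0.0, s, **payoffs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionContext":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise TwinConfigError(f"unknown DecisionContext fields: {sorted(extra)}")
        return cls(**d)


@dataclass(frozen=True)
class TimeWindow:
    """An interval of arrival-time differences where integration is optimal.

    ``width`` is the scalar fed into the integration-probability formulas
    as ω. ``clipped`` flags truncation at the observation interval, in
    which case ``width`` refers to the truncated interval.
    """

    exists: bool
    lower: float = 0.0
    upper: float = 0.0
    clipped: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower if self.exists else 0.0

    @staticmethod
    def empty() -> "TimeWindow":
        return TimeWindow(exists=False)


def density_separate(t: float, ctx: DecisionContext) -> float:
    """Uniform likelihood of an arrival-time difference under two
    unrelated sources: 1/(t1 − t0) inside the observation interval,
    0 outside."""
    return 1.0 / ctx.s if ctx.t0 < t < ctx.t1 else 0.0


def density_common(
    t: float, lambda_v: float, lambda_a: float, paradigm: Paradigm
) -> float:
    """Likelihood of an arrival-time difference under a common source.

    FAP (signed t = V − A): asymmetric Laplace,
        [λ_V λ_A/(λ_V+λ_A)] · e^{−λ_V t} for t >= 0, · e^{λ_A t} for t < 0.
    CSP (t = |V − A| >= 0): mixture of exponentials,
        [λ_V λ_A/(λ_V+λ_A)] · (e^{−λ_A t} + e^{−λ_V t}),
    i.e. the signed density folded onto the non-negative half-line.
    """
    if not (lambda_v > 0 and lambda_a > 0):
        raise TwinConfigError("rates must be positive")
    c = lambda_v * lambda_a / (lambda_v + lambda_a)
    if paradigm.is_fap:
        return c * math.exp(-lambda_v * t) if t >= 0 else c * math.exp(lambda_a * t)
    if t < 0:
        raise ValueError(
            f"CSP arrival-time differences are absolute values; got t = {t}"
        )
    return c * (math.exp(-lambda_a * t) + math.exp(-lambda_v * t))


def likelihood_ratio(
    t: float,
    lambda_v: float,
    lambda_a: float,
    ctx: DecisionContext,
    paradigm: Paradigm,
) -> float:
    """L(t) = f(t | C=1) / f(t | C=2) = density_common(t) · (t1 − t0).

    Peaks at t = 0 and decays exponentially away from it, so large
    disparities are evidence for separate sources; for CSP it is strictly
    decreasing on its whole domain.
    """
    if not (ctx.t0 < t < ctx.t1):
        raise ValueError(
            f"t = {t} outside the observation interval ({ctx.t0}, {ctx.t1})"
        )
    return density_common(t, lambda_v, lambda_a, paradigm) * ctx.s


def posterior_common(
    t: float,
    lambda_v: float,
    lambda_a: float,
    ctx: DecisionContext,
    paradigm: Paradigm,
) -> float:
    """Posterior probability of a common source given the difference t,
    by Bayes' rule: pL / (pL + (1 − p))."""
    p = ctx.p_common
    if p == 1.0:
        return 1.0
    lr = likelihood_ratio(t, lambda_v, lambda_a, ctx, paradigm)
    return p * lr / (p * lr + (1.0 - p))


def decision_threshold(ctx: DecisionContext) -> float:
    """Critical likelihood ratio above which integrating maximizes the
    expected payoff: [(1 − p)/p] · [(u20 − u21)/(u11 − u10)].

    Larger priors for a common source lower the threshold and widen the
    window; raising the cost of wrongly integrating raises it.
    """
    p = ctx.p_common
    return (1.0 - p) / p * ctx.utility_ratio


def _clip(lo: float, hi: float, ctx: DecisionContext) -> TimeWindow:
    clipped = False
    if lo < ctx.t0:
        lo, clipped = ctx.t0, True
    if hi > ctx.t1:
        hi, clipped = ctx.t1, True
    if hi < lo:
        return TimeWindow.empty()
    return TimeWindow(exists=True, lower=lo, upper=hi, clipped=clipped)


def optimal_window_closed_form(
    lam: float, ctx: DecisionContext, paradigm: Paradigm
) -> TimeWindow:
    """Optimal window under matched rates λ_V = λ_A = λ, in closed form.

    With s = t1 − t0 and threshold θ = [(1−p)/p]·[(u20−u21)/(u11−u10)]
    (θ = (1−p)/p for the unit utility ratio):

    FAP: the symmetric interval
        [−(1/λ)·ln(λs/(2θ)), (1/λ)·ln(λs/(2θ))], width (2/λ)·ln(λs/(2θ)),
    which exists only while λs/(2θ) >= 1 — with unit payoffs,
    2(1−p)/(λsp) <= 1, i.e. p >= 2/(λs + 2).

    CSP: [0, (1/λ)·ln(λs/θ)), existing only while λs/θ >= 1 — with unit
    payoffs p >= 1/(λs + 1).

    Nonexistence is returned as an empty window, never raised, so sweeps
    over the prior can cross the threshold without aborting. Bounds
    exceeding the observation interval are clipped and flagged.
    """
    if not lam > 0:
        raise TwinConfigError("rate must be positive")
    ctx.validate_for(paradigm)
    if ctx.p_common == 1.0:
        # threshold 0: every difference in the interval favors integration
        lo = ctx.t0 if paradigm.is_fap else max(ctx.t0, 0.0)
        return TimeWindow(exists=True, lower=lo, upper=ctx.t1, clipped=True)
    theta = decision_threshold(ctx)
    if paradigm.is_fap:
        arg = lam * ctx.s / (2.0 * theta)
        if arg < 1.0:
            return TimeWindow.empty()
        upper = math.log(arg) / lam
        return _clip(-upper, upper, ctx)
    arg = lam * ctx.s / theta
    if arg < 1.0:
        return TimeWindow.empty()
    return _clip(max(ctx.t0, 0.0), math.log(arg) / lam, ctx)


def _grow_bracket(f, lo_ok: float, direction: float, limit: float):
    """Geometric bracket growth from |t| = 1 ms toward ``limit`` until f
    changes sign; returns (a, b) with f(a) > 0 > f(b), or None."""
    step = 1.0
    a = lo_ok
    while True:
        b = lo_ok + direction * step
        if (direction > 0 and b >= limit) or (direction < 0 and b <= limit):
            b = limit
        if f(b) <= 0:
            return (a, b) if direction > 0 else (b, a)
        if b == limit:
            return None
        a = b
        step *= 2.0


def optimal_window_numeric(
    lambda_v: float,
    lambda_a: float,
    ctx: DecisionContext,
    paradigm: Paradigm,
) -> TimeWindow:
    """Optimal window {t : L(t) > threshold} ∩ (t0, t1) by root-finding.

    Generalizes the closed form to unmatched rates and non-unit utility
    ratios: L(t) is unimodal with its peak at 0, so each boundary is the
    root of L(t) − θ on a monotone branch, bracketed geometrically and
    solved by Brent's method to sub-nanosecond tolerance. Agrees with
    :func:`optimal_window_closed_form` wherever that applies.
    """
    ctx.validate_for(paradigm)
    if ctx.p_common == 1.0:
        lo = ctx.t0 if paradigm.is_fap else max(ctx.t0, 0.0)
        return TimeWindow(exists=True, lower=lo, upper=ctx.t1, clipped=True)
    theta = decision_threshold(ctx)

    def excess(t: float) -> float:
        return density_common(t, lambda_v, lambda_a, paradigm) * ctx.s - theta

    anchor = 0.0 if paradigm.is_fap else max(ctx.t0, 0.0)
    if excess(anchor) <= 0:
        return TimeWindow.empty()

    def solve(direction: float, limit: float) -> tuple[float, bool]:
        if excess(limit) > 0:
            return limit, True  # window runs into the interval bound
        bracket = _grow_bracket(excess, anchor, direction, limit)
        if bracket is None:
            return limit, True
        root = brentq(excess, *bracket, xtol=_BISECT_XTOL)
        return float(root), False

    upper, clip_hi = solve(+1.0, ctx.t1)
    if paradigm.is_fap:
        lower, clip_lo = solve(-1.0, ctx.t0)
    else:
        lower, clip_lo = max(ctx.t0, 0.0), False
    return TimeWindow(
        exists=True, lower=lower, upper=upper, clipped=clip_hi or clip_lo
    )


def cre_optimal(
    lam: float,
    ctx: DecisionContext,
    delta: float,
    mu: float,
    paradigm: Paradigm,
) -> float:
    """Percent crossmodal response enhancement when ω is set to the
    optimal window width (matched rates, unit utility ratio).

    Substituting ω_opt into the enhancement formulas gives, with
    s = t1 − t0 and p the prior of a common source:

    CSP: 100·(1/λ + μ)^{−1} · [1/(2λ) + Δ·(1 − (1−p)/(λps))]
    FAP: 100·(1/λ + μ)^{−1} · (Δ/2) · [1 − (2(1−p)/(λps))²]

    As λ grows without bound the CSP value approaches twice the FAP value.
    Raises :class:`NoOptimalWindowError` when the prior sits below the
    window's existence threshold.
    """
    if not lam > 0:
        raise TwinConfigError("rate must be positive")
    if not mu > 0:
        raise TwinConfigError("mu must be positive")
    if abs(ctx.utility_ratio - 1.0) > 1e-12:
        raise TwinConfigError(
            "closed-form optimal enhancement assumes a unit utility ratio; "
            "compute the window numerically and evaluate cre() at its width"
        )
    window = optimal_window_closed_form(lam, ctx, paradigm)
    if not window.exists:
        raise NoOptimalWindowError(
            f"no optimal window exists at p = {ctx.p_common} "
            f"(below the existence threshold for {paradigm.regime.value})"
        )
    p, s = ctx.p_common, ctx.s
    scale = 100.0 / (1.0 / lam + mu)
    if paradigm.is_fap:
        q = 2.0 * (1.0 - p) / (lam * p * s)
        return scale * (delta / 2.0) * (1.0 - q * q)
    q = (1.0 - p) / (lam * p * s)
    return scale * (1.0 / (2.0 * lam) + delta * (1.0 - q))
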