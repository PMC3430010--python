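"""Trial-level Monte Carlo simulation of the two-stage TWIN process.

Each trial draws the peripheral processing times, applies the paradigm's
window rule to decide whether integration is triggered, and then draws a
Gaussian second stage whose mean is lowered by Δ on integrated trials.
The simulator is the package's independent check on every closed form:
with σ = 0 and soa = 0 the sample means converge to the analytic expected
reaction times, the integration proportions to the analytic
probabilities, and the plug-in enhancement estimates to the analytic CRE.

RNG contract: one seeded ``numpy.random.Generator`` per call; the stream
order is fixed (all V draws, then all A draws, then all W2 draws), so
identical (params, paradigm, n, seed) reproduce records bit-for-bit.

Trial-table data dictionary (column order as written to CSV):

========== ===========================================================
column     meaning
========== ===========================================================
trial_id   0-based trial index (int)
condition  "CSP", "FAP", "unimodal_V" or "unimodal_A"
v_time     sampled visual peripheral duration V (ms; NaN if no visual)
a_time     sampled auditory peripheral duration A (ms; NaN if none)
winner     modality terminating first ("visual"/"auditory"; "n/a"
           for unimodal trials); the SOA-shifted auditory time competes
soa        onset shift applied to the auditory stimulus (ms)
integrated whether the paradigm's window condition held (bool)
w1         first-stage duration (ms): race winner for CSP, target
           peripheral time for FAP, the single peripheral time unimodally
w2         second-stage duration (ms), Normal(μ − Δ·integrated, σ)
           truncated below at 0
rt         total reaction time w1 + w2 (ms)
========== ===========================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .params import Modality, Paradigm, TwinConfigError, TwinParams

__all__ = ["TRIAL_COLUMNS", "SummaryStats", "simulate_trials", "simulate_unimodal", "summarize"]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "trial_id",
    "condition",
    "v_time",
    "a_time",
    "winner",
    "soa",
    "integrated",
    "w1",
    "w2",
    "rt",
]


def _second_stage(
    rng: np.random.Generator, n: int, mu: float, sigma: float, reduction: np.ndarray
) -> tuple[np.ndarray, int]:
    """Draw W2 ~ Normal(μ − reduction, σ), truncated below at 0.

    Truncation keeps reaction times non-negative; at sane σ (default
    μ/10) the truncated mass is ~0 and the mean bias is far below Monte
    Carlo noise, but the count is returned and logged so it can be
    audited.
    """
    w2 = rng.normal(mu - reduction, sigma) if sigma > 0 else mu - reduction
    w2 = np.broadcast_to(np.asarray(w2, dtype=float), (n,)).copy()
    negative = w2 < 0
    truncated = int(negative.sum())
    if truncated:
        w2[negative] = 0.0
        logger.warning("truncated %d negative second-stage draws at 0", truncated)
    return w2, truncated


def _check_n_seed(n: int, seed: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise TwinConfigError(f"n must be a positive integer, got {n!r}")
    if seed is None or not isinstance(seed, (int, np.integer)) or seed < 0:
        raise TwinConfigError(f"an explicit non-negative integer seed is required, got {seed!r}")


def simulate_trials(
    params: TwinParams, paradigm: Paradigm, n: int, seed: int
) -> pd.DataFrame:
    """Simulate ``n`` crossmodal trials; returns a trial table (one
    :data:`TRIAL_COLUMNS` row per trial).

    Per trial: V ~ Exp(λ_V), A ~ Exp(λ_A); the effective auditory arrival
    is A' = A + soa. Integration follows the strict window rule —
    CSP: |V − A'| < ω; FAP: the non-target must win and the target land
    inside the window it opens (visual target: A' < V < A' + ω). Ties are
    measure-zero and count as non-integration. W1 is min(V, A') for CSP
    and the target time for FAP; W2 is the truncated Gaussian second
    stage with mean μ − Δ on integrated trials.
    """
    _check_n_seed(n, seed)
    rng = np.random.default_rng(seed)
    v = rng.exponential(1.0 / params.lambda_v, n)
    a = rng.exponential(1.0 / params.lambda_a, n)
    a_eff = a + params.soa

    if paradigm.is_fap:
        target = v if paradigm.target_modality is Modality.VISUAL else a_eff
        nontarget = a_eff if paradigm.target_modality is Modality.VISUAL else v
        integrated = (nontarget < target) & (target < nontarget + params.omega)
        w1 = target
    else:
        integrated = np.abs(v - a_eff) < params.omega
        w1 = np.minimum(v, a_eff)

    w2, _ = _second_stage(rng, n, params.mu, params.sigma, params.delta * integrated)
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "condition": paradigm.regime.value,
            "v_time": v,
            "a_time": a,
            "winner": np.where(v < a_eff, "visual", "auditory"),
            "soa": params.soa,
            "integrated": integrated,
            "w1": w1,
            "w2": w2,
            "rt": w1 + w2,
        },
        columns=TRIAL_COLUMNS,
    )
    if paradigm.is_fap:
        df.attrs["target_modality"] = paradigm.target_modality.value
    return df


def simulate_unimodal(
    params: TwinParams, modality: Modality | str, n: int, seed: int
) -> pd.DataFrame:
    """Simulate ``n`` unimodal trials for one modality.

    The peripheral time is drawn from the same exponential marginal used
    crossmodally (context invariance holds by construction); with a
    single stimulus no window can open, so no trial is integrated and
    W2 ~ Normal(μ, σ).
    """
    _check_n_seed(n, seed)
    modality = Modality(modality)
    rng = np.random.default_rng(seed)
    w1 = rng.exponential(1.0 / params.rate(modality), n)
    w2, _ = _second_stage(rng, n, params.mu, params.sigma, np.zeros(n))
    visual = modality is Modality.VISUAL
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "condition": "unimodal_V" if visual else "unimodal_A",
            "v_time": w1 if visual else np.full(n, np.nan),
            "a_time": np.full(n, np.nan) if visual else w1,
            "winner": "n/a",
            "soa": 0.0,
            "integrated": False,
            "w1": w1,
            "w2": w2,
            "rt": w1 + w2,
        },
        columns=TRIAL_COLUMNS,
    )


@dataclass(frozen=True)
class SummaryStats:
    """Aggregates of a simulated experiment, with plug-in standard errors.

    ``pr_integration_hat`` carries a binomial standard error;
    ``mean_rt``/``se_rt`` map condition labels to the sample mean and its
    normal-theory standard error; ``cre_hat``/``se_cre`` are the percent
    enhancement computed from the sample means (crossmodal vs. the
    relevant unimodal reference) with a first-order propagated error.
    """

    n: int
    paradigm: str
    pr_integration_hat: float
    se_pr_integration: float
    mean_rt: dict = field(default_factory=dict)
    se_rt: dict = field(default_factory=dict)
    cre_hat: float = float("nan")
    se_cre: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    return float(x.mean()), float(se)


def summarize(trials: pd.DataFrame, unimodal_trials: pd.DataFrame) -> SummaryStats:
    """Estimate integration probability, mean RTs, and CRE from trial
    tables.

    ``trials`` must hold one crossmodal condition (CSP or FAP);
    ``unimodal_trials`` the unimodal condition(s). The enhancement
    reference is the faster unimodal sample mean for CSP (both unimodal
    conditions required) and the target-modality mean for FAP, matching
    the definition of percent enhancement the closed forms use. FAP
    tables must identify the target via a ``target_modality`` attribute
    or contain only one unimodal condition (taken as the target).
    """
    if trials.empty or unimodal_trials.empty:
        raise TwinConfigError("empty trial tables")
    conditions = trials["condition"].unique()
    if len(conditions) != 1 or conditions[0] not in ("CSP", "FAP"):
        raise TwinConfigError(
            f"expected a single crossmodal condition, got {sorted(conditions)}"
        )
    paradigm_label = conditions[0]

    n = len(trials)
    p_hat = float(trials["integrated"].mean())
    se_p = float(np.sqrt(p_hat * (1.0 - p_hat) / n))

    mean_rt: dict[str, float] = {}
    se_rt: dict[str, float] = {}
    mean_rt[paradigm_label], se_rt[paradigm_label] = _mean_se(trials["rt"])
    uni_groups = {
        str(cond): grp["rt"].to_numpy()
        for cond, grp in unimodal_trials.groupby("condition")
    }
    for cond, rts in uni_groups.items():
        if cond not in ("unimodal_V", "unimodal_A"):
            raise TwinConfigError(f"unexpected unimodal condition {cond!r}")
        mean_rt[cond], se_rt[cond] = _mean_se(rts)

    if paradigm_label == "CSP":
        if not {"unimodal_V", "unimodal_A"} <= set(uni_groups):
            raise TwinConfigError(
                "CSP enhancement needs both unimodal conditions"
            )
        ref_cond = min(("unimodal_V", "unimodal_A"), key=lambda c: mean_rt[c])
    else:
        target = trials.attrs.get("target_modality")
        if target is not None:
            ref_cond = (
                "unimodal_V" if Modality(target) is Modality.VISUAL else "unimodal_A"
            )
            if ref_cond not in uni_groups:
                raise TwinConfigError(
                    f"FAP enhancement needs the target-modality condition {ref_cond}"
                )
        elif len(uni_groups) == 1:
            ref_cond = next(iter(uni_groups))
        else:
            raise TwinConfigError(
                "ambiguous FAP reference: set trials.attrs['target_modality'] "
                "or pass only the target-modality unimodal table"
            )

    ref_mean, ref_se = mean_rt[ref_cond], se_rt[ref_cond]
    x_mean, x_se = mean_rt[paradigm_label], se_rt[paradigm_label]
    cre_hat = 100.0 * (ref_mean - x_mean) / ref_mean
    # first-order error propagation of 100·(U − X)/U in (X, U)
    se_cre = 100.0 * np.hypot(x_se / ref_mean, x_mean * ref_se / ref_mean**2)
    return SummaryStats(
        n=n,
        paradigm=paradigm_label,
        pr_integration_hat=p_hat,
        se_pr_integration=se_p,
        mean_rt=mean_rt,
        se_rt=se_rt,
        cre_hat=float(cre_hat),
        se_cre=float(se_cre),
    )
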