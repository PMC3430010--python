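"""Parameter containers for the time-window-of-integration (TWIN) model.

The TWIN model decomposes a crossmodal reaction time into a peripheral race
(first stage) and a compound integration/response stage (second stage).
All durations are in milliseconds; rates are in 1/ms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict


class Modality(str, enum.Enum):
    VISUAL = "visual"
    AUDITORY = "auditory"


class Regime(str, enum.Enum):
    """Instruction regime of a crossmodal RT experiment.

    CSP (crossmodal signals paradigm, a.k.a. redundant target paradigm):
    respond to any stimulus; integration requires both peripheral
    terminations to land within the window of each other.

    FAP (focused attention paradigm): respond only to the target modality;
    integration requires the non-target to win the race and the target to
    terminate within the window opened by the non-target.
    """

    CSP = "CSP"
    FAP = "FAP"


class TwinConfigError(ValueError):
    """Invalid model parameters or an unsupported configuration."""


class SOANotSupportedError(TwinConfigError):
    """Closed-form predictions are derived at simultaneity (soa = 0) only."""


@dataclass(frozen=True)
class Paradigm:
    """Instruction regime plus, for FAP, the designated target modality.

    CSP is symmetric in the modalities and ignores ``target_modality``.
    FAP with an auditory target is handled by swapping the roles of the
    visual and auditory rates in the visual-target formulas.
    """

    regime: Regime = Regime.CSP
    target_modality: Modality = Modality.VISUAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "regime", Regime(self.regime))
        object.__setattr__(self, "target_modality", Modality(self.target_modality))

    @property
    def is_fap(self) -> bool:
        return self.regime is Regime.FAP

    @property
    def nontarget_modality(self) -> Modality:
        return (
            Modality.AUDITORY
            if self.target_modality is Modality.VISUAL
            else Modality.VISUAL
        )


#: Convenient ready-made paradigms.
CSP = Paradigm(Regime.CSP)
FAP_VISUAL = Paradigm(Regime.FAP, Modality.VISUAL)
FAP_AUDITORY = Paradigm(Regime.FAP, Modality.AUDITORY)


@dataclass(frozen=True)
class TwinParams:
    """All first- and second-stage TWIN parameters.

    Parameters
    ----------
    lambda_v, lambda_a
        Rates of the exponential visual/auditory peripheral processing
        times V and A (1/ms, > 0). The mean peripheral duration is the
        reciprocal rate, so intensity manipulations map onto the rates.
    omega
        Width of the time window of integration (ms, >= 0). Peripheral
        terminations closer together than ``omega`` trigger integration.
    delta
        Second-stage interaction Δ = E[W2 | no integration] − E[W2 |
        integration] (ms). Positive values are facilitation, negative
        inhibition; no clamping is applied anywhere.
    mu
        Baseline mean second-stage duration μ = E[W2 | no integration]
        (ms, > 0).
    sigma
        Second-stage standard deviation (ms, >= 0). Consumed only by the
        simulator; no closed-form mean or enhancement depends on it.
    soa
        Stimulus onset asynchrony of the auditory (non-target, in the
        default FAP) stimulus relative to the visual one (ms). Simulation
        only: the closed forms hold at simultaneity and refuse soa != 0.
    """

    lambda_v: float
    lambda_a: float
    omega: float
    delta: float = 0.0
    mu: float = 100.0
    sigma: float = 10.0
    soa: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_v", "lambda_a", "mu"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise TwinConfigError(f"{name} must be finite and > 0, got {v!r}")
        if not (math.isfinite(self.omega) and self.omega >= 0):
            raise TwinConfigError(f"omega must be finite and >= 0, got {self.omega!r}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise TwinConfigError(f"sigma must be finite and >= 0, got {self.sigma!r}")
        if not math.isfinite(self.delta):
            raise TwinConfigError(f"delta must be finite, got {self.delta!r}")
        if not math.isfinite(self.soa):
            raise TwinConfigError(f"soa must be finite, got {self.soa!r}")

    def require_simultaneous(self) -> None:
        """Guard used by every closed-form operation."""
        if self.soa != 0.0:
            raise SOANotSupportedError(
                "closed-form predictions hold at soa = 0 only; "
                f"got soa = {self.soa} ms (use the simulator for soa != 0)"
            )

    def rate(self, modality: Modality | str) -> float:
        modality = Modality(modality)
        return self.lambda_v if modality is Modality.VISUAL else self.lambda_a

    def target_rates(self, paradigm: Paradigm) -> tuple[float, float]:
        """(target rate, non-target rate) for FAP; (λ_V, λ_A) for CSP."""
        if paradigm.is_fap and paradigm.target_modality is Modality.AUDITORY:
            return self.lambda_a, self.lambda_v
        return self.lambda_v, self.lambda_a

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TwinParams":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise TwinConfigError(f"unknown TwinParams fields: {sorted(extra)}")
        return cls(**d)


def matched_rate(params: TwinParams, rtol: float = 1e-12) -> float | None:
    """Return the common rate if λ_V and λ_A are equal to relative
    tolerance ``rtol``, else None. Matched-intensity identities (the
    factor-of-two law, the simplified enhancement forms) apply only then."""
    hi = max(params.lambda_v, params.lambda_a)
    if abs(params.lambda_v - params.lambda_a) / hi <= rtol:
        return 0.5 * (params.lambda_v + params.lambda_a)
    return None
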