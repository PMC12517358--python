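"""Synthetic observer: trial-level data with the generative structure the
analysis assumes.

Each trial draws a uniformly random target orientation (the Landolt-C gap is
a full-circle variable) and, on flanked trials, a fair clockwise/anticlockwise
flanker direction.  The report error is drawn, in flanker-positive sign
space, from the three-component mixture the pooling model fits: a uniform
lapse component with probability ``w_random``, otherwise a target-centered
von Mises with probability ``w_target`` or a flanker-centered von Mises at
the condition's orientation difference.  ``w_target`` follows a ground-truth
logistic spatial profile in target-flanker spacing, so recovering that
profile end-to-end is a well-posed parameter-recovery experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import DesignGrid, StimulusCondition
from .errors import compute_signed_error, wrap_signed
from .profile import logistic_p_target

__all__ = [
    "ProfileTruth",
    "ObserverParams",
    "TrialRecord",
    "sample_trial",
    "simulate_session",
]

#: Ground-truth transition-zone span, as a fraction of eccentricity, for each
#: orientation difference: spans shrink as target-flanker similarity drops.
DEFAULT_SPAN_FRACTIONS: Mapping[float, float] = {
    22.5: 0.45,
    45.0: 0.35,
    90.0: 0.22,
    180.0: 0.15,
}
#: Ground-truth spatial-profile midpoint as a fraction of eccentricity.
DEFAULT_MIDPOINT_FRACTION = 0.33

_2LN15 = 2.0 * math.log(1.5)  # span = 2 G ln 1.5 for the logistic


@dataclass(frozen=True)
class ProfileTruth:
    """Ground-truth logistic spatial profile: midpoint L and gradient G (deg)."""

    location: float
    gradient: float

    def __post_init__(self) -> None:
        if self.gradient <= 0:
            raise ValueError("gradient must be > 0")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic observer.

    ``profile`` maps ``(eccentricity, orientation_difference)`` to the
    ground-truth logistic governing the target-component weight as a function
    of spacing.  Concentrations are for the 360-degree-period von Mises.
    """

    w_random: float = 0.05
    kappa_target: float = 20.0
    kappa_flanker: float = 20.0
    mu_target: float = 0.0
    kappa_unflanked: float = 30.0
    profile: Mapping[tuple[float, float], ProfileTruth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_random <= 1.0:
            raise ValueError("w_random must be in [0, 1]")
        for name in ("kappa_target", "kappa_flanker", "kappa_unflanked"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -10.0 <= self.mu_target <= 10.0:
            raise ValueError("mu_target must be in [-10, 10]")

    @classmethod
    def study_defaults(
        cls,
        eccentricities: Sequence[float] = (4.24, 12.72, 21.2),
        orientation_differences: Sequence[float] = (22.5, 45.0, 90.0, 180.0),
        midpoint_fraction: float = DEFAULT_MIDPOINT_FRACTION,
        span_fractions: Mapping[float, float] = DEFAULT_SPAN_FRACTIONS,
        **overrides,
    ) -> "ObserverParams":
        """Defaults emulating the study conditions.

        Midpoints at ``midpoint_fraction * E`` and spans declining with
        orientation difference; gradient G = span / (2 ln 1.5).
        """
        profile = {
            (e, od): ProfileTruth(
                location=midpoint_fraction * e,
                gradient=span_fractions[od] * e / _2LN15,
            )
            for e in eccentricities
            for od in orientation_differences
        }
        return cls(profile=profile, **overrides)

    def true_w_target(self, condition: StimulusCondition) -> float:
        """Ground-truth target-component weight for a flanked condition."""
        key = (condition.eccentricity, condition.orientation_difference)
        try:
            truth = self.profile[key]
        except KeyError:
            raise KeyError(
                f"no ground-truth profile for eccentricity "
                f"{condition.eccentricity}, orientation difference "
                f"{condition.orientation_difference}"
            ) from None
        return logistic_p_target(condition.spacing, truth.location, truth.gradient)


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation and its continuous orientation report."""

    participant: str
    condition: StimulusCondition
    target_orientation: float
    flanker_sign: int | None
    response_orientation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_orientation < 360.0:
            raise ValueError("target_orientation must be in [0, 360)")
        if not 0.0 <= self.response_orientation < 360.0:
            raise ValueError("response_orientation must be in [0, 360)")
        if (self.flanker_sign is None) != self.condition.is_unflanked:
            raise ValueError(
                "flanker_sign must be absent exactly when the condition is unflanked"
            )
        if self.flanker_sign is not None and self.flanker_sign not in (1, -1):
            raise ValueError("flanker_sign must be +1 or -1")

    @property
    def signed_error(self) -> float:
        """Signed report error (deg) with the flanker-positive convention."""
        return compute_signed_error(
            self.target_orientation, self.response_orientation, self.flanker_sign
        )


def _sample_error(
    condition: StimulusCondition, params: ObserverParams, rng: np.random.Generator
) -> float:
    """Draw one report error (deg) in flanker-positive sign space."""
    if rng.uniform() < params.w_random:
        return 180.0 - rng.uniform(0.0, 360.0)  # uniform on (-180, 180]
    if condition.is_unflanked:
        mu, kappa = params.mu_target, params.kappa_unflanked
    elif rng.uniform() < params.true_w_target(condition):
        mu, kappa = params.mu_target, params.kappa_target
    else:
        mu, kappa = condition.orientation_difference, params.kappa_flanker
    return wrap_signed(math.degrees(rng.vonmises(math.radians(mu), kappa)))


def sample_trial(
    condition: StimulusCondition,
    params: ObserverParams,
    rng: np.random.Generator,
    participant: str = "sim01",
) -> TrialRecord:
    """Draw one trial: target orientation, flanker direction, and response.

    The error is drawn in flipped-sign (flanker-positive) space and the
    flanker direction is undone when placing the response on the circle, so
    ``TrialRecord.signed_error`` recovers the drawn error exactly.
    """
    target = rng.uniform(0.0, 360.0)
    if condition.is_unflanked:
        sign: int | None = None
    else:
        sign = 1 if rng.uniform() < 0.5 else -1
    e = _sample_error(condition, params, rng)
    response = (target + (sign if sign is not None else 1) * e) % 360.0
    return TrialRecord(
        participant=participant,
        condition=condition,
        target_orientation=target,
        flanker_sign=sign,
        response_orientation=response,
    )


def simulate_session(
    design: DesignGrid,
    params: ObserverParams,
    seed: int | np.random.SeedSequence,
    participant: str = "sim01",
) -> list[TrialRecord]:
    """Simulate one session: ``trials_planned`` records per condition.

    All random draws come from a single stream seeded by ``seed``, in
    condition-then-trial order, so a session is reproducible from
    ``(design, params, seed)``.  The assembled records are then shuffled
    (with the same stream) to mirror randomized presentation order within
    the session.
    """
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for condition in design.conditions:
        for _ in range(condition.trials_planned):
            records.append(sample_trial(condition, params, rng, participant))
    order = rng.permutation(len(records))
    return [records[i] for i in order]
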