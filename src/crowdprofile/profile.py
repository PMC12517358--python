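"""Logistic spatial profiles of crowding.

The proportion of non-random responses centered on the target, p(Target),
rises with target-flanker spacing S.  That rise is modelled by a two-parameter
logistic

    p(S) = 1 / (1 + exp(-(S - L) / G))

whose location L (the midpoint, deg) is the spacing where target- and
flanker-centered responses are balanced, and whose gradient G (deg) sets the
steepness.  The transition-zone span is the spacing difference between
p = 0.4 and p = 0.6, which for this logistic is exactly 2 G ln(1.5).
Points are weighted by the inverse SSE of the pooling fit they came from, and
spatial quantities can be expressed in Bouma units (spacing / eccentricity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ProfilePoint",
    "SpatialProfileFit",
    "UnderdeterminedFitError",
    "logistic_p_target",
    "invert_logistic",
    "span_of",
    "to_bouma",
    "r_squared",
    "SpatialProfileModel",
    "fit_profile",
]

SPAN_FACTOR = 2.0 * math.log(1.5)  # span = 2 G ln 1.5
#: Floor applied to pooling-fit SSEs before inverting into weights, so a
#: numerically perfect pooling fit cannot dominate with infinite weight.
DEFAULT_WEIGHT_FLOOR = 1e-8


class UnderdeterminedFitError(ValueError):
    """Raised when too few distinct spacings are available to fit a profile."""


def logistic_p_target(spacing: float, location: float, gradient: float):
    """p(Target) predicted at a spacing; increasing in spacing, 0.5 at L.

    Raises
    ------
    ValueError
        If ``gradient <= 0``.
    """
    if gradient <= 0:
        raise ValueError(f"gradient must be > 0, got {gradient}")
    s = np.asarray(spacing, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates p at 0 exactly
        out = 1.0 / (1.0 + np.exp(-(s - location) / gradient))
    return float(out) if out.ndim == 0 else out


def invert_logistic(p: float, location: float, gradient: float) -> float:
    """Spacing at which the logistic reaches probability ``p`` in (0, 1)."""
    if gradient <= 0:
        raise ValueError(f"gradient must be > 0, got {gradient}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be strictly inside (0, 1), got {p}")
    return location + gradient * math.log(p / (1.0 - p))


def span_of(location: float, gradient: float) -> float:
    """Transition-zone span: spacing difference between p = 0.6 and p = 0.4.

    Equals ``2 * G * ln(1.5)``; independent of the midpoint, linear in the
    gradient, so shallower profiles have wider transition zones.
    """
    return invert_logistic(0.6, location, gradient) - invert_logistic(
        0.4, location, gradient
    )


def to_bouma(spacing: float, eccentricity: float) -> float:
    """Express a spacing as a fraction of target eccentricity (Bouma units)."""
    if eccentricity <= 0:
        raise ValueError(f"eccentricity must be > 0, got {eccentricity}")
    return spacing / eccentricity


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST (unweighted).

    SST is the total sum of squares around the mean of ``observed``.  May be
    negative when the model describes the data more poorly than a flat line
    through the mean.  Returns NaN when all observed values are equal
    (zero SST leaves the ratio undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same shape")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - pred) ** 2))
    if sst == 0.0:
        return float("nan")
    return 1.0 - sse / sst


@dataclass(frozen=True)
class ProfilePoint:
    """One p(Target) estimate at one spacing, with its fit-quality weight."""

    spacing: float
    p_target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_target <= 1.0:
            raise ValueError("p_target must be in [0, 1]")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class SpatialProfileFit:
    """Fitted spatial profile for one (participant, eccentricity, Delta)."""

    location: float
    gradient: float
    span: float
    r_squared: float
    eccentricity: float
    orientation_difference: float | None
    midpoint_bouma: float
    span_bouma: float
    sse: float
    flags: tuple[str, ...] = ()

    def predict(self, spacing):
        return logistic_p_target(spacing, self.location, self.gradient)


class SpatialProfileModel(RegressorMixin, BaseEstimator):
    """Weighted nonlinear least-squares fit of the logistic spatial profile.

    Parameters
    ----------
    eccentricity : float
        Target eccentricity (deg).  The midpoint is capped at this value.
    gradient_max : float or None
        Upper bound on the gradient; defaults to ``2 * eccentricity`` to
        prevent degenerate, perfectly flat fits.
    n_starts : int
        Size (per axis, roughly) of the deterministic multi-start grid.

    Attributes
    ----------
    location_, gradient_ : float
        Fitted midpoint and gradient (deg).
    span_, midpoint_bouma_, span_bouma_ : float
        Derived transition-zone span and Bouma-unit conversions.
    r_squared_ : float
        Unweighted 1 - SSE/SST of the fit.
    sse_ : float
        Weighted sum of squared errors actually minimised.
    flags_ : tuple of str
        Diagnostic flags (boundary-pinned parameters, one-sided data, ...).
    """

    _BOUND_TOL = 1e-6

    def __init__(self, eccentricity: float = 12.72, gradient_max: float | None = None):
        self.eccentricity = eccentricity
        self.gradient_max = gradient_max

    def _bounds(self):
        g_max = (
            2.0 * self.eccentricity if self.gradient_max is None else self.gradient_max
        )
        lo = np.array([1e-6, 1e-6])
        hi = np.array([self.eccentricity, g_max])
        return lo, hi

    def fit(self, X, y, sample_weight=None):
        """Fit to spacings ``X`` (deg) and p(Target) values ``y``.

        ``sample_weight`` carries the 1/SSE weights of the source pooling
        fits; unweighted if omitted.
        """
        if self.eccentricity <= 0:
            raise ValueError("eccentricity must be > 0")
        S = np.asarray(X, dtype=float).reshape(-1)
        p = np.asarray(y, dtype=float).reshape(-1)
        if S.shape != p.shape:
            raise ValueError("X and y must have the same length")
        w = (
            np.ones_like(p)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).reshape(-1)
        )
        if w.shape != p.shape:
            raise ValueError("sample_weight must match y in length")
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
        if len(np.unique(S)) < 3:
            raise UnderdeterminedFitError(
                "need at least 3 distinct spacings to fit location and gradient"
            )
        sqw = np.sqrt(w)
        lo, hi = self._bounds()

        def residuals(theta):
            L, G = theta
            with np.errstate(over="ignore"):
                return sqw * (p - 1.0 / (1.0 + np.exp(-(S - L) / G)))

        best = None
        for L0 in (0.2, 0.4, 0.6, 0.8):
            for G0 in (0.05, 0.15, 0.45):
                x0 = np.clip(
                    [L0 * self.eccentricity, G0 * self.eccentricity], lo, hi
                )
                res = least_squares(
                    residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                )
                sse = float(np.sum(res.fun**2))
                if best is None or sse < best[0]:
                    best = (sse, res.x)
        self.sse_, (self.location_, self.gradient_) = best[0], tuple(best[1])

        flags = []
        for name, val, l, h in (
            ("location", self.location_, lo[0], hi[0]),
            ("gradient", self.gradient_, lo[1], hi[1]),
        ):
            if val - l < self._BOUND_TOL:
                flags.append(f"{name}_at_lower_bound")
            elif h - val < self._BOUND_TOL * max(1.0, h):
                flags.append(f"{name}_at_upper_bound")
        if np.all(p > 0.5) or np.all(p < 0.5):
            flags.append("one_sided_data")
        if len(p) >= 2 and np.polyfit(S, p, 1)[0] < 0:
            flags.append("inverted_trend")
        self.flags_ = tuple(flags)

        self.span_ = span_of(self.location_, self.gradient_)
        self.midpoint_bouma_ = to_bouma(self.location_, self.eccentricity)
        self.span_bouma_ = to_bouma(self.span_, self.eccentricity)
        self.r_squared_ = r_squared(p, self.predict(S)) if len(p) >= 2 else float("nan")
        if np.isnan(self.r_squared_):
            self.flags_ = self.flags_ + ("zero_sst",)
        return self

    def predict(self, X):
        S = np.asarray(X, dtype=float).reshape(-1)
        return logistic_p_target(S, self.location_, self.gradient_)


def fit_profile(
    points: Sequence[ProfilePoint],
    eccentricity: float,
    orientation_difference: float | None = None,
) -> SpatialProfileFit:
    """Fit the weighted logistic profile to p(Target)-vs-spacing points."""
    model = SpatialProfileModel(eccentricity=eccentricity)
    model.fit(
        [pt.spacing for pt in points],
        [pt.p_target for pt in points],
        sample_weight=[pt.weight for pt in points],
    )
    return SpatialProfileFit(
        location=model.location_,
        gradient=model.gradient_,
        span=model.span_,
        r_squared=model.r_squared_,
        eccentricity=eccentricity,
        orientation_difference=orientation_difference,
        midpoint_bouma=model.midpoint_bouma_,
        span_bouma=model.span_bouma_,
        sse=model.sse_,
        flags=model.flags_,
    )
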