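"""Signed response errors and 72-bin circular error histograms.

Report errors are the circular difference between the reported and presented
gap orientation, re-signed on flanked trials so that errors toward the
flanker orientation are positive (clockwise flankers leave clockwise-positive
errors unchanged; anticlockwise flankers flip the sign).  Errors live on the
half-open interval (-180, 180] and are tallied into 72 five-degree bins with
centers -175, -170, ..., 180.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .design import StimulusCondition

__all__ = [
    "BIN_CENTERS",
    "BIN_WIDTH_DEG",
    "N_BINS",
    "ErrorDistribution",
    "wrap_signed",
    "compute_signed_error",
    "bin_index",
    "bin_errors",
    "distributions_from_trials",
]

BIN_WIDTH_DEG = 5.0
#: The 72 bin centers: -175, -170, ..., 175, 180 (the wrap point is 180, not -180).
BIN_CENTERS = np.arange(-175.0, 180.0 + BIN_WIDTH_DEG / 2, BIN_WIDTH_DEG)
N_BINS = len(BIN_CENTERS)
assert N_BINS == 72


def wrap_signed(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = angle % 360.0
    if a > 180.0:
        a -= 360.0
    return a


def compute_signed_error(
    target_orientation: float,
    response_orientation: float,
    flanker_sign: int | None = None,
) -> float:
    """Signed report error in degrees, in (-180, 180].

    The raw error is ``response - target`` wrapped into (-180, 180].  On
    flanked trials it is multiplied by ``flanker_sign`` (+1 for clockwise
    flankers, -1 for anticlockwise), so positive errors always point toward
    the flanker orientation.  If the flip lands exactly on -180 it is mapped
    to +180 (the two are the same direction).
    """
    raw = wrap_signed(response_orientation - target_orientation)
    if flanker_sign is None:
        return raw
    if flanker_sign not in (1, -1):
        raise ValueError(f"flanker_sign must be +1 or -1, got {flanker_sign}")
    e = flanker_sign * raw
    if e == -180.0:
        e = 180.0
    return e


def bin_index(error: float) -> int:
    """Index (0..71) of the 5-degree bin whose center is nearest ``error``.

    Half-way values (odd multiples of 2.5) round away from zero; -180 and
    +180 share the bin centered at +180.
    """
    # round-half-away-from-zero on error/5
    k = math.floor(abs(error) / BIN_WIDTH_DEG + 0.5)
    if error < 0:
        k = -k
    if k == -36:  # -180 is the same bin as +180
        k = 36
    return k + 35  # center -175 -> index 0, center 180 -> index 71


@dataclass(frozen=True)
class ErrorDistribution:
    """72-bin circular histogram of signed report errors for one condition."""

    probabilities: np.ndarray
    n_trials: int
    condition: StimulusCondition | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bin probabilities, got {p.shape}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("bin probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def bin_centers(self) -> np.ndarray:
        return BIN_CENTERS


def bin_errors(
    errors: Sequence[float], condition: StimulusCondition | None = None
) -> ErrorDistribution:
    """Tally signed errors (each in (-180, 180]) into the 72 bins.

    Each error is assigned to the nearest bin center under circular distance;
    probabilities are counts divided by the number of trials.

    Raises
    ------
    ValueError
        On empty input or errors outside (-180, 180].
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("cannot bin an empty collection of errors")
    if np.any(errors <= -180.0) or np.any(errors > 180.0):
        raise ValueError("errors must lie in (-180, 180]")
    counts = np.zeros(N_BINS)
    for e in errors:
        counts[bin_index(float(e))] += 1
    return ErrorDistribution(
        probabilities=counts / errors.size,
        n_trials=int(errors.size),
        condition=condition,
    )


def distributions_from_trials(trials: Iterable) -> dict[StimulusCondition, ErrorDistribution]:
    """Group trial records by condition and bin their signed errors.

    Accepts any iterable of records with ``condition`` and ``signed_error``
    attributes (e.g. :class:`~crowdprofile.observer.TrialRecord`).
    """
    by_condition: dict[StimulusCondition, list[float]] = {}
    for t in trials:
        by_condition.setdefault(t.condition, []).append(t.signed_error)
    return {
        cond: bin_errors(errs, condition=cond)
        for cond, errs in by_condition.items()
    }
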