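"""Experimental design grids and eccentricity-scaled stimulus geometry.

The study design crosses target eccentricity, target-flanker orientation
difference, and tangential center-to-center spacing, plus an unflanked
baseline condition at each eccentricity.  Stimulus (Landolt-C) diameter is
scaled with eccentricity so that acuity demands are roughly equated across
the visual field: a target at the reference eccentricity of 12.72 deg has a
diameter of 1.5 deg, and diameter grows linearly with eccentricity from a
foveal offset of 1.77 deg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ECCENTRICITY_OFFSET_DEG",
    "REFERENCE_DIAMETER_DEG",
    "REFERENCE_ECCENTRICITY_DEG",
    "InvalidDesignError",
    "StimulusCondition",
    "DesignGrid",
    "scaled_diameter",
    "default_spacings",
    "build_design",
    "design_to_frame",
    "design_from_frame",
    "write_design",
    "read_design",
]

#: Foveal offset (deg) of the linear diameter-vs-eccentricity scaling rule.
ECCENTRICITY_OFFSET_DEG = 1.77
#: Diameter (deg) of the reference target.
REFERENCE_DIAMETER_DEG = 1.5
#: Eccentricity (deg) at which the reference target has its reference diameter.
REFERENCE_ECCENTRICITY_DEG = 12.72

#: Orientation differences (deg) sampled in the study design.
STUDY_ORIENTATION_DIFFERENCES = (22.5, 45.0, 90.0, 180.0)
#: Eccentricities (deg) sampled in the study design.
STUDY_ECCENTRICITIES = (4.24, 12.72, 21.2)


class InvalidDesignError(ValueError):
    """Raised when a requested condition grid is geometrically impossible."""


def scaled_diameter(eccentricity: float) -> float:
    """Stimulus diameter (deg) at a given eccentricity (deg).

    Linear scaling ``(E + 1.77) * 1.5 / (12.72 + 1.77)``; the target is
    1.5 deg across at 12.72 deg eccentricity and grows with E.

    Raises
    ------
    ValueError
        If ``eccentricity`` is negative.
    """
    if eccentricity < 0:
        raise ValueError(f"eccentricity must be >= 0, got {eccentricity}")
    return (
        (eccentricity + ECCENTRICITY_OFFSET_DEG)
        * REFERENCE_DIAMETER_DEG
        / (REFERENCE_ECCENTRICITY_DEG + ECCENTRICITY_OFFSET_DEG)
    )


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the design.

    ``orientation_difference`` and ``spacing`` are both ``None`` for the
    unflanked (target-alone) condition.  ``spacing`` is the tangential
    center-to-center target-flanker separation in deg of visual angle and can
    never be smaller than the stimulus diameter (flankers at minimum are just
    touching the target).
    """

    eccentricity: float
    orientation_difference: float | None
    spacing: float | None
    diameter: float
    trials_planned: int

    def __post_init__(self) -> None:
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")
        if (self.orientation_difference is None) != (self.spacing is None):
            raise InvalidDesignError(
                "unflanked conditions have neither orientation_difference nor "
                "spacing; flanked conditions need both"
            )
        expected = scaled_diameter(self.eccentricity)
        if abs(self.diameter - expected) > 1e-12:
            raise InvalidDesignError(
                f"diameter {self.diameter} does not match the eccentricity "
                f"scaling rule ({expected})"
            )
        if self.spacing is not None and self.spacing < self.diameter - 1e-12:
            raise InvalidDesignError(
                f"spacing {self.spacing} is below the stimulus diameter "
                f"{self.diameter}: flankers would overlap the target"
            )
        if self.trials_planned <= 0:
            raise ValueError("trials_planned must be a positive integer")

    @property
    def is_unflanked(self) -> bool:
        return self.orientation_difference is None


@dataclass(frozen=True)
class DesignGrid:
    """Ordered collection of stimulus conditions forming one session design."""

    conditions: tuple[StimulusCondition, ...]
    eccentricities: tuple[float, ...]
    label: str = ""

    @property
    def total_trials(self) -> int:
        return sum(c.trials_planned for c in self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    @staticmethod
    def combine(grids: Iterable["DesignGrid"], label: str = "") -> "DesignGrid":
        """Concatenate per-eccentricity grids into one multi-location design."""
        conditions: list[StimulusCondition] = []
        eccs: list[float] = []
        for g in grids:
            conditions.extend(g.conditions)
            for e in g.eccentricities:
                if e not in eccs:
                    eccs.append(e)
        return DesignGrid(tuple(conditions), tuple(eccs), label=label)


def default_spacings(
    eccentricity: float, n: int = 5, max_fraction: float = 0.8
) -> np.ndarray:
    """Default tangential spacing grid (deg) at one eccentricity.

    ``n`` values linearly spaced from the just-touching separation (one
    stimulus diameter) out to ``max_fraction * eccentricity``, spanning the
    crowding zone (whose midpoint sits near a third of the eccentricity).
    """
    lo = scaled_diameter(eccentricity)
    hi = max_fraction * eccentricity
    if hi < lo:
        raise InvalidDesignError(
            f"outermost spacing {hi} is below the touching separation {lo}"
        )
    return np.linspace(lo, hi, n)


def build_design(
    eccentricity: float,
    orientation_differences: Sequence[float] = STUDY_ORIENTATION_DIFFERENCES,
    spacings: Sequence[float] | None = None,
    trials_per_condition: int = 150,
    include_unflanked: bool = True,
    label: str = "",
) -> DesignGrid:
    """Build the full condition grid at one eccentricity.

    Returns ``len(orientation_differences) * len(spacings)`` flanked
    conditions (every combination), plus one unflanked condition when
    ``include_unflanked``.  With the study defaults (4 orientation
    differences, 5 spacings, unflanked) this gives 21 conditions.

    Raises
    ------
    InvalidDesignError
        If any spacing is smaller than the scaled stimulus diameter, or if
        orientation differences are given without spacings.
    """
    orientation_differences = tuple(orientation_differences)
    if spacings is None:
        spacings = default_spacings(eccentricity) if orientation_differences else ()
    spacings = tuple(float(s) for s in spacings)
    if orientation_differences and not spacings:
        raise InvalidDesignError(
            "flanked conditions requested but no spacings were given"
        )
    diameter = scaled_diameter(eccentricity)
    for s in spacings:
        if s < diameter - 1e-12:
            raise InvalidDesignError(
                f"spacing {s} is below the stimulus diameter {diameter}"
            )
    conditions = [
        StimulusCondition(
            eccentricity=eccentricity,
            orientation_difference=od,
            spacing=s,
            diameter=diameter,
            trials_planned=trials_per_condition,
        )
        for od in orientation_differences
        for s in spacings
    ]
    if include_unflanked:
        conditions.append(
            StimulusCondition(
                eccentricity=eccentricity,
                orientation_difference=None,
                spacing=None,
                diameter=diameter,
                trials_planned=trials_per_condition,
            )
        )
    return DesignGrid(tuple(conditions), (eccentricity,), label=label)


# ---------------------------------------------------------------------------
# Tabular serialization (one row per condition)
# ---------------------------------------------------------------------------

def design_to_frame(grid: DesignGrid) -> pd.DataFrame:
    rows = [
        {
            "eccentricity_deg": c.eccentricity,
            "orientation_diff_deg": c.orientation_difference,
            "spacing_deg": c.spacing,
            "diameter_deg": c.diameter,
            "trials_planned": c.trials_planned,
        }
        for c in grid.conditions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "eccentricity_deg",
            "orientation_diff_deg",
            "spacing_deg",
            "diameter_deg",
            "trials_planned",
        ],
    )


def design_from_frame(frame: pd.DataFrame, label: str = "") -> DesignGrid:
    conditions = []
    for _, row in frame.iterrows():
        od = row["orientation_diff_deg"]
        sp = row["spacing_deg"]
        od = None if pd.isna(od) else float(od)
        sp = None if pd.isna(sp) else float(sp)
        conditions.append(
            StimulusCondition(
                eccentricity=float(row["eccentricity_deg"]),
                orientation_difference=od,
                spacing=sp,
                diameter=float(row["diameter_deg"]),
                trials_planned=int(row["trials_planned"]),
            )
        )
    eccs = tuple(dict.fromkeys(c.eccentricity for c in conditions))
    return DesignGrid(tuple(conditions), eccs, label=label)


def lossless_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV whose floats survive a read round-trip bit-for-bit."""
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def write_design(grid: DesignGrid, path: str | Path) -> None:
    lossless_csv(design_to_frame(grid), path)


def read_design(path: str | Path, label: str = "") -> DesignGrid:
    return design_from_frame(
        pd.read_csv(path, float_precision="round_trip"), label=label
    )
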