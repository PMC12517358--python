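"""End-to-end pipeline: simulate (or load) trials, bin errors, fit pooling
models per condition, and fit one spatial profile per orientation difference.

For each (participant, eccentricity) the unflanked condition is fit first;
its concentration bounds every flanked pooling fit at that eccentricity.
Each flanked fit contributes one p(Target) point, weighted by the inverse of
its SSE, to the logistic spatial-profile fit of its orientation difference.
Given the same resolved configuration and seed, two runs produce identical
output tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    STUDY_ECCENTRICITIES,
    STUDY_ORIENTATION_DIFFERENCES,
    DesignGrid,
    StimulusCondition,
    build_design,
    default_spacings,
    lossless_csv,
    scaled_diameter,
)
from .errors import distributions_from_trials
from .observer import ObserverParams, TrialRecord, simulate_session
from .pooling import PoolingFit, UnflankedFit, fit_pooling, fit_unflanked
from .profile import DEFAULT_WEIGHT_FLOOR, ProfilePoint, SpatialProfileFit, fit_profile

__all__ = [
    "RunConfig",
    "RunResult",
    "TrialTableError",
    "run_pipeline",
    "fit_trials",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = [
    "participant",
    "eccentricity_deg",
    "orientation_diff_deg",
    "spacing_deg",
    "flanker_sign",
    "target_orientation_deg",
    "response_orientation_deg",
]

#: Trials per condition in the study design: 150 at the original 12.72 deg
#: eccentricity, 80 at the two later-added eccentricities.
STUDY_TRIALS_PER_CONDITION: Mapping[float, int] = {4.24: 80, 12.72: 150, 21.2: 80}


class TrialTableError(ValueError):
    """Raised when a trial table violates the tabular schema."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    eccentricities: tuple[float, ...] = STUDY_ECCENTRICITIES
    orientation_differences: tuple[float, ...] = STUDY_ORIENTATION_DIFFERENCES
    n_spacings: int = 5
    spacing_max_fraction: float = 0.8
    spacings: Mapping[float, tuple[float, ...]] | None = None
    trials_per_condition: int | Mapping[float, int] = field(
        default_factory=lambda: dict(STUDY_TRIALS_PER_CONDITION)
    )
    include_unflanked: bool = True
    participants: tuple[str, ...] = ("sim01",)
    observer: Mapping | None = None
    seed: int = 0
    trials_path: str | None = None
    weight_floor: float = DEFAULT_WEIGHT_FLOOR

    def n_trials(self, eccentricity: float) -> int:
        if isinstance(self.trials_per_condition, Mapping):
            return int(self.trials_per_condition[eccentricity])
        return int(self.trials_per_condition)

    def spacings_at(self, eccentricity: float) -> tuple[float, ...]:
        if self.spacings is not None and eccentricity in self.spacings:
            return tuple(self.spacings[eccentricity])
        return tuple(
            default_spacings(
                eccentricity, n=self.n_spacings, max_fraction=self.spacing_max_fraction
            )
        )

    def design_at(self, eccentricity: float) -> DesignGrid:
        return build_design(
            eccentricity,
            self.orientation_differences,
            self.spacings_at(eccentricity),
            self.n_trials(eccentricity),
            include_unflanked=self.include_unflanked,
        )

    def observer_params(self) -> ObserverParams:
        overrides = dict(self.observer or {})
        return ObserverParams.study_defaults(
            eccentricities=self.eccentricities,
            orientation_differences=self.orientation_differences,
            **overrides,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["trials_per_condition"], Mapping):
            d["trials_per_condition"] = {
                str(k): v for k, v in d["trials_per_condition"].items()
            }
        if d["spacings"] is not None:
            d["spacings"] = {str(k): list(v) for k, v in d["spacings"].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key in ("eccentricities", "orientation_differences", "participants"):
            if key in d:
                d[key] = tuple(d[key])
        tpc = d.get("trials_per_condition")
        if isinstance(tpc, Mapping):
            d["trials_per_condition"] = {float(k): int(v) for k, v in tpc.items()}
        sp = d.get("spacings")
        if isinstance(sp, Mapping):
            d["spacings"] = {float(k): tuple(v) for k, v in sp.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunResult:
    """All artifacts of one pipeline run, as tidy tables."""

    trials: pd.DataFrame
    distributions: pd.DataFrame
    pooling_fits: pd.DataFrame
    profile_fits: pd.DataFrame
    metadata: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lossless_csv(self.trials, outdir / "trials.csv")
        lossless_csv(self.distributions, outdir / "distributions.csv")
        lossless_csv(self.pooling_fits, outdir / "pooling_fits.csv")
        lossless_csv(self.profile_fits, outdir / "profile_fits.csv")
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Trial-table IO
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "participant": t.participant,
            "eccentricity_deg": t.condition.eccentricity,
            "orientation_diff_deg": t.condition.orientation_difference,
            "spacing_deg": t.condition.spacing,
            "flanker_sign": t.flanker_sign,
            "target_orientation_deg": t.target_orientation,
            "response_orientation_deg": t.response_orientation,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    lossless_csv(trials_to_frame(trials), path)


def trials_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns: {missing}")
    if len(frame) == 0:
        raise TrialTableError("trial table is empty")

    # First pass: group rows into conditions so trials_planned = observed count.
    def _key(row):
        od = row["orientation_diff_deg"]
        sp = row["spacing_deg"]
        return (
            float(row["eccentricity_deg"]),
            None if pd.isna(od) else float(od),
            None if pd.isna(sp) else float(sp),
        )

    counts: dict[tuple, int] = {}
    for _, row in frame.iterrows():
        k = _key(row)
        counts[k] = counts.get(k, 0) + 1

    conditions: dict[tuple, StimulusCondition] = {}
    problems: list[str] = []
    for k, n in counts.items():
        ecc, od, sp = k
        try:
            conditions[k] = StimulusCondition(
                eccentricity=ecc,
                orientation_difference=od,
                spacing=sp,
                diameter=scaled_diameter(ecc),
                trials_planned=n,
            )
        except ValueError as exc:
            problems.append(f"condition {k}: {exc}")

    records: list[TrialRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        line = i + 2  # header is line 1
        k = _key(row)
        if k not in conditions:
            continue  # condition-level problem already recorded
        sign = row["flanker_sign"]
        sign = None if pd.isna(sign) else int(sign)
        try:
            records.append(
                TrialRecord(
                    participant=str(row["participant"]),
                    condition=conditions[k],
                    target_orientation=float(row["target_orientation_deg"]),
                    flanker_sign=sign,
                    response_orientation=float(row["response_orientation_deg"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise TrialTableError(
            "malformed trial table:\n  " + "\n  ".join(problems)
        )
    return records


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial table; malformed rows are reported with line numbers."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"{path} is empty") from None
    return trials_from_frame(frame)


# ---------------------------------------------------------------------------
# Fitting stages
# ---------------------------------------------------------------------------

def fit_trials(
    trials: Sequence[TrialRecord], weight_floor: float = DEFAULT_WEIGHT_FLOOR
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the two fitting stages over a trial collection.

    Returns (distributions, pooling_fits, profile_fits) tidy frames.  The
    pooling-fit table also carries the unflanked fits (empty orientation
    difference and spacing).

    Raises
    ------
    ValueError
        If any (participant, eccentricity) group lacks an unflanked
        condition: its fitted concentration defines the flanked bounds.
    """
    by_group: dict[tuple[str, float], list[TrialRecord]] = {}
    for t in trials:
        by_group.setdefault((t.participant, t.condition.eccentricity), []).append(t)

    dist_rows, pool_rows, prof_rows = [], [], []
    for (participant, ecc) in sorted(by_group):
        group = by_group[(participant, ecc)]
        dists = distributions_from_trials(group)
        unflanked = [c for c in dists if c.is_unflanked]
        if not unflanked:
            raise ValueError(
                f"participant {participant} at {ecc} deg has no unflanked "
                "condition; the concentration bound of the pooling fits is "
                "undefined"
            )
        ufit = fit_unflanked(dists[unflanked[0]])
        pool_rows.append(
            _pooling_row(participant, ecc, None, None, ufit=ufit)
        )
        flanked = sorted(
            (c for c in dists if not c.is_unflanked),
            key=lambda c: (c.orientation_difference, c.spacing),
        )
        fits: dict[float, list[PoolingFit]] = {}
        for cond in flanked:
            pfit = fit_pooling(dists[cond], kappa_unflanked=ufit.kappa)
            fits.setdefault(cond.orientation_difference, []).append(pfit)
            pool_rows.append(
                _pooling_row(
                    participant, ecc, cond.orientation_difference, cond.spacing,
                    pfit=pfit,
                )
            )
        for cond in sorted(dists, key=_cond_sort_key):
            d = dists[cond]
            for center, prob in zip(d.bin_centers, d.probabilities):
                dist_rows.append(
                    {
                        "participant": participant,
                        "eccentricity_deg": ecc,
                        "orientation_diff_deg": cond.orientation_difference,
                        "spacing_deg": cond.spacing,
                        "bin_center_deg": center,
                        "probability": prob,
                        "n_trials": d.n_trials,
                    }
                )
        for od in sorted(fits):
            points = [
                ProfilePoint(
                    spacing=f.condition.spacing,
                    p_target=f.p_target,
                    weight=1.0 / max(f.sse, weight_floor),
                )
                for f in fits[od]
            ]
            prof = fit_profile(points, eccentricity=ecc, orientation_difference=od)
            prof_rows.append(_profile_row(participant, prof))

    return (
        pd.DataFrame(dist_rows),
        pd.DataFrame(pool_rows),
        pd.DataFrame(prof_rows),
    )


def _cond_sort_key(c: StimulusCondition):
    return (
        c.is_unflanked,
        c.orientation_difference if c.orientation_difference is not None else -1.0,
        c.spacing if c.spacing is not None else -1.0,
    )


def _pooling_row(
    participant: str,
    ecc: float,
    od: float | None,
    spacing: float | None,
    pfit: PoolingFit | None = None,
    ufit: UnflankedFit | None = None,
) -> dict:
    row = {
        "participant": participant,
        "eccentricity_deg": ecc,
        "orientation_diff_deg": od,
        "spacing_deg": spacing,
    }
    if ufit is not None:
        row.update(
            kind="unflanked", w_random=np.nan, w_target=np.nan, p_target=np.nan,
            mu_target=ufit.mu, kappa_target=ufit.kappa, kappa_flanker=np.nan,
            sse=ufit.sse, flags="|".join(ufit.flags),
        )
    else:
        row.update(
            kind="pooling", w_random=pfit.w_random, w_target=pfit.w_target,
            p_target=pfit.p_target, mu_target=pfit.mu_target,
            kappa_target=pfit.kappa_target, kappa_flanker=pfit.kappa_flanker,
            sse=pfit.sse, flags="|".join(pfit.flags),
        )
    return row


def _profile_row(participant: str, prof: SpatialProfileFit) -> dict:
    return {
        "participant": participant,
        "eccentricity_deg": prof.eccentricity,
        "orientation_diff_deg": prof.orientation_difference,
        "location_deg": prof.location,
        "gradient_deg": prof.gradient,
        "span_deg": prof.span,
        "midpoint_bouma": prof.midpoint_bouma,
        "span_bouma": prof.span_bouma,
        "r_squared": prof.r_squared,
        "weighted_sse": prof.sse,
        "flags": "|".join(prof.flags),
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Simulate (or load) trials and run both fitting stages.

    With ``config.trials_path`` set, trials are read from that table instead
    of simulated.  Identical resolved config and seed give byte-identical
    output tables.
    """
    if config.trials_path is not None:
        trials = read_trials(config.trials_path)
    else:
        params = config.observer_params()
        root = np.random.SeedSequence(config.seed)
        children = iter(
            root.spawn(len(config.participants) * len(config.eccentricities))
        )
        trials = []
        for participant in config.participants:
            for ecc in config.eccentricities:
                trials.extend(
                    simulate_session(
                        config.design_at(ecc), params, next(children), participant
                    )
                )
    distributions, pooling_fits, profile_fits = fit_trials(
        trials, weight_floor=config.weight_floor
    )
    metadata = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_trials": len(trials),
        "version": __version__,
    }
    result = RunResult(
        trials=trials_to_frame(trials),
        distributions=distributions,
        pooling_fits=pooling_fits,
        profile_fits=profile_fits,
        metadata=metadata,
    )
    if outdir is not None:
        result.write(outdir)
    return result
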