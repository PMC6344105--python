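"""Domain types, validation and CSV/JSON IO for effortful free-choice datasets.

A dataset holds, per participant, likeability ratings of food items over three
rating sessions (R1, R2, R3) and the trials of two interleaved effort sessions
(E1, E2) in which each presented item had to be earned by squeezing a handgrip
above an imposed target force level (expressed as a fraction of the
participant's maximal force F_max, between 0.20 and 1.20).  Items rated but
never offered in the effort task ("excluded" items) serve as pure controls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("prefdrift")

RATING_COLUMNS = ["subject_id", "experiment", "item_id", "session", "rating", "excluded"]
TRIAL_COLUMNS = [
    "subject_id",
    "experiment",
    "session",
    "trial_index",
    "item_id",
    "target_level",
    "accepted",
    "success",
    "peak_force",
    "hand",
]

#: Participants with fewer accepted-but-failed trials than this cannot separate
#: the choice and success effects and are dropped from cohort analyses.
DEFAULT_MIN_FAILURES = 3


class SchemaError(ValueError):
    """A CSV file does not conform to the expected column schema."""


class ValidationError(ValueError):
    """A dataset violates one of the structural invariants."""


@dataclass(frozen=True)
class RatingObservation:
    """One likeability rating: item ``item_id`` in rating session 1-3."""

    subject_id: str
    item_id: str
    session: int
    rating: float
    excluded: bool = False


@dataclass(frozen=True)
class EffortTrial:
    """One effort-task trial.

    ``success`` is None iff the offer was declined; ``peak_force`` is None when
    no squeeze was produced.  Forces are fractions of F_max.
    """

    subject_id: str
    item_id: str
    session: int
    target_level: float
    accepted: bool
    success: bool | None
    peak_force: float | None
    experiment: int = 1


@dataclass
class SubjectDataset:
    """All behavioural data for one participant.

    ``ratings`` columns: item_id, session, rating, excluded.
    ``trials`` columns: session, trial_index, item_id, target_level, accepted,
    success (NaN when declined), peak_force (NaN when no squeeze), hand.
    ``item_partition`` maps ``presented`` / ``excluded_extreme`` /
    ``excluded_random`` to lists of item ids.
    """

    subject_id: str
    experiment: int
    ratings: pd.DataFrame
    trials: pd.DataFrame
    f_max: float = 1.0
    item_partition: dict = field(default_factory=dict)

    @property
    def presented_items(self) -> list:
        return list(self.item_partition.get("presented", []))

    @property
    def excluded_items(self) -> list:
        return list(self.item_partition.get("excluded_extreme", [])) + list(
            self.item_partition.get("excluded_random", [])
        )

    def n_failures(self) -> int:
        """Accepted trials in which the target was not reached."""
        t = self.trials
        acc = t["accepted"].astype(bool)
        suc = t["success"].fillna(0).astype(bool)
        return int((acc & ~suc).sum())

    def rating_matrix(self) -> tuple[list, np.ndarray]:
        """Return (item order, items x 3 array of ratings, NaN if missing)."""
        items = sorted(self.ratings["item_id"].unique())
        idx = {it: i for i, it in enumerate(items)}
        mat = np.full((len(items), 3), np.nan)
        for _, row in self.ratings.iterrows():
            mat[idx[row["item_id"]], int(row["session"]) - 1] = row["rating"]
        return items, mat


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: SubjectDataset) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty report means the dataset is internally consistent.
    """
    report: list[str] = []
    sid = ds.subject_id
    r, t = ds.ratings, ds.trials

    bad_sessions = set(r["session"]) - {1, 2, 3}
    if bad_sessions:
        report.append(f"{sid}: rating session outside {{1,2,3}}: {sorted(bad_sessions)}")
    dup = r.duplicated(subset=["item_id", "session"])
    for _, row in r[dup].iterrows():
        report.append(f"{sid}/{row['item_id']}: duplicate rating in session {row['session']}")

    bad_trial_sessions = set(t["session"]) - {1, 2}
    if bad_trial_sessions:
        report.append(f"{sid}: effort session outside {{1,2}}: {sorted(bad_trial_sessions)}")

    for _, row in t.iterrows():
        item = row["item_id"]
        accepted = bool(row["accepted"])
        has_success = not pd.isna(row["success"])
        peak = row["peak_force"]
        if accepted != has_success:
            report.append(
                f"{sid}/{item}: success must be present iff the trial was accepted"
            )
            continue
        if has_success and bool(row["success"]):
            if pd.isna(peak) or peak < row["target_level"]:
                report.append(
                    f"{sid}/{item}: successful trial requires peak_force >= target_level"
                )
        elif accepted:  # accepted and failed
            if not pd.isna(peak) and peak >= row["target_level"]:
                report.append(
                    f"{sid}/{item}: failed trial requires peak_force < target_level"
                )
        if not pd.isna(peak) and peak < 0:
            report.append(f"{sid}/{item}: negative peak_force")
        if not (0.20 <= row["target_level"] <= 1.20):
            report.append(f"{sid}/{item}: target_level outside [0.20, 1.20]")

    presented = set(ds.item_partition.get("presented", set(t["item_id"])))
    excluded = set(ds.excluded_items)
    for item in presented:
        for session in (1, 2):
            n = int(((t["item_id"] == item) & (t["session"] == session)).sum())
            if n != 1:
                report.append(
                    f"{sid}/{item}: presented item appears {n} times in effort session {session}"
                )
        r1 = r[(r["item_id"] == item) & (r["session"] == 1)]
        if len(r1) == 0:
            report.append(f"{sid}/{item}: presented item lacks a session-1 rating")
    for item in excluded:
        if (t["item_id"] == item).any():
            report.append(f"{sid}/{item}: excluded item appears in the effort task")
    return report


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _partition_from_flags(ratings: pd.DataFrame, n_extreme: int = 30) -> dict:
    """Reconstruct the item partition from the ``excluded`` flag.

    The extreme/random split is not serialized; excluded items at the
    ``n_extreme/2`` top and bottom ranks of the session-1 ratings are taken as
    the extreme exclusions, any remaining excluded items as random exclusions.
    """
    r1 = ratings[ratings["session"] == 1].sort_values("rating", ascending=False)
    excluded_flag = ratings.groupby("item_id")["excluded"].max()
    excluded = [it for it in r1["item_id"] if excluded_flag.get(it, 0)]
    presented = [it for it in r1["item_id"] if not excluded_flag.get(it, 0)]
    half = n_extreme // 2
    ranked_exc = excluded  # already in descending rating order
    extreme = ranked_exc[:half] + ranked_exc[len(ranked_exc) - half :] if len(ranked_exc) >= n_extreme else ranked_exc
    random_exc = [it for it in ranked_exc if it not in set(extreme)]
    return {
        "presented": presented,
        "excluded_extreme": list(extreme),
        "excluded_random": random_exc,
    }


def load_dataset(ratings_path, trials_path) -> list[SubjectDataset]:
    """Load a cohort from the two CSV files; validate every subject."""
    ratings = pd.read_csv(ratings_path)
    trials = pd.read_csv(trials_path)
    _check_columns(ratings, RATING_COLUMNS, ratings_path)
    _check_columns(trials, TRIAL_COLUMNS, trials_path)

    cohort = []
    for sid, r in ratings.groupby("subject_id", sort=True):
        t = trials[trials["subject_id"] == sid]
        experiment = int(r["experiment"].iloc[0])
        ds = SubjectDataset(
            subject_id=str(sid),
            experiment=experiment,
            ratings=r.drop(columns=["subject_id", "experiment"]).reset_index(drop=True),
            trials=t.drop(columns=["subject_id", "experiment"]).reset_index(drop=True),
            item_partition=_partition_from_flags(r),
        )
        problems = validate_dataset(ds)
        if problems:
            raise ValidationError(
                f"invalid dataset for subject {sid}: " + "; ".join(problems[:5])
            )
        cohort.append(ds)
    return cohort


def write_cohort(cohort: Iterable[SubjectDataset], ratings_path, trials_path) -> None:
    """Serialize a cohort to the two-CSV interchange format."""
    rating_frames, trial_frames = [], []
    for ds in cohort:
        r = ds.ratings.copy()
        r.insert(0, "subject_id", ds.subject_id)
        r.insert(1, "experiment", ds.experiment)
        rating_frames.append(r[RATING_COLUMNS])
        t = ds.trials.copy()
        t.insert(0, "subject_id", ds.subject_id)
        t.insert(1, "experiment", ds.experiment)
        trial_frames.append(t[TRIAL_COLUMNS])
    pd.concat(rating_frames, ignore_index=True).to_csv(ratings_path, index=False)
    pd.concat(trial_frames, ignore_index=True).to_csv(trials_path, index=False)


def apply_failure_exclusion(
    cohort: Sequence[SubjectDataset], min_failures: int = DEFAULT_MIN_FAILURES
) -> tuple[list[SubjectDataset], list[dict]]:
    """Drop subjects with fewer than ``min_failures`` accepted-and-failed trials.

    Without enough failures the choice and success regressors are collinear and
    their effects cannot be separated.  Returns the filtered cohort and a log
    of the exclusions.
    """
    if min_failures < 0:
        raise ValueError("min_failures must be >= 0")
    kept, log = [], []
    for ds in cohort:
        n_fail = ds.n_failures()
        if n_fail < min_failures:
            log.append({"subject_id": ds.subject_id, "n_failures": n_fail})
        else:
            kept.append(ds)
    if not kept:
        raise ValidationError("failure exclusion removed every subject")
    return kept, log


# ---------------------------------------------------------------------------
# JSON helpers for fitted results
# ---------------------------------------------------------------------------

def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
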