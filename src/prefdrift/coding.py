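"""Orthogonalized choice / success / force regressors from raw effort trials.

Two coding schemes are used downstream:

``signed`` (model-based)
    C = +1 accepted / -1 declined; S = +1 earned / -1 accepted-and-failed /
    0 declined; F = within-subject z-score of peak force over the successful
    trials of the same effort session, 0 otherwise.  This is the coding that
    enters the bias term of the generative models.

``zscored`` (model-free)
    The acceptance indicator z-scored over all trials (both sessions pooled),
    the success indicator z-scored over accepted trials (0 elsewhere) and the
    peak force z-scored over successful trials (0 elsewhere), each within
    subject.  This is the coding of the delta-rating regression.

The conditional-subset construction (success defined only on accepted trials,
force only on successful ones) is what keeps the three regressors orthogonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import SubjectDataset, ValidationError

logger = logging.getLogger("prefdrift")

SCHEMES = ("signed", "zscored")


@dataclass
class ActionRegressors:
    """Per (item, session) C/S/F regressors for one subject."""

    subject_id: str
    scheme: str
    table: pd.DataFrame  # columns: item_id, session, C, S, F

    def for_session(self, session: int) -> pd.DataFrame:
        return self.table[self.table["session"] == session]


def derive_choice(trial, experiment: int | None = None) -> bool:
    """Acceptance criterion: implicit force threshold (Exp 1-2) or explicit
    yes/no response (Exp 3).

    In Exp 1-2 a trial counts as accepted iff peak force exceeded the minimal
    target level of 20% F_max; in Exp 3 the recorded button press decides.
    """
    exp = experiment if experiment is not None else getattr(trial, "experiment", 1)
    peak = trial["peak_force"] if isinstance(trial, (dict, pd.Series)) else trial.peak_force
    accepted = trial["accepted"] if isinstance(trial, (dict, pd.Series)) else trial.accepted
    if exp in (1, 2):
        if peak is None or (isinstance(peak, float) and np.isnan(peak)):
            if accepted is None or (isinstance(accepted, float) and np.isnan(accepted)):
                raise ValidationError("Exp 1-2 trial with no peak force and no skip record")
            return bool(accepted)
        return float(peak) > 0.20
    return bool(accepted)


def _safe_zscore(values: np.ndarray, label: str, subject_id: str) -> np.ndarray:
    """z-score, mapping degenerate subsets (n < 2 or zero variance) to 0."""
    if len(values) < 2 or np.std(values) == 0:
        if len(values) > 0:
            logger.warning(
                "degenerate %s subset for subject %s: regressor set to 0", label, subject_id
            )
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / values.std()


def build_regressors(
    ds: SubjectDataset, scheme: str = "signed", signed_force_pooled: bool = False
) -> ActionRegressors:
    """Compute the C/S/F coding for every effort trial of one subject.

    ``signed_force_pooled`` switches the signed scheme's force z-score
    reference from per-effort-session (default, so the E1 bias never depends
    on E2 data) to both sessions pooled.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown coding scheme '{scheme}'")
    t = ds.trials
    accepted = t["accepted"].astype(bool).to_numpy()
    success = t["success"].fillna(0).astype(bool).to_numpy() & accepted
    failed = accepted & ~success
    peak = t["peak_force"].to_numpy(dtype=float)
    session = t["session"].to_numpy(dtype=int)

    C = np.where(accepted, 1.0, -1.0)
    S = np.where(success, 1.0, np.where(failed, -1.0, 0.0))
    F = np.zeros(len(t))

    if scheme == "signed":
        if signed_force_pooled:
            F[success] = _safe_zscore(peak[success], "force (pooled)", ds.subject_id)
        else:
            # F referenced per effort session so the E1 bias never depends on E2
            for k in (1, 2):
                m = success & (session == k)
                F[m] = _safe_zscore(peak[m], f"force (session {k})", ds.subject_id)
    else:
        C = _safe_zscore(np.where(accepted, 1.0, 0.0), "choice", ds.subject_id)
        S = np.zeros(len(t))
        S[accepted] = _safe_zscore(
            np.where(success[accepted], 1.0, 0.0), "success", ds.subject_id
        )
        F[success] = _safe_zscore(peak[success], "force", ds.subject_id)

    table = pd.DataFrame(
        {
            "item_id": t["item_id"].to_numpy(),
            "session": session,
            "C": C,
            "S": S,
            "F": F,
        }
    )
    return ActionRegressors(subject_id=ds.subject_id, scheme=scheme, table=table)
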