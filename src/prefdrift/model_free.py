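"""Model-free analyses: trial-level regressions and group-level tests.

These are the classical two-stage (summary statistics) analyses: per-subject
OLS / logistic regressions, whose coefficients are then entered into
group-level random-effects t-tests.  The estimators are written from first
principles — OLS through QR (``lstsq``) and logistic regression through
iteratively reweighted least squares with a ridge-stabilized fallback for
separable data — because their numerical behaviour (not just their output) is
exercised by the test suite.

Note that the delta-rating regression here is exactly the analysis that is
vulnerable to the regression-to-the-mean artifact: because presented items
are selected by their first-rating rank, value and first-session rating noise
are negatively correlated among them, so the choice regressor picks up part
of the noise reversion.  The model-based pipeline exists to control for this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import build_regressors
from .core_data import SubjectDataset

logger = logging.getLogger("prefdrift")

RIDGE_FALLBACK = 1e-4


class DegenerateDataError(ValueError):
    """The requested estimate is undefined on these data."""


@dataclass
class RegressionResult:
    subject_id: str
    outcome: str  # choice | success | force | delta_rating
    coefficients: dict[str, float]
    fit_quality: float  # balanced accuracy (logistic) or R^2 (linear)
    flags: list[str] = field(default_factory=list)


@dataclass
class GroupTestResult:
    factor: str
    mean: float
    sem: float
    t: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "mean": self.mean,
            "sem": self.sem,
            "t": self.t,
            "p": self.p,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares via QR; returns (beta, R^2)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return beta, r2


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Logistic regression by iteratively reweighted least squares.

    Returns (beta, converged).  ``ridge`` adds an L2 penalty to the normal
    equations (used to stabilize separable problems).
    """
    n, p = X.shape
    beta = np.zeros(p)
    eye = np.eye(p)
    for _ in range(max_iter):
        z = X @ beta
        mu = 1.0 / (1.0 + np.exp(-z))
        w = mu * (1.0 - mu)
        g = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * eye
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            return beta, False
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def _logistic_fit(X, y, subject_id, outcome) -> tuple[np.ndarray, list[str]]:
    flags: list[str] = []
    beta, ok = irls_logistic(X, y)
    if not ok or np.max(np.abs(beta)) > 30:
        beta, ok = irls_logistic(X, y, ridge=RIDGE_FALLBACK)
        flags.append("ridge_stabilized")
        logger.warning(
            "ridge-stabilized logistic fit (%s, %s)", subject_id, outcome
        )
        if not ok:
            raise DegenerateDataError(
                f"logistic fit failed for {subject_id}/{outcome}"
            )
    return beta, flags


def balanced_accuracy(prob: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 at the given probability threshold."""
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise DegenerateDataError("balanced accuracy undefined for single-class outcomes")
    pred = np.asarray(prob) > threshold
    sens = float(np.mean(pred[y]))
    spec = float(np.mean(~pred[~y]))
    return 0.5 * (sens + spec)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Per-subject regressions
# ---------------------------------------------------------------------------

def _trial_table(ds: SubjectDataset) -> pd.DataFrame:
    """Trials of both effort sessions joined with the preceding rating."""
    rating = {
        (row["item_id"], int(row["session"])): row["rating"]
        for _, row in ds.ratings.iterrows()
    }
    t = ds.trials.copy()
    t["R"] = [rating[(it, int(k))] for it, k in zip(t["item_id"], t["session"])]
    return t


def fit_action_regressions(ds: SubjectDataset) -> dict[str, RegressionResult]:
    """Sanity-check regressions: do ratings and targets predict behaviour?

    choice  ~ logistic(zR, zL)   over all trials,
    success ~ logistic(zR, zL)   over accepted trials,
    force   ~ linear(zR, zL)     over successful trials,
    with both effort sessions pooled and predictors z-scored within subject
    over the trials entering each regression.
    """
    t = _trial_table(ds)
    results: dict[str, RegressionResult] = {}

    def design(sub: pd.DataFrame) -> np.ndarray:
        return np.column_stack(
            [
                _zscore(sub["R"].to_numpy(dtype=float)),
                _zscore(sub["target_level"].to_numpy(dtype=float)),
                np.ones(len(sub)),
            ]
        )

    specs = [
        ("choice", t, t["accepted"].to_numpy(dtype=float), "logistic"),
        (
            "success",
            t[t["accepted"] == 1],
            t.loc[t["accepted"] == 1, "success"].to_numpy(dtype=float),
            "logistic",
        ),
        (
            "force",
            t[(t["accepted"] == 1) & (t["success"] == 1)],
            t.loc[(t["accepted"] == 1) & (t["success"] == 1), "peak_force"].to_numpy(
                dtype=float
            ),
            "linear",
        ),
    ]
    for outcome, sub, y, kind in specs:
        if len(sub) < 10:
            raise DegenerateDataError(
                f"fewer than 10 usable trials for {ds.subject_id}/{outcome}"
            )
        X = design(sub)
        if kind == "logistic":
            if len(np.unique(y)) < 2:
                raise DegenerateDataError(
                    f"constant outcome for {ds.subject_id}/{outcome}"
                )
            beta, flags = _logistic_fit(X, y, ds.subject_id, outcome)
            prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
            quality = balanced_accuracy(prob, y)
        else:
            beta, quality = ols(X, y)
            flags = []
        results[outcome] = RegressionResult(
            subject_id=ds.subject_id,
            outcome=outcome,
            coefficients={"R": float(beta[0]), "L": float(beta[1]), "T": float(beta[2])},
            fit_quality=float(quality),
            flags=flags,
        )
    return results


def fit_delta_rating_regression(ds: SubjectDataset) -> RegressionResult:
    """Spread-of-preference analysis: Δ-rating against C, S, F (z-scored
    coding) with a constant term T, both repetitions pooled.

    Ratings are z-scored within subject (all sessions pooled) before
    differencing; Δ = (R2-R1, R3-R2) per presented item.
    """
    items, R = ds.rating_matrix()
    idx = {it: i for i, it in enumerate(items)}
    flat = R[~np.isnan(R)]
    mu, sd = flat.mean(), flat.std()
    Z = (R - mu) / sd if sd > 0 else np.zeros_like(R)

    reg = build_regressors(ds, "zscored").table
    rows_y, rows_x = [], []
    for _, row in reg.iterrows():
        i = idx[row["item_id"]]
        k = int(row["session"])
        rows_y.append(Z[i, k] - Z[i, k - 1])
        rows_x.append([row["C"], row["S"], row["F"], 1.0])
    y = np.array(rows_y)
    X = np.array(rows_x)
    beta, r2 = ols(X, y)
    return RegressionResult(
        subject_id=ds.subject_id,
        outcome="delta_rating",
        coefficients={
            "C": float(beta[0]),
            "S": float(beta[1]),
            "F": float(beta[2]),
            "T": float(beta[3]),
        },
        fit_quality=float(r2),
    )


# ---------------------------------------------------------------------------
# Group-level tests
# ---------------------------------------------------------------------------

def group_ttest(
    values,
    mode: str = "one_sample",
    other=None,
    popmean: float = 0.0,
    factor: str = "",
) -> GroupTestResult:
    """Two-tailed t-test: one-sample against ``popmean`` or Welch two-sample."""
    a = np.asarray(values, dtype=float)
    if len(a) < 2:
        raise DegenerateDataError("t-test requires n >= 2")
    if mode == "one_sample":
        sem = a.std(ddof=1) / np.sqrt(len(a))
        if sem == 0:
            t = 0.0 if a.mean() == popmean else np.inf * np.sign(a.mean() - popmean)
            p = 1.0 if t == 0 else 0.0
        else:
            t = (a.mean() - popmean) / sem
            p = 2.0 * stats.t.sf(abs(t), df=len(a) - 1)
        return GroupTestResult(factor, float(a.mean()), float(sem), float(t), float(p), len(a))
    if mode != "welch_two_sample":
        raise ValueError(f"unknown t-test mode '{mode}'")
    b = np.asarray(other, dtype=float)
    if len(b) < 2:
        raise DegenerateDataError("Welch test requires n >= 2 in both samples")
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        t, p, df = 0.0, 1.0, len(a) + len(b) - 2.0
    else:
        t = (a.mean() - b.mean()) / denom
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2.0 * stats.t.sf(abs(t), df=df)
    return GroupTestResult(
        factor, float(a.mean() - b.mean()), float(denom), float(t), float(p), len(a)
    )


def excluded_item_contrast(cohort) -> dict[str, GroupTestResult]:
    """Δ-rating of chosen / unchosen items against never-presented controls.

    Per subject: mean Δ-rating (z-scored, both repetitions) for items chosen
    or not in the corresponding effort session, and for randomly excluded
    items; paired group tests chosen-vs-excluded and unchosen-vs-excluded.
    """
    chosen, unchosen, excluded = [], [], []
    for ds in cohort:
        if not ds.item_partition.get("excluded_random"):
            raise DegenerateDataError(
                f"subject {ds.subject_id} has no randomly excluded items"
            )
        items, R = ds.rating_matrix()
        idx = {it: i for i, it in enumerate(items)}
        flat = R[~np.isnan(R)]
        Z = (R - flat.mean()) / flat.std()
        deltas = {"chosen": [], "unchosen": []}
        for _, row in ds.trials.iterrows():
            i = idx[row["item_id"]]
            k = int(row["session"])
            d = Z[i, k] - Z[i, k - 1]
            deltas["chosen" if row["accepted"] else "unchosen"].append(d)
        exc = []
        for it in ds.item_partition["excluded_random"]:
            i = idx[it]
            exc.extend([Z[i, 1] - Z[i, 0], Z[i, 2] - Z[i, 1]])
        chosen.append(np.mean(deltas["chosen"]))
        unchosen.append(np.mean(deltas["unchosen"]))
        excluded.append(np.mean(exc))
    chosen, unchosen, excluded = map(np.asarray, (chosen, unchosen, excluded))
    return {
        "chosen_mean": group_ttest(chosen, factor="chosen"),
        "unchosen_mean": group_ttest(unchosen, factor="unchosen"),
        "excluded_mean": group_ttest(excluded, factor="excluded"),
        "chosen_vs_excluded": group_ttest(
            chosen - excluded, factor="chosen_vs_excluded"
        ),
        "unchosen_vs_excluded": group_ttest(
            unchosen - excluded, factor="unchosen_vs_excluded"
        ),
    }


def cohort_delta_betas(cohort) -> pd.DataFrame:
    """Per-subject Δ-rating regression coefficients, one row per subject."""
    rows = []
    for ds in cohort:
        res = fit_delta_rating_regression(ds)
        rows.append({"subject_id": ds.subject_id, **res.coefficients})
    return pd.DataFrame(rows).set_index("subject_id")
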