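"""Group-level random-effects Bayesian model selection and model averaging.

Model frequencies r in the population are given a Dirichlet prior; each
subject's model assignment is a latent categorical variable.  The variational
fixed point alternates

    u_nm  propto  exp( lme_nm + psi(alpha_m) - psi(sum alpha) )
    alpha = alpha0 + sum_n u_n

until the concentration stabilizes.  Expected frequencies are the Dirichlet
posterior mean; exceedance probabilities (the probability that a model, or a
family of models, is the most frequent in the population) are Monte-Carlo
estimates over Dirichlet draws.  For family inference, the per-model prior
concentration is 1 / (family size x number of families), equalizing prior
family mass regardless of how many models each hypothesis contributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .model_free import GroupTestResult, group_ttest
from .inversion import SubjectFit

DEFAULT_XP_SAMPLES = 100_000


@dataclass
class BMSResult:
    """Dirichlet posterior over model (and optionally family) frequencies."""

    models: list[str]
    alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    subject_posteriors: np.ndarray  # subjects x models
    families: dict[str, list[str]] | None = None
    family_expected_frequency: dict[str, float] | None = None
    family_exceedance_probability: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "models": self.models,
            "alpha": self.alpha.tolist(),
            "expected_frequency": self.expected_frequency.tolist(),
            "exceedance_probability": self.exceedance_probability.tolist(),
        }
        if self.families is not None:
            out["families"] = {k: list(v) for k, v in self.families.items()}
            out["family_expected_frequency"] = self.family_expected_frequency
            out["family_exceedance_probability"] = self.family_exceedance_probability
        return out


@dataclass
class BMAEstimate:
    """Per-subject posterior-weighted parameters within a model family."""

    subject_id: str
    scope: str
    values: dict[str, float]
    weights: dict[str, float] = field(default_factory=dict)


def _as_matrix(evidence) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(evidence, pd.DataFrame):
        return evidence.to_numpy(dtype=float), list(evidence.index), list(evidence.columns)
    arr = np.asarray(evidence, dtype=float)
    return (
        arr,
        [f"s{i}" for i in range(arr.shape[0])],
        [f"m{j}" for j in range(arr.shape[1])],
    )


def rfx_bms(
    evidence,
    alpha0=1.0,
    xp_samples: int = DEFAULT_XP_SAMPLES,
    seed=0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix."""
    lme, subjects, models = _as_matrix(evidence)
    if not np.all(np.isfinite(lme)):
        i, j = np.argwhere(~np.isfinite(lme))[0]
        raise ValueError(
            f"non-finite log evidence for subject {subjects[i]}, model {models[j]}"
        )
    n, k = lme.shape
    alpha0 = np.full(k, alpha0, dtype=float) if np.isscalar(alpha0) else np.asarray(alpha0, float)
    if np.any(alpha0 <= 0):
        raise ValueError("prior concentration must be positive")
    alpha = alpha0.copy()
    for _ in range(max_iter):
        w = lme + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    ef = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(xp_samples))
    xp = np.bincount(np.argmax(draws, axis=1), minlength=k) / float(xp_samples)
    return BMSResult(
        models=models,
        alpha=alpha,
        expected_frequency=ef,
        exceedance_probability=xp,
        subject_posteriors=u,
    )


def family_prior_concentration(
    models: list[str], families: dict[str, list[str]]
) -> np.ndarray:
    """Per-model Dirichlet prior concentration 1/(family size x n families).

    Gives every family the same prior mass (1/n_families) regardless of how
    many models it contributes, so a 2-model null family is not disadvantaged
    against a 14-model alternative a priori.
    """
    index = {m: j for j, m in enumerate(models)}
    seen: list[str] = []
    for fam, members in families.items():
        if not members:
            raise ValueError(f"family '{fam}' is empty")
        for m in members:
            if m not in index:
                raise ValueError(f"family '{fam}' names unknown model '{m}'")
            seen.append(m)
    if sorted(seen) != sorted(models):
        raise ValueError("families must partition the model space disjointly")
    n_fam = len(families)
    alpha0 = np.empty(len(models))
    for members in families.values():
        for m in members:
            alpha0[index[m]] = 1.0 / (len(members) * n_fam)
    return alpha0


def family_bms(
    evidence,
    families: dict[str, list[str]],
    xp_samples: int = DEFAULT_XP_SAMPLES,
    seed=0,
) -> BMSResult:
    """Family-level BMS with the prior mass equalized across families."""
    lme, _, models = _as_matrix(evidence)
    index = {m: j for j, m in enumerate(models)}
    alpha0 = family_prior_concentration(models, families)
    result = rfx_bms(evidence, alpha0=alpha0, xp_samples=xp_samples, seed=seed)

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(result.alpha, size=int(xp_samples))
    fam_names = list(families)
    n_fam = len(families)
    fam_freq = np.column_stack(
        [draws[:, [index[m] for m in families[f]]].sum(axis=1) for f in fam_names]
    )
    winner = np.argmax(fam_freq, axis=1)
    fam_xp = np.bincount(winner, minlength=n_fam) / float(xp_samples)
    fam_ef = {
        f: float(result.alpha[[index[m] for m in families[f]]].sum() / result.alpha.sum())
        for f in fam_names
    }
    result.families = families
    result.family_expected_frequency = fam_ef
    result.family_exceedance_probability = dict(zip(fam_names, fam_xp.astype(float)))
    return result


def ffx_model_posterior(evidence) -> pd.Series:
    """Fixed-effects variant: posterior over models from summed evidences."""
    lme, _, models = _as_matrix(evidence)
    total = lme.sum(axis=0)
    post = np.exp(total - logsumexp(total))
    return pd.Series(post, index=models)


# ---------------------------------------------------------------------------
# Bayesian model averaging
# ---------------------------------------------------------------------------

BIAS_PARAMS = ("b_choice", "b_success", "b_force", "b_time")


def bma_parameters(
    fits: list[SubjectFit],
    params: tuple[str, ...] = BIAS_PARAMS,
    scope_label: str = "",
) -> BMAEstimate:
    """Evidence-weighted average of parameters over one subject's fits.

    Weights are softmax of the log evidences over the supplied family;
    parameters switched off in a member model contribute structural zeros.
    """
    if not fits:
        raise ValueError("no successful fits to average")
    sid = fits[0].subject_id
    if any(f.subject_id != sid for f in fits):
        raise ValueError("bma_parameters averages fits of a single subject")
    lmes = np.array([f.log_evidence for f in fits])
    w = np.exp(lmes - lmes.max())
    w = w / w.sum()
    values = {p: float(sum(wi * f.get(p, 0.0) for wi, f in zip(w, fits))) for p in params}
    return BMAEstimate(
        subject_id=sid,
        scope=scope_label or (fits[0].spec.family if fits else ""),
        values=values,
        weights={f.spec.label: float(wi) for f, wi in zip(fits, w)},
    )


def cohort_bma(
    fits: dict,
    model_labels: list[str],
    params: tuple[str, ...] = BIAS_PARAMS,
    scope_label: str = "",
) -> pd.DataFrame:
    """BMA per subject over the given family; one row per subject."""
    by_subject: dict[str, list[SubjectFit]] = {}
    for (sid, label), fit in fits.items():
        if label in model_labels:
            by_subject.setdefault(sid, []).append(fit)
    rows = []
    for sid in sorted(by_subject):
        est = bma_parameters(by_subject[sid], params=params, scope_label=scope_label)
        rows.append({"subject_id": sid, **est.values})
    if not rows:
        raise ValueError("no fits matched the requested family")
    return pd.DataFrame(rows).set_index("subject_id")


def rho_positivity_check(fits: dict, model_labels: list[str]) -> dict[str, GroupTestResult]:
    """One-sample t-tests of the BMA value weights rho_C/S/F against zero.

    A positive rho confirms that hidden values drive the effort behaviours,
    i.e. that value updates can express themselves in later actions.
    """
    table = cohort_bma(
        fits, model_labels, params=("rho_c", "rho_s", "rho_f"), scope_label="rho"
    )
    return {
        name: group_ttest(table[name].to_numpy(), factor=name)
        for name in ("rho_c", "rho_s", "rho_f")
    }


def hypothesis_families(model_space) -> dict[str, list[str]]:
    """Partition a model space by hypothesis (H0 holds the two null models)."""
    fams: dict[str, list[str]] = {}
    for spec in model_space:
        fams.setdefault(spec.family, []).append(spec.label)
    return fams


def factor_families(model_space, factor: str) -> dict[str, list[str]]:
    """Partition by presence of one bias factor (e.g. 'choice')."""
    fams: dict[str, list[str]] = {"with": [], "without": []}
    for spec in model_space:
        fams["with" if getattr(spec, factor) else "without"].append(spec.label)
    return {k: v for k, v in fams.items() if v}
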