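"""Per-subject Bayesian model inversion.

Each model is inverted by MAP estimation under independent Gaussian priors
(noise SDs log-transformed so all parameters are optimized unconstrained),
with a Laplace approximation to the log model evidence:

    ln p(y | m)  ~  ln p(y, theta*) + (d/2) ln 2*pi - (1/2) ln det H

where theta* is the posterior mode, d the number of free parameters and H the
Hessian of the negative log-joint at the mode.  The optimizer is a damped
Newton descent using the analytic gradient and Hessian of the joint (the
posterior has an arrow structure: many item values, few shared parameters),
with a prior-whitened L-BFGS-B fallback when Newton stalls; the same analytic
Hessian evaluated at the mode supplies the Laplace term.  Free parameters are
the per-item initial values V1, the active bias weights, the rating noise SD
and, in extended scope, the nine response parameters and force noise SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .core_data import SubjectDataset
from .model_free import irls_logistic, ols
from .models import (
    LOG2PI,
    BIAS_NAMES,
    SCALAR_ORDER,
    BiasParameters,
    CompiledSubject,
    ModelSpec,
    ResponseParameters,
    loglik_hess,
    loglik_terms,
)

logger = logging.getLogger("prefdrift")

RESPONSE_NAMES = (
    "rho_c", "eta_c", "c0", "rho_s", "eta_s", "s0",
    "rho_f", "eta_f", "f0", "log_sigma_f",
)

#: Weakly informative default priors on the declared scales: values on the
#: 0-100 rating scale, biases in rating units, target levels in [0.2, 1.2].
DEFAULT_PRIOR_TABLE = {
    "v": (50.0, 25.0),
    "b_choice": (0.0, 5.0),
    "b_success": (0.0, 5.0),
    "b_force": (0.0, 5.0),
    "b_time": (0.0, 5.0),
    "log_sigma_r": (math.log(10.0), 1.0),
    "rho_c": (0.0, 1.0),
    "eta_c": (0.0, 5.0),
    "c0": (0.0, 3.0),
    "rho_s": (0.0, 1.0),
    "eta_s": (0.0, 5.0),
    "s0": (0.0, 3.0),
    "rho_f": (0.0, 1.0),
    "eta_f": (0.0, 5.0),
    "f0": (0.0, 3.0),
    "log_sigma_f": (math.log(0.1), 1.0),
}

HESSIAN_EIGEN_FLOOR = 1e-8
GRAD_TOL = 1e-6
MAX_ITER = 500


class InversionError(RuntimeError):
    """The optimizer failed to produce a usable posterior mode."""


@dataclass
class PriorSpec:
    """Gaussian prior mean/SD per parameter (in transformed space for the
    log-transformed noise SDs).  ``table['v']`` applies to every item value."""

    table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_TABLE)
    )

    def __post_init__(self):
        for name, (_, sd) in self.table.items():
            if sd <= 0:
                raise ValueError(f"prior SD for {name} must be > 0")

    def get(self, name: str) -> tuple[float, float]:
        return self.table[name]


@dataclass
class SubjectFit:
    """Posterior mode, Laplace covariance and log evidence for one
    subject x model."""

    subject_id: str
    spec: ModelSpec
    scope: str
    params: dict  # name -> value; "v" maps to the item-value array
    log_evidence: float
    param_names: list[str]
    cov: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def get(self, name: str, default: float = 0.0) -> float:
        return float(self.params.get(name, default))

    def bias_estimate(self) -> BiasParameters:
        return BiasParameters(
            choice=self.get("b_choice"),
            success=self.get("b_success"),
            force=self.get("b_force"),
            time=self.get("b_time"),
        )

    def to_dict(self) -> dict:
        out = {
            "subject_id": self.subject_id,
            "model": self.spec.to_dict(),
            "scope": self.scope,
            "log_evidence": self.log_evidence,
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()
            },
            "diagnostics": self.diagnostics,
        }
        if self.cov is not None:
            out["posterior_sd"] = np.sqrt(np.diag(self.cov)).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectFit":
        params = {
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in d["params"].items()
        }
        return cls(
            subject_id=d["subject_id"],
            spec=ModelSpec.from_dict(d["model"]),
            scope=d["scope"],
            params=params,
            log_evidence=float(d["log_evidence"]),
            param_names=d.get("param_names", []),
            diagnostics=d.get("diagnostics", {}),
        )


class _Layout:
    """Mapping between the flat optimization vector and named parameters."""

    def __init__(self, cs: CompiledSubject, spec: ModelSpec, scope: str, fixed: dict):
        self.M = cs.M
        self.scope = scope
        self.fixed = dict(fixed or {})
        scalars = [f"b_{n}" for n in spec.active_biases]
        scalars.append("log_sigma_r")
        if scope == "extended":
            scalars.extend(RESPONSE_NAMES)
        self.scalars = [s for s in scalars if s not in self.fixed]
        self.fixed_scalars = [s for s in scalars if s in self.fixed]
        self.names = [f"v[{i}]" for i in range(self.M)] + self.scalars
        self.dim = self.M + len(self.scalars)
        self.spec = spec

    def unpack(self, x: np.ndarray):
        v = x[: self.M]
        val = dict(zip(self.scalars, x[self.M :]))
        val.update(self.fixed)
        bias = BiasParameters(
            **{n: val.get(f"b_{n}", 0.0) for n in BIAS_NAMES}
        )
        sigma_r = math.exp(val["log_sigma_r"])
        resp = None
        if self.scope == "extended":
            resp = ResponseParameters(
                **{n: val[n] for n in RESPONSE_NAMES if n != "log_sigma_f"},
                sigma_f=math.exp(val["log_sigma_f"]),
                sigma_r=sigma_r,
            )
        return v, bias, resp, sigma_r

    def prior_vectors(self, priors: PriorSpec):
        mv, sv = priors.get("v")
        means = np.concatenate(
            [np.full(self.M, mv), [priors.get(s)[0] for s in self.scalars]]
        )
        sds = np.concatenate(
            [np.full(self.M, sv), [priors.get(s)[1] for s in self.scalars]]
        )
        return means, sds

    def scalar_grad(self, grads: dict) -> np.ndarray:
        bias_grad = dict(zip([f"b_{n}" for n in BIAS_NAMES], grads["bias"]))
        out = []
        for s in self.scalars:
            if s in bias_grad:
                out.append(bias_grad[s])
            else:
                out.append(grads[s])
        return np.asarray(out)


def _initial_point(cs: CompiledSubject, layout: _Layout, priors: PriorSpec) -> np.ndarray:
    """Deterministic warm start: shrunk item means for V1, moment-matched
    response parameters from quick IRLS / OLS fits, biases at zero."""
    n_obs = cs.R_mask.sum(axis=1).clip(min=1)
    item_mean = np.where(
        cs.R_mask.any(axis=1),
        cs.R_filled.sum(axis=1) / n_obs,
        priors.get("v")[0],
    )
    resid = cs.R_filled - item_mean[:, None]
    nres = int(cs.R_mask.sum())
    sigma0 = float(np.sqrt((resid[cs.R_mask] ** 2).sum() / max(nres - cs.M, 1)))
    sigma0 = max(sigma0, 0.5)
    mv, sv = priors.get("v")
    prec_like = n_obs / sigma0**2
    v0 = (item_mean * prec_like + mv / sv**2) / (prec_like + 1.0 / sv**2)

    values = {"log_sigma_r": math.log(sigma0)}
    for b in layout.scalars:
        if b.startswith("b_"):
            values[b] = 0.0
    if layout.scope == "extended":
        t_item = np.concatenate(cs.t_item)
        if len(t_item):
            X = np.column_stack(
                [v0[t_item], np.concatenate(cs.t_L), np.ones(len(t_item))]
            )
            y = np.concatenate(cs.t_acc)
            beta, _ = irls_logistic(X, y, ridge=1e-3, max_iter=25)
            values.update(rho_c=beta[0], eta_c=beta[1], c0=-beta[2])
            s_item = np.concatenate(cs.s_item)
            if len(s_item):
                X = np.column_stack(
                    [v0[s_item], np.concatenate(cs.s_L), np.ones(len(s_item))]
                )
                beta, _ = irls_logistic(X, np.concatenate(cs.s_suc), ridge=1e-3, max_iter=25)
                values.update(rho_s=beta[0], eta_s=beta[1], s0=beta[2])
            f_item = np.concatenate(cs.f_item)
            if len(f_item):
                X = np.column_stack(
                    [v0[f_item], np.concatenate(cs.f_L), np.ones(len(f_item))]
                )
                peak = np.concatenate(cs.f_peak)
                beta, _ = ols(X, peak)
                sd = float(np.std(peak - X @ beta))
                values.update(
                    rho_f=beta[0], eta_f=beta[1], f0=beta[2],
                    log_sigma_f=math.log(max(sd, 1e-3)),
                )
        for name in RESPONSE_NAMES:
            values.setdefault(name, priors.get(name)[0])
    x0 = np.concatenate([v0, [values[s] for s in layout.scalars]])
    return x0


def _natural_indices(layout: _Layout) -> np.ndarray:
    idx = list(range(layout.M)) + [
        layout.M + SCALAR_ORDER.index(s) for s in layout.scalars
    ]
    return np.asarray(idx, dtype=int)


def _neg_log_joint_hess(x, cs, layout, means, sds, nat_idx):
    """Negative log joint with analytic gradient and Hessian."""
    v, bias, resp, sigma_r = layout.unpack(x)
    ll, g, H = loglik_hess(cs, layout.spec, v, bias, resp, sigma_r, layout.scope)
    g = g[nat_idx]
    H = H[np.ix_(nat_idx, nat_idx)]
    z = (x - means) / sds
    lp = float(-0.5 * z @ z - np.sum(np.log(sds)) - 0.5 * len(x) * LOG2PI)
    f = -(ll + lp)
    grad = -(g - z / sds)
    H_neg = -H + np.diag(1.0 / sds**2)
    return f, grad, H_neg


def _newton(fun3, x0, max_iter=100, gtol=GRAD_TOL):
    """Damped (Levenberg-style) Newton descent on the negative log joint."""
    x = np.asarray(x0, dtype=float)
    f, g, H = fun3(x)
    if not np.isfinite(f):
        return x, f, g, H, 0, False
    lam = 1e-6
    eye = np.eye(len(x))
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < gtol:
            return x, f, g, H, it, True
        accepted = False
        for _ in range(30):
            try:
                cho = linalg.cho_factor(H + lam * eye, check_finite=False)
                step = linalg.cho_solve(cho, -g, check_finite=False)
            except (np.linalg.LinAlgError, linalg.LinAlgError):
                lam = max(lam, 1e-10) * 10.0
                continue
            xn = x + step
            fn, gn, Hn = fun3(xn)
            if np.isfinite(fn) and fn <= f + 1e-10 * (1.0 + abs(f)):
                improved = fn < f - 1e-12 * (1.0 + abs(f))
                x, f, g, H = xn, fn, gn, Hn
                lam = max(lam * 0.2, 1e-10)
                accepted = True
                if not improved and np.max(np.abs(g)) < gtol:
                    return x, f, g, H, it, True
                break
            lam = max(lam, 1e-10) * 10.0
        if not accepted:
            break
    converged = np.max(np.abs(g)) < gtol
    return x, f, g, H, it, converged


def _neg_log_joint(x, cs, layout, means, sds):
    v, bias, resp, sigma_r = layout.unpack(x)
    try:
        ll, grads = loglik_terms(
            cs, layout.spec, v, bias, resp, sigma_r, scope=layout.scope, want_grad=True
        )
    except (OverflowError, FloatingPointError):
        return np.inf, np.zeros_like(x)
    z = (x - means) / sds
    lp = float(-0.5 * z @ z - np.sum(np.log(sds)) - 0.5 * len(x) * LOG2PI)
    g = np.concatenate([grads["v"], layout.scalar_grad(grads)]) - z / sds
    return -(ll + lp), -g


def fit_subject(
    ds,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    scope: str = "extended",
    n_restarts: int = 3,
    seed=0,
    fixed: dict | None = None,
    store_cov: bool = True,
) -> SubjectFit:
    """MAP + Laplace inversion of one model for one subject.

    ``n_restarts`` quasi-Newton runs are started from the warm start (first
    restart) and jittered copies of it (jitter SD = 0.1 prior SD); the best
    mode wins.  ``fixed`` pins parameters to known constants (they leave the
    free vector and carry no prior mass).
    """
    if spec.hypothesis == "H3" and scope == "ratings_only":
        raise ValueError("H3 requires the extended scope")
    priors = priors or PriorSpec()
    cs = ds if isinstance(ds, CompiledSubject) else CompiledSubject(ds)
    layout = _Layout(cs, spec, scope, fixed)
    means, sds = layout.prior_vectors(priors)
    nat_idx = _natural_indices(layout)
    fun3 = lambda x: _neg_log_joint_hess(x, cs, layout, means, sds, nat_idx)

    x0 = _initial_point(cs, layout, priors)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    best = None
    n_failed = 0
    total_iters = 0
    used_fallback = False
    for r in range(max(n_restarts, 1)):
        start = x0 if r == 0 else x0 + 0.1 * sds * rng.standard_normal(layout.dim)
        x, f, g, H, nit, converged = _newton(fun3, start, max_iter=MAX_ITER)
        total_iters += nit
        if not converged:
            # quasi-Newton fallback in prior-whitened coordinates
            fun = lambda z: _neg_log_joint(means + sds * z, cs, layout, means, sds)
            res = optimize.minimize(
                jac=True,
                fun=lambda z: (lambda fr: (fr[0], fr[1] * sds))(fun(z)),
                x0=(x - means) / sds,
                method="L-BFGS-B",
                options={"maxiter": 4 * MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-14},
            )
            used_fallback = True
            if np.isfinite(res.fun) and res.fun <= f:
                x = means + sds * res.x
                f, g, H, nit2, converged = (lambda t: (t[1], t[2], t[3], t[4], t[5]))(
                    (None, *_newton(fun3, x, max_iter=20))
                )
                total_iters += nit2
        if not np.isfinite(f):
            n_failed += 1
            continue
        if best is None or f < best[1]:
            best = (x, f, g, H, converged)
    if best is None:
        raise InversionError(
            f"optimizer failed for {cs.subject_id} / {spec.label} after "
            f"{max(n_restarts, 1)} restarts"
        )
    x_best, f_best, g_best, H, converged = best

    eigval, eigvec = np.linalg.eigh(H)
    repaired = bool(np.any(eigval < HESSIAN_EIGEN_FLOOR))
    if repaired:
        logger.warning(
            "non-PD Hessian repaired for %s / %s", cs.subject_id, spec.label
        )
    eigval = np.clip(eigval, HESSIAN_EIGEN_FLOOR, None)
    logdet = float(np.sum(np.log(eigval)))
    log_evidence = float(-f_best + 0.5 * layout.dim * LOG2PI - 0.5 * logdet)
    cov = (eigvec / eigval) @ eigvec.T if store_cov else None

    v, bias, resp, sigma_r = layout.unpack(x_best)
    params: dict = {"v": v.copy(), "sigma_r": sigma_r}
    for j, name in enumerate(layout.scalars):
        params[name] = float(x_best[cs.M + j])
    if resp is not None:
        params["sigma_f"] = resp.sigma_f
    return SubjectFit(
        subject_id=cs.subject_id,
        spec=spec,
        scope=scope,
        params=params,
        log_evidence=log_evidence,
        param_names=layout.names,
        cov=cov,
        diagnostics={
            "iterations": int(total_iters),
            "grad_norm": float(np.max(np.abs(g_best))),
            "converged": bool(converged),
            "restarts": max(n_restarts, 1),
            "failed_restarts": n_failed,
            "fallback_used": used_fallback,
            "pd_repaired": repaired,
            "neg_log_joint": float(f_best),
        },
    )


def fit_cohort(
    cohort,
    model_space: list[ModelSpec],
    priors: PriorSpec | None = None,
    scope: str = "extended",
    n_restarts: int = 3,
    seed=0,
    store_cov: bool = False,
    max_failure_fraction: float = 0.2,
):
    """Invert every (subject, model) cell.

    Returns ``(evidence, fits, failures)``: a subjects x models evidence
    DataFrame (NaN for failed cells), the per-cell fits, and the failure log.
    Individual cell failures are isolated; more than ``max_failure_fraction``
    failed cells raises.
    """
    evidence = np.full((len(cohort), len(model_space)), np.nan)
    fits: dict[tuple[str, str], SubjectFit] = {}
    failures = []
    for i, ds in enumerate(cohort):
        cs = ds if isinstance(ds, CompiledSubject) else CompiledSubject(ds)
        for j, spec in enumerate(model_space):
            cell_seed = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i, j])
            try:
                fit = fit_subject(
                    cs,
                    spec,
                    priors=priors,
                    scope=scope,
                    n_restarts=n_restarts,
                    seed=cell_seed,
                    store_cov=store_cov,
                )
                evidence[i, j] = fit.log_evidence
                fits[(cs.subject_id, spec.label)] = fit
            except Exception as exc:  # noqa: BLE001 - cell isolation
                failures.append(
                    {"subject_id": cs.subject_id, "model": spec.label, "error": str(exc)}
                )
    n_cells = evidence.size
    if n_cells and len(failures) > max_failure_fraction * n_cells:
        raise InversionError(
            f"{len(failures)} of {n_cells} inversion cells failed"
        )
    ev = pd.DataFrame(
        evidence,
        index=[getattr(ds, "subject_id") for ds in cohort],
        columns=[m.label for m in model_space],
    )
    return ev, fits, failures
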