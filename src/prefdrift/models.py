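"""The H0-H3 generative model space for ratings and effort behaviour.

Hidden item values V drive four observables:

* ratings            R = V + Gaussian noise (SD sigma_R)
* choice             p(accept)  = sig(rho_C V + eta_C L - C0)
* success            p(success) = sig(rho_S V + eta_S L + S0)   (accepted trials)
* force              F = rho_F V + eta_F L + F0 + Gaussian noise (successful trials)

where L is the imposed target force level and sig the logistic function.
Past actions in effort session k induce a per-item bias

    b_ik = b_C C_ik + b_S S_ik + b_F F_ik + b_T

from the signed C/S/F coding.  The four hypotheses differ in where that bias
lands:

* H0 - nowhere (stable values; the two null models are "no effect" and
  "time effect only"),
* H1 - only the next rating session,
* H2 - all later rating sessions (biases accumulate in ratings),
* H3 - the hidden value itself (V^{k+1} = V^1 + cumulative bias), hence all
  later ratings *and* actions.

Switching the four bias parameters on/off yields 16 models per hypothesis
structure, two of which (none / time-only) belong to H0.

Model evidence comparisons may be restricted to rating data
(``scope="ratings_only"``, valid for H0-H2) or include the effort observables
(``scope="extended"``); H3's distinguishing predictions concern actions, so it
requires the extended scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .coding import ActionRegressors, build_regressors
from .core_data import SubjectDataset

LOG2PI = math.log(2.0 * math.pi)

BIAS_NAMES = ("choice", "success", "force", "time")
HYPOTHESES = ("H0", "H1", "H2", "H3")


@dataclass(frozen=True)
class BiasParameters:
    """Weights of past choice/success/force and of session repetition (time),
    in rating-scale units per regressor unit."""

    choice: float = 0.0
    success: float = 0.0
    force: float = 0.0
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.choice, self.success, self.force, self.time])


@dataclass(frozen=True)
class ResponseParameters:
    """Cost/benefit response functions: value weights rho, target-level
    weights eta, offsets, and the two noise SDs."""

    rho_c: float = 0.1
    eta_c: float = -3.0
    c0: float = 0.0
    rho_s: float = 0.02
    eta_s: float = -6.0
    s0: float = 5.0
    rho_f: float = 0.001
    eta_f: float = 0.9
    f0: float = 0.1
    sigma_f: float = 0.08
    sigma_r: float = 5.0

    def __post_init__(self):
        # sigma_r = 0 is tolerated here so the generator can produce the
        # degenerate noiseless case; likelihood evaluation requires > 0.
        if self.sigma_f <= 0 or self.sigma_r < 0:
            raise ValueError("noise SDs must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """One model: hypothesis label plus on/off switches for the four biases.

    ``structure`` names the dynamics the bias follows (H1 last-session,
    H2/H3 cumulative); it equals ``hypothesis`` except for the two null
    models, which are labelled H0 but inherit the structure of the space they
    are compared in.
    """

    hypothesis: str
    choice: bool = False
    success: bool = False
    force: bool = False
    time: bool = False
    structure: str = ""

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        has_action = self.choice or self.success or self.force
        if self.hypothesis == "H0" and has_action:
            raise ValueError("H0 admits no action bias switch")
        if self.hypothesis != "H0" and not has_action:
            raise ValueError(f"{self.hypothesis} requires at least one action switch")
        if not self.structure:
            object.__setattr__(
                self, "structure", self.hypothesis if self.hypothesis != "H0" else "H1"
            )
        if self.structure not in ("H1", "H2", "H3"):
            raise ValueError(f"invalid structure {self.structure!r}")

    @property
    def switches(self) -> dict:
        return {name: getattr(self, name) for name in BIAS_NAMES}

    @property
    def active_biases(self) -> tuple[str, ...]:
        return tuple(name for name in BIAS_NAMES if getattr(self, name))

    @property
    def family(self) -> str:
        return self.hypothesis

    @property
    def label(self) -> str:
        code = "".join(n[0].upper() for n in self.active_biases) or "-"
        return f"{self.hypothesis}[{code}]"

    def switch_mask(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in BIAS_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "structure": self.structure,
            "switches": self.switches,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            hypothesis=d["hypothesis"],
            structure=d.get("structure", ""),
            **{k: bool(v) for k, v in d["switches"].items()},
        )


def enumerate_model_space(
    hypotheses=HYPOTHESES, scope: str = "extended"
) -> list[ModelSpec]:
    """All 2^4 switch settings per requested hypothesis.

    The two all-action-off settings (no bias, time-only) are emitted once,
    labelled H0, with the dynamics of the highest requested hypothesis.  The
    full H0-H3 request yields 2 + 14 + 14 + 14 = 44 models.
    """
    requested = [h for h in HYPOTHESES if h in hypotheses]
    if not requested:
        raise ValueError("no hypothesis requested")
    alternatives = [h for h in requested if h != "H0"]
    if scope == "ratings_only" and "H3" in alternatives:
        raise ValueError("H3 predicts actions; it cannot be compared on ratings only")
    null_structure = alternatives[-1] if alternatives else "H1"

    specs: list[ModelSpec] = []
    if "H0" in requested:
        specs.append(ModelSpec("H0", structure=null_structure))
        specs.append(ModelSpec("H0", time=True, structure=null_structure))
    for h in alternatives:
        for c, s, f, t in product((False, True), repeat=4):
            if not (c or s or f):
                continue
            specs.append(ModelSpec(h, choice=c, success=s, force=f, time=t))
    return specs


# ---------------------------------------------------------------------------
# Compiled per-subject arrays
# ---------------------------------------------------------------------------

class CompiledSubject:
    """Dense array view of one subject's data for fast likelihood evaluation.

    Items are indexed in sorted item-id order; the signed C/S/F regressors are
    expanded to (session, regressor, item) with zeros for items without an
    effort trial, so excluded items automatically carry zero bias.
    """

    def __init__(self, ds: SubjectDataset):
        self.subject_id = ds.subject_id
        items, R = ds.rating_matrix()
        self.items = items
        self.index = {it: i for i, it in enumerate(items)}
        self.M = len(items)
        self.R = R
        self.R_mask = ~np.isnan(R)
        self.R_filled = np.where(self.R_mask, np.nan_to_num(R), 0.0)

        reg = build_regressors(ds, "signed").table
        self.X = np.zeros((2, 4, self.M))  # (session, C/S/F/T, item)
        t = ds.trials
        self.t_item: list[np.ndarray] = []
        self.t_L: list[np.ndarray] = []
        self.t_acc: list[np.ndarray] = []
        self.s_item: list[np.ndarray] = []
        self.s_L: list[np.ndarray] = []
        self.s_suc: list[np.ndarray] = []
        self.f_item: list[np.ndarray] = []
        self.f_L: list[np.ndarray] = []
        self.f_peak: list[np.ndarray] = []
        for k in (1, 2):
            sub = t[t["session"] == k]
            rsub = reg[reg["session"] == k]
            idx = np.array([self.index[it] for it in sub["item_id"]], dtype=int)
            ridx = np.array([self.index[it] for it in rsub["item_id"]], dtype=int)
            for j, col in enumerate(("C", "S", "F")):
                self.X[k - 1, j, ridx] = rsub[col].to_numpy()
            self.X[k - 1, 3, ridx] = 1.0
            L = sub["target_level"].to_numpy(dtype=float)
            acc = sub["accepted"].to_numpy(dtype=float)
            suc = sub["success"].fillna(0).to_numpy(dtype=float)
            peak = sub["peak_force"].to_numpy(dtype=float)
            self.t_item.append(idx)
            self.t_L.append(L)
            self.t_acc.append(acc)
            a = acc > 0
            self.s_item.append(idx[a])
            self.s_L.append(L[a])
            self.s_suc.append(suc[a])
            s = (suc > 0) & a
            self.f_item.append(idx[s])
            self.f_L.append(L[s])
            self.f_peak.append(peak[s])


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def _bernoulli_block(z, y, v, item, M, want_grad):
    """Log-likelihood and gradients for a logistic block p = sig(z)."""
    ll = float(np.sum(y * _log_sigmoid(z) + (1.0 - y) * _log_sigmoid(-z)))
    if not want_grad:
        return ll, None, None
    p = 1.0 / (1.0 + np.exp(-z))
    g = y - p
    dv_items = np.bincount(item, weights=g, minlength=M)
    return ll, g, dv_items


def loglik_terms(
    cs: CompiledSubject,
    spec: ModelSpec,
    v: np.ndarray,
    bias: BiasParameters,
    resp: ResponseParameters | None,
    sigma_r: float,
    scope: str = "extended",
    want_grad: bool = False,
):
    """Joint log-likelihood of one subject's data, with analytic gradients.

    Returns ``(ll, grads)`` where ``grads`` is None unless requested, else a
    dict with keys ``v`` (M,), ``bias`` (4, in C/S/F/T order),
    ``log_sigma_r`` and, in extended scope, the nine response parameters and
    ``log_sigma_f``.
    """
    if sigma_r <= 0:
        raise ValueError("sigma_r must be > 0")
    if scope not in ("ratings_only", "extended"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "extended" and resp is None:
        raise ValueError("extended scope requires response parameters")

    mask = spec.switch_mask()
    bvec = bias.as_array() * mask
    B0 = bvec @ cs.X[0]
    B1 = bvec @ cs.X[1]
    cumulative = spec.structure in ("H2", "H3")
    d1 = B0
    d2 = B0 + B1 if cumulative else B1

    grads = None
    if want_grad:
        grads = {
            "v": np.zeros(cs.M),
            "bias": np.zeros(4),
            "log_sigma_r": 0.0,
        }
    dB0 = np.zeros(cs.M)
    dB1 = np.zeros(cs.M)

    # --- ratings ---
    ll = 0.0
    var = sigma_r**2
    for s, delta in enumerate((np.zeros(cs.M), d1, d2)):
        m = cs.R_mask[:, s]
        res = np.where(m, cs.R_filled[:, s] - (v + delta), 0.0)
        n_obs = int(m.sum())
        ll += float(
            -0.5 * np.sum(res**2) / var
            - n_obs * (math.log(sigma_r) + 0.5 * LOG2PI)
        )
        if want_grad:
            r = res / var
            grads["v"] += r
            grads["log_sigma_r"] += float(np.sum(res**2) / var) - n_obs
            if s == 1:
                dB0 += r
            elif s == 2:
                dB1 += r
                if cumulative:
                    dB0 += r

    # --- effort-task observables ---
    if scope == "extended":
        h3 = spec.structure == "H3"
        values = [v, v + B0 if h3 else v]
        rgrad = {k: 0.0 for k in (
            "rho_c", "eta_c", "c0", "rho_s", "eta_s", "s0",
            "rho_f", "eta_f", "f0", "log_sigma_f",
        )}
        varf = resp.sigma_f**2
        for k in (0, 1):
            vk = values[k]
            # choice
            vt = vk[cs.t_item[k]]
            z = resp.rho_c * vt + resp.eta_c * cs.t_L[k] - resp.c0
            bll, g, dvi = _bernoulli_block(z, cs.t_acc[k], vt, cs.t_item[k], cs.M, want_grad)
            ll += bll
            if want_grad and g is not None:
                rgrad["rho_c"] += float(g @ vt)
                rgrad["eta_c"] += float(g @ cs.t_L[k])
                rgrad["c0"] -= float(np.sum(g))
                dv = resp.rho_c * dvi
                grads["v"] += dv
                if h3 and k == 1:
                    dB0 += dv
            # success (accepted trials)
            if len(cs.s_item[k]):
                vs = vk[cs.s_item[k]]
                z = resp.rho_s * vs + resp.eta_s * cs.s_L[k] + resp.s0
                bll, g, dvi = _bernoulli_block(
                    z, cs.s_suc[k], vs, cs.s_item[k], cs.M, want_grad
                )
                ll += bll
                if want_grad and g is not None:
                    rgrad["rho_s"] += float(g @ vs)
                    rgrad["eta_s"] += float(g @ cs.s_L[k])
                    rgrad["s0"] += float(np.sum(g))
                    dv = resp.rho_s * dvi
                    grads["v"] += dv
                    if h3 and k == 1:
                        dB0 += dv
            # force (successful trials)
            if len(cs.f_item[k]):
                vf = vk[cs.f_item[k]]
                mforce = resp.rho_f * vf + resp.eta_f * cs.f_L[k] + resp.f0
                res = cs.f_peak[k] - mforce
                ll += float(
                    -0.5 * np.sum(res**2) / varf
                    - len(res) * (math.log(resp.sigma_f) + 0.5 * LOG2PI)
                )
                if want_grad:
                    e = res / varf
                    rgrad["rho_f"] += float(e @ vf)
                    rgrad["eta_f"] += float(e @ cs.f_L[k])
                    rgrad["f0"] += float(np.sum(e))
                    rgrad["log_sigma_f"] += float(np.sum(res**2) / varf) - len(res)
                    dvi = np.bincount(cs.f_item[k], weights=e, minlength=cs.M)
                    dv = resp.rho_f * dvi
                    grads["v"] += dv
                    if h3 and k == 1:
                        dB0 += dv
        if want_grad:
            grads.update(rgrad)

    if want_grad:
        grads["bias"] = (cs.X[0] @ dB0 + cs.X[1] @ dB1) * mask
    return ll, grads


# ---------------------------------------------------------------------------
# Analytic Hessian (natural parameter order: V block then SCALAR_ORDER)
# ---------------------------------------------------------------------------

SCALAR_ORDER = (
    "b_choice", "b_success", "b_force", "b_time", "log_sigma_r",
    "rho_c", "eta_c", "c0", "rho_s", "eta_s", "s0",
    "rho_f", "eta_f", "f0", "log_sigma_f",
)


def _logistic_hess_block(
    ll_g_H, idx, L, vt, y, rho, eta, off, off_sign, si, M, x_cols
):
    """Accumulate one Bernoulli block: z = rho*v + eta*L + off_sign*off.

    ``x_cols`` is the (4, n) bias-regressor matrix when the values carry the
    session-1 bias (H3 session 2), else None.  Writes cross blocks into
    (V/bias row, scalar col) and the scalar-scalar upper triangle.
    """
    ll, g, H = ll_g_H
    i_rho, i_eta, i_off = si
    z = rho * vt + eta * L + off_sign * off
    ll += float(np.sum(y * _log_sigmoid(z) + (1.0 - y) * _log_sigmoid(-z)))
    p = 1.0 / (1.0 + np.exp(-z))
    w = p * (1.0 - p)
    gg = y - p
    bc = lambda vals: np.bincount(idx, weights=vals, minlength=M)

    g[:M] += rho * bc(gg)
    g[i_rho] += float(gg @ vt)
    g[i_eta] += float(gg @ L)
    g[i_off] += off_sign * float(np.sum(gg))

    bw = bc(w)
    H[np.arange(M), np.arange(M)] += -(rho**2) * bw
    H[:M, i_rho] += bc(-w * vt * rho + gg)
    H[:M, i_eta] += -rho * bc(w * L)
    H[:M, i_off] += -rho * off_sign * bw
    H[i_rho, i_rho] += -float(w @ (vt * vt))
    H[i_rho, i_eta] += -float((w * vt) @ L)
    H[i_rho, i_off] += -off_sign * float(w @ vt)
    H[i_eta, i_eta] += -float(w @ (L * L))
    H[i_eta, i_off] += -off_sign * float(w @ L)
    H[i_off, i_off] += -float(np.sum(w))

    if x_cols is not None:
        x = x_cols  # (4, n)
        bsl = slice(M, M + 4)
        g[bsl] += rho * (x @ gg)
        H[bsl, bsl] += np.triu(-(rho**2) * (x * w) @ x.T)
        for j in range(4):
            H[:M, M + j] += -(rho**2) * bc(w * x[j])
        H[bsl, i_rho] += x @ (-w * vt * rho + gg)
        H[bsl, i_eta] += -rho * (x @ (w * L))
        H[bsl, i_off] += -rho * off_sign * (x @ w)
    return ll


def loglik_hess(
    cs: CompiledSubject,
    spec: ModelSpec,
    v: np.ndarray,
    bias: BiasParameters,
    resp: ResponseParameters | None,
    sigma_r: float,
    scope: str = "extended",
):
    """Log-likelihood with analytic gradient and Hessian.

    Returns ``(ll, g, H)`` in the natural order: the M item values followed by
    :data:`SCALAR_ORDER`.  Used by the Newton optimizer and for the exact
    Laplace Hessian at the mode.
    """
    if sigma_r <= 0:
        raise ValueError("sigma_r must be > 0")
    M = len(cs.items)
    si = {name: M + j for j, name in enumerate(SCALAR_ORDER)}
    N = M + len(SCALAR_ORDER)
    g = np.zeros(N)
    H = np.zeros((N, N))
    ll = 0.0

    mask = spec.switch_mask()
    bvec = bias.as_array() * mask
    B0 = bvec @ cs.X[0]
    B1 = bvec @ cs.X[1]
    cumulative = spec.structure in ("H2", "H3")
    deltas = (np.zeros(cs.M), B0, B0 + B1 if cumulative else B1)
    G1 = cs.X[0].T  # (M, 4)
    G2 = cs.X[1].T + (cs.X[0].T if cumulative else 0.0)
    Gs = (None, G1, G2)

    q = 1.0 / sigma_r**2
    i_ls = si["log_sigma_r"]
    bsl = slice(M, M + 4)
    diag = np.arange(M)
    for s in range(3):
        m = cs.R_mask[:, s]
        mf = m.astype(float)
        res = np.where(m, cs.R_filled[:, s] - (v + deltas[s]), 0.0)
        n_obs = int(m.sum())
        ll += float(-0.5 * np.sum(res**2) * q - n_obs * (math.log(sigma_r) + 0.5 * LOG2PI))
        r = res * q
        g[:M] += r
        g[i_ls] += float(np.sum(res**2) * q) - n_obs
        H[diag, diag] += -q * mf
        H[:M, i_ls] += -2.0 * r
        H[i_ls, i_ls] += -2.0 * float(np.sum(res**2) * q)
        G = Gs[s]
        if G is not None:
            Gm = G * mf[:, None]
            g[bsl] += G.T @ r
            H[bsl, bsl] += np.triu(-q * (G.T @ Gm))
            H[:M, bsl] += -q * Gm
            H[bsl, i_ls] += -2.0 * (G.T @ r)

    if scope == "extended":
        if resp is None:
            raise ValueError("extended scope requires response parameters")
        h3 = spec.structure == "H3"
        qf = 1.0 / resp.sigma_f**2
        i_lf = si["log_sigma_f"]
        for k in (0, 1):
            vk = v + B0 if (h3 and k == 1) else v
            xc = cs.X[0][:, :] if (h3 and k == 1) else None
            # choice
            vt = vk[cs.t_item[k]]
            x_cols = xc[:, cs.t_item[k]] if xc is not None else None
            ll = _logistic_hess_block(
                (ll, g, H), cs.t_item[k], cs.t_L[k], vt, cs.t_acc[k],
                resp.rho_c, resp.eta_c, resp.c0, -1.0,
                (si["rho_c"], si["eta_c"], si["c0"]), M, x_cols,
            )
            # success
            if len(cs.s_item[k]):
                vt = vk[cs.s_item[k]]
                x_cols = xc[:, cs.s_item[k]] if xc is not None else None
                ll = _logistic_hess_block(
                    (ll, g, H), cs.s_item[k], cs.s_L[k], vt, cs.s_suc[k],
                    resp.rho_s, resp.eta_s, resp.s0, +1.0,
                    (si["rho_s"], si["eta_s"], si["s0"]), M, x_cols,
                )
            # force
            if len(cs.f_item[k]):
                idx = cs.f_item[k]
                L = cs.f_L[k]
                vt = vk[idx]
                res = cs.f_peak[k] - (resp.rho_f * vt + resp.eta_f * L + resp.f0)
                n = len(res)
                ll += float(
                    -0.5 * np.sum(res**2) * qf
                    - n * (math.log(resp.sigma_f) + 0.5 * LOG2PI)
                )
                e = res * qf
                bc = lambda vals: np.bincount(idx, weights=vals, minlength=M)
                i_r, i_e, i_0 = si["rho_f"], si["eta_f"], si["f0"]
                rho = resp.rho_f
                g[:M] += rho * bc(e)
                g[i_r] += float(e @ vt)
                g[i_e] += float(e @ L)
                g[i_0] += float(np.sum(e))
                g[i_lf] += float(np.sum(res**2) * qf) - n
                cnt = bc(np.ones(n))
                H[diag, diag] += -(rho**2) * qf * cnt
                H[:M, i_r] += bc(-qf * vt * rho + e)
                H[:M, i_e] += -rho * qf * bc(L)
                H[:M, i_0] += -rho * qf * cnt
                H[:M, i_lf] += -2.0 * rho * bc(e)
                H[i_r, i_r] += -qf * float(vt @ vt)
                H[i_r, i_e] += -qf * float(vt @ L)
                H[i_r, i_0] += -qf * float(np.sum(vt))
                H[i_r, i_lf] += -2.0 * float(e @ vt)
                H[i_e, i_e] += -qf * float(L @ L)
                H[i_e, i_0] += -qf * float(np.sum(L))
                H[i_e, i_lf] += -2.0 * float(e @ L)
                H[i_0, i_0] += -qf * n
                H[i_0, i_lf] += -2.0 * float(np.sum(e))
                H[i_lf, i_lf] += -2.0 * float(np.sum(res**2) * qf)
                if xc is not None:
                    x = xc[:, idx]
                    g[bsl] += rho * (x @ e)
                    H[bsl, bsl] += np.triu(-(rho**2) * qf * (x @ x.T))
                    for j in range(4):
                        H[:M, M + j] += -(rho**2) * qf * bc(x[j])
                    H[bsl, i_r] += x @ (-qf * vt * rho + e)
                    H[bsl, i_e] += -rho * qf * (x @ L)
                    H[bsl, i_0] += -rho * qf * x.sum(axis=1)
                    H[bsl, i_lf] += -2.0 * rho * (x @ e)

    # mask inactive bias rows/cols and symmetrize
    for j, name in enumerate(BIAS_NAMES):
        if not mask[j]:
            g[M + j] = 0.0
            H[M + j, :] = 0.0
            H[:, M + j] = 0.0
    H = H + H.T - np.diag(np.diag(H))
    return ll, g, H


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def compute_bias(
    regressors: ActionRegressors, bias: BiasParameters, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Total per-(item, session) bias b = b_C C + b_S S + b_F F + b_T.

    Items without an effort trial (excluded items) carry zero bias and are
    simply absent from the returned table.
    """
    if regressors.scheme != "signed":
        raise ValueError("bias computation requires the signed coding scheme")
    bvec = bias.as_array()
    if spec is not None:
        bvec = bvec * spec.switch_mask()
    t = regressors.table
    b = bvec[0] * t["C"] + bvec[1] * t["S"] + bvec[2] * t["F"] + bvec[3]
    return pd.DataFrame(
        {"item_id": t["item_id"], "session": t["session"], "bias": b}
    )


def _value_vector(ds_or_cs, v) -> tuple[CompiledSubject, np.ndarray]:
    cs = ds_or_cs if isinstance(ds_or_cs, CompiledSubject) else CompiledSubject(ds_or_cs)
    if isinstance(v, dict):
        v = np.array([v[it] for it in cs.items], dtype=float)
    return cs, np.asarray(v, dtype=float)


def predict_ratings(ds, spec: ModelSpec, v, bias: BiasParameters, sigma_r: float) -> float:
    """Summed Gaussian log-density of all observed ratings under the model."""
    cs, v = _value_vector(ds, v)
    ll, _ = loglik_terms(cs, spec, v, bias, None, sigma_r, scope="ratings_only")
    return ll


def predict_actions(
    ds, spec: ModelSpec, v, bias: BiasParameters, resp: ResponseParameters
) -> float:
    """Summed log-density of choices, successes and forces under the model."""
    cs, v = _value_vector(ds, v)
    full, _ = loglik_terms(cs, spec, v, bias, resp, resp.sigma_r, scope="extended")
    ratings_part, _ = loglik_terms(
        cs, spec, v, bias, None, resp.sigma_r, scope="ratings_only"
    )
    return full - ratings_part


def model_loglik(
    ds,
    spec: ModelSpec,
    v,
    bias: BiasParameters,
    resp: ResponseParameters | None = None,
    sigma_r: float | None = None,
    scope: str = "extended",
) -> float:
    """Joint model log-likelihood over the requested scope."""
    if spec.hypothesis == "H3" and scope == "ratings_only":
        raise ValueError("H3 requires the extended scope")
    if sigma_r is None:
        if resp is None:
            raise ValueError("provide sigma_r or response parameters")
        sigma_r = resp.sigma_r
    cs, v = _value_vector(ds, v)
    ll, _ = loglik_terms(cs, spec, v, bias, resp, sigma_r, scope=scope)
    return ll
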