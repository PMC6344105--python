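"""Task-design construction and synthetic cohort generation.

The generator emulates the rating / effort / rating / effort / rating
paradigm: items are rated on a 0-100 visual-analogue scale, ranked on the
first rating, stripped of the 15 highest and 15 lowest ranked items (plus,
in Exp 2-3 style designs, 30 random control items that are rated but never
offered), and the remaining 90 items are paired with target force levels
between 20% and 120% of maximal grip force, orthogonally to the ratings.
Targets above 100% are unreachable by design and produce failures.

Behaviour is then generated under any of the H0-H3 hypotheses with the
response functions of :mod:`prefdrift.models`: sequential per effort session,
so that the bias induced by session k's actions can feed the values used from
session k+1 onward (H3) or the later ratings (H1/H2).

Generated ratings are *not* clipped to [0, 100] by default: clipping would
break the Gaussian rating likelihood that the models assume.  A ``clip`` flag
exists for realism studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SubjectDataset
from .models import BiasParameters, ModelSpec, ResponseParameters

#: Generator defaults used for parameter-recovery studies.  The bias weights
#: sit in the regime of the group estimates this package is built to recover
#: (choice ~ +1.8, success ~ +0.7, no force effect, slight negative drift);
#: the response parameters give ~50% acceptance, strong value and target
#: sensitivity of choice, failures concentrated on near- and supra-maximal
#: targets, and force tracking the target level.
DEFAULT_BIAS = BiasParameters(choice=1.8, success=0.7, force=0.0, time=-0.3)
DEFAULT_RESPONSE = ResponseParameters(
    rho_c=0.2,
    eta_c=-4.5,
    c0=6.85,
    rho_s=0.03,
    eta_s=-8.0,
    s0=7.0,
    rho_f=0.001,
    eta_f=0.85,
    f0=0.15,
    sigma_f=0.07,
    sigma_r=5.0,
)

LEVEL_MIN, LEVEL_MID, LEVEL_MAX = 0.20, 0.70, 1.20
ORTHO_TOL = 0.05


class ConfigurationError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass
class DesignPairing:
    """Mapping from item rank (1 = highest first rating) to target level,
    one column per effort session."""

    scheme: str
    levels: np.ndarray  # (n_ranks, 2)


def diamond_levels(n_ranks: int = 90) -> np.ndarray:
    """The fixed diamond-shaped rank -> level mapping.

    Rank r gets ``0.70 + s_r * 0.50 * (1 - d_r)`` with
    ``d_r = |r - (n+1)/2| / ((n-1)/2)`` and a sign ``s_r`` alternating between
    adjacent ranks (positive at rank 1), so extremes of rank sit near 70%
    F_max while mid-ranked items alternate near 20% and 120%.
    """
    r = np.arange(1, n_ranks + 1, dtype=float)
    d = np.abs(r - (n_ranks + 1) / 2.0) / ((n_ranks - 1) / 2.0)
    s = np.where(np.arange(n_ranks) % 2 == 0, 1.0, -1.0)
    return LEVEL_MID + s * 0.50 * (1.0 - d)


def _rank_corr(levels: np.ndarray) -> float:
    ranks = np.arange(1, len(levels) + 1)
    return float(np.corrcoef(ranks, levels)[0, 1])


def build_pairing(
    scheme: str,
    n_ranks: int = 90,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 10_000,
) -> DesignPairing:
    """Construct the rank -> target-level pairing for both effort sessions.

    ``diamond_fixed`` uses the deterministic diamond for both sessions;
    ``randomized_orthogonal`` rejection-samples permutations of the same level
    multiset until rank/level (and the two sessions' levels) are orthogonal.
    """
    base = diamond_levels(n_ranks)
    if scheme == "diamond_fixed":
        return DesignPairing(scheme, np.column_stack([base, base]))
    if scheme != "randomized_orthogonal":
        raise ConfigurationError(f"unknown pairing scheme '{scheme}'")
    rng = np.random.default_rng(rng)
    columns = []
    iters = 0
    while len(columns) < 2:
        perm = rng.permutation(base)
        iters += 1
        if iters > max_iter:
            raise ConfigurationError(
                f"pairing rejection sampling exceeded {max_iter} iterations"
            )
        if abs(_rank_corr(perm)) >= ORTHO_TOL:
            continue
        if columns and abs(np.corrcoef(columns[0], perm)[0, 1]) >= ORTHO_TOL:
            continue
        columns.append(perm)
    return DesignPairing(scheme, np.column_stack(columns))


def select_items(
    n_items: int,
    first_ratings: np.ndarray,
    n_random_excluded: int,
    rng: np.random.Generator | int | None = None,
    n_extreme_excluded: int = 30,
    n_presented: int = 90,
) -> dict:
    """Partition items into presented / extreme-excluded / random-excluded.

    Extremes are the ``n_extreme_excluded/2`` highest- and lowest-ranked items
    on the first rating; random exclusions are drawn uniformly from the rest.
    Returns index arrays into the item order of ``first_ratings``.
    """
    if n_items - n_extreme_excluded - n_random_excluded != n_presented:
        raise ConfigurationError(
            f"{n_items} items minus {n_extreme_excluded} extreme and "
            f"{n_random_excluded} random exclusions must leave {n_presented}"
        )
    if len(first_ratings) != n_items:
        raise ConfigurationError("first_ratings length must equal n_items")
    rng = np.random.default_rng(rng)
    order = np.argsort(-np.asarray(first_ratings, dtype=float), kind="stable")
    half = n_extreme_excluded // 2
    extreme = np.concatenate([order[:half], order[n_items - (n_extreme_excluded - half):]])
    middle = order[half : n_items - (n_extreme_excluded - half)]
    random_exc = rng.choice(middle, size=n_random_excluded, replace=False)
    presented = np.array([i for i in middle if i not in set(random_exc.tolist())])
    return {
        "presented": presented,  # in descending first-rating order (rank 1 first)
        "excluded_extreme": extreme,
        "excluded_random": random_exc,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 24
    n_items: int = 150
    experiment: int = 2
    model: ModelSpec = field(
        default_factory=lambda: ModelSpec(
            "H3", choice=True, success=True, time=True
        )
    )
    bias: BiasParameters = DEFAULT_BIAS
    resp: ResponseParameters = DEFAULT_RESPONSE
    value_mean: float = 50.0
    value_sd: float = 20.0
    n_extreme_excluded: int = 30
    n_random_excluded: int | None = None  # derived from experiment when None
    n_presented: int = 90
    pairing_scheme: str | None = None  # derived from experiment when None
    clip: bool = False
    max_pairing_iter: int = 10_000

    def __post_init__(self):
        if self.experiment not in (1, 2, 3):
            raise ConfigurationError("experiment must be 1, 2 or 3")
        if self.n_random_excluded is None:
            self.n_random_excluded = 0 if self.experiment == 1 else 30
        if self.pairing_scheme is None:
            self.pairing_scheme = (
                "diamond_fixed" if self.experiment == 1 else "randomized_orthogonal"
            )
        if self.value_sd <= 0:
            raise ConfigurationError("value_sd must be > 0")
        if self.n_items - self.n_extreme_excluded - self.n_random_excluded != self.n_presented:
            raise ConfigurationError(
                "item counts do not add up: n_items - extremes - random != presented"
            )


def _hand_sequence(n: int, block: int = 15) -> np.ndarray:
    blocks = (np.arange(n) // block) % 2
    return np.where(blocks == 0, "R", "L")


def _session_zscore(x: np.ndarray) -> np.ndarray:
    if len(x) < 2 or x.std() == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / x.std()



def _generate_behaviour(model, bias, resp, v1, pres, levels, rng, clip):
    """Sequential behaviour generation on a fixed design.

    Returns the (n_items, 3) rating matrix and per-trial records; the bias
    realized in effort session k feeds the ratings of session k+1 (H1/H2) or
    the values used from session k+1 onward (H3).
    """
    M = len(v1)
    bvec = bias.as_array() * model.switch_mask()
    ratings = np.empty((M, 3))
    ratings[:, 0] = v1 + rng.normal(0.0, resp.sigma_r, size=M)
    cum_bias = np.zeros(M)
    trial_rows = []
    for k in (0, 1):
        L = levels[:, k]
        v_now = v1 + cum_bias if model.structure == "H3" else v1
        vp = v_now[pres]
        p_acc = 1.0 / (1.0 + np.exp(-(resp.rho_c * vp + resp.eta_c * L - resp.c0)))
        acc = rng.random(len(pres)) < p_acc
        suc = np.zeros(len(pres), dtype=bool)
        p_suc = 1.0 / (1.0 + np.exp(-(resp.rho_s * vp + resp.eta_s * L + resp.s0)))
        suc[acc] = rng.random(int(acc.sum())) < p_suc[acc]
        peak = np.full(len(pres), np.nan)
        if suc.any():
            m = resp.rho_f * vp[suc] + resp.eta_f * L[suc] + resp.f0
            a = (L[suc] - m) / resp.sigma_f
            peak[suc] = stats.truncnorm.rvs(
                a, np.inf, loc=m, scale=resp.sigma_f, random_state=rng
            )
        failed = acc & ~suc
        if failed.any():
            peak[failed] = rng.uniform(LEVEL_MIN + 1e-9, L[failed])

        C = np.where(acc, 1.0, -1.0)
        S = np.where(suc, 1.0, np.where(failed, -1.0, 0.0))
        F = np.zeros(len(pres))
        F[suc] = _session_zscore(peak[suc])
        session_bias = bvec[0] * C + bvec[1] * S + bvec[2] * F + bvec[3]
        cum_bias[pres] += session_bias

        if model.hypothesis == "H0" and not model.time:
            delta = np.zeros(M)
        elif model.structure == "H1":
            delta = np.zeros(M)
            delta[pres] = session_bias
        else:  # cumulative structures H2 / H3
            delta = cum_bias
        ratings[:, k + 1] = v1 + delta + rng.normal(0.0, resp.sigma_r, size=M)

        order = rng.permutation(len(pres))
        hands = _hand_sequence(len(pres))
        for trial_index, j in enumerate(order):
            trial_rows.append(
                {
                    "session": k + 1,
                    "trial_index": trial_index,
                    "pres_pos": int(j),
                    "target_level": float(L[j]),
                    "accepted": int(acc[j]),
                    "success": (int(suc[j]) if acc[j] else np.nan),
                    "peak_force": (float(peak[j]) if not np.isnan(peak[j]) else np.nan),
                    "hand": hands[trial_index],
                }
            )
    if clip:
        ratings = np.clip(ratings, 0.0, 100.0)
    return ratings, trial_rows


def _trials_frame(trial_rows, pres_item_ids):
    rows = []
    for r in trial_rows:
        r = dict(r)
        r["item_id"] = pres_item_ids[r.pop("pres_pos")]
        rows.append(r)
    cols = ["session", "trial_index", "item_id", "target_level",
            "accepted", "success", "peak_force", "hand"]
    return pd.DataFrame(rows)[cols]


def simulate_subject(
    cfg: GeneratorConfig,
    seed=None,
    subject_id: str = "S001",
    pairing: DesignPairing | None = None,
    v1: np.ndarray | None = None,
) -> SubjectDataset:
    """Generate one participant under the configured hypothesis.

    The first rating session is a noisy read-out of the initial values; item
    selection and rank -> target pairing follow the first ratings; effort
    behaviour is generated session by session so that realized actions
    determine the bias carried into later ratings (H1/H2) or values (H3).

    ``v1`` overrides the latent item values (otherwise drawn from the value
    prior); the bootstrap null control uses this to replay the full paradigm
    -- including the rank-based item selection that creates the
    regression-to-the-mean confound -- from a subject's fitted values.
    """
    rng = np.random.default_rng(seed)
    M = cfg.n_items
    resp, bias, model = cfg.resp, cfg.bias, cfg.model

    item_ids = np.array([f"I{i + 1:03d}" for i in range(M)])
    if v1 is None:
        v1 = rng.normal(cfg.value_mean, cfg.value_sd, size=M)
    else:
        v1 = np.asarray(v1, dtype=float)
        if len(v1) != M:
            raise ConfigurationError("v1 override must provide one value per item")
    first = v1 + rng.normal(0.0, resp.sigma_r, size=M)
    part = select_items(
        M, first, cfg.n_random_excluded, rng, cfg.n_extreme_excluded, cfg.n_presented
    )
    pres = part["presented"]  # rank order: highest first rating first
    if pairing is None:
        pairing = build_pairing(
            cfg.pairing_scheme, cfg.n_presented, rng, cfg.max_pairing_iter
        )

    # regenerate with the pre-drawn R1 so selection is based on it
    ratings, trial_rows = _generate_behaviour(
        model, bias, resp, v1, pres, pairing.levels, rng, cfg.clip
    )
    ratings[:, 0] = np.clip(first, 0.0, 100.0) if cfg.clip else first

    excluded = np.zeros(M, dtype=int)
    excluded[part["excluded_extreme"]] = 1
    excluded[part["excluded_random"]] = 1
    rating_rows = pd.DataFrame(
        {
            "item_id": np.tile(item_ids, 3),
            "session": np.repeat([1, 2, 3], M),
            "rating": ratings.T.ravel(),
            "excluded": np.tile(excluded, 3),
        }
    )
    ds = SubjectDataset(
        subject_id=subject_id,
        experiment=cfg.experiment,
        ratings=rating_rows,
        trials=_trials_frame(trial_rows, item_ids[pres]),
        f_max=float(rng.normal(350.0, 40.0)),
        item_partition={
            "presented": item_ids[pres].tolist(),
            "excluded_extreme": item_ids[part["excluded_extreme"]].tolist(),
            "excluded_random": item_ids[part["excluded_random"]].tolist(),
        },
    )
    return ds


def simulate_cohort(cfg: GeneratorConfig, seed=None) -> list[SubjectDataset]:
    """Independent subjects with per-subject seeds spawned from the master."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_subjects)
    return [
        simulate_subject(cfg, seed=child, subject_id=f"S{i + 1:03d}")
        for i, child in enumerate(children)
    ]


def resimulate_subject(
    ds: SubjectDataset,
    v1: np.ndarray,
    resp: ResponseParameters,
    rng=None,
    model: ModelSpec | None = None,
    bias: BiasParameters | None = None,
) -> SubjectDataset:
    """Regenerate a subject's behaviour on their *own* design.

    Used by the bootstrap null control: the fitted H0 parameters (item values,
    rating noise, response parameters) drive the generator with all biases at
    zero, on the original item partition and force pairing.  ``v1`` is aligned
    with the sorted item-id order of ``ds``.
    """
    rng = np.random.default_rng(rng)
    model = model or ModelSpec("H0", structure="H3")
    bias = bias or BiasParameters()
    items, _ = ds.rating_matrix()
    index = {it: i for i, it in enumerate(items)}
    v1 = np.asarray(v1, dtype=float)
    if len(v1) != len(items):
        raise ValueError("v1 must provide one value per rated item")

    pres_ids = ds.presented_items
    pres = np.array([index[it] for it in pres_ids])
    levels = np.zeros((len(pres), 2))
    for k in (1, 2):
        sub = ds.trials[ds.trials["session"] == k]
        lev = dict(zip(sub["item_id"], sub["target_level"]))
        levels[:, k - 1] = [lev[it] for it in pres_ids]

    cfg = GeneratorConfig(
        n_subjects=1,
        n_items=len(items),
        experiment=ds.experiment,
        model=model,
        bias=bias,
        resp=resp,
        n_extreme_excluded=len(ds.item_partition.get("excluded_extreme", [])),
        n_random_excluded=len(ds.item_partition.get("excluded_random", [])),
        n_presented=len(pres),
    )
    sim = _replay(cfg, ds, v1, pres, levels, rng)
    return sim


def _replay(cfg, ds, v1, pres, levels, rng) -> SubjectDataset:
    """Behaviour generation on a fixed design (shared by the bootstrap)."""
    items, _ = ds.rating_matrix()
    item_ids = np.array(items)
    M = len(items)
    ratings, trial_rows = _generate_behaviour(
        cfg.model, cfg.bias, cfg.resp, v1, pres, levels, rng, cfg.clip
    )
    excluded_ids = set(ds.excluded_items)
    excluded = np.array([1 if it in excluded_ids else 0 for it in item_ids])
    rating_rows = pd.DataFrame(
        {
            "item_id": np.tile(item_ids, 3),
            "session": np.repeat([1, 2, 3], M),
            "rating": ratings.T.ravel(),
            "excluded": np.tile(excluded, 3),
        }
    )
    return SubjectDataset(
        subject_id=ds.subject_id,
        experiment=ds.experiment,
        ratings=rating_rows,
        trials=_trials_frame(trial_rows, item_ids[pres]),
        f_max=ds.f_max,
        item_partition=dict(ds.item_partition),
    )
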