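"""Bootstrap control for the regression-to-the-mean artifact.

Even with stable values, noisy ratings plus rank-based item selection make
action regressors correlate with first-session rating noise, so *any*
estimator that contrasts post-action ratings with R1 acquires a small
positive bias on the choice weight.  The control: simulate cohorts under the
null (fitted H0 parameters, all biases zero, each subject's own design),
refit the bias models on the mock data, and benchmark the real estimates
against the resulting null distribution — via 95% credible-interval
classification per subject and Welch two-sample tests at the group level
(n real values vs n values drawn from the null pool, p averaged over many
redraws for stability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_free import group_ttest
from .models import BiasParameters, ModelSpec, ResponseParameters
from .synthetic import GeneratorConfig, resimulate_subject, simulate_subject

logger = logging.getLogger("prefdrift")


@dataclass
class NullDistribution:
    """Bootstrap samples of bias estimates under H0, one pool per parameter."""

    samples: dict[str, np.ndarray]
    ci: dict[str, tuple[float, float]]
    config: dict

    @classmethod
    def from_samples(cls, samples: dict, config: dict | None = None) -> "NullDistribution":
        samples = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
        ci = {}
        for k, v in samples.items():
            if len(v) < 50:
                logger.warning(
                    "null pool for %s has only %d samples; percentiles unstable", k, len(v)
                )
            lo, hi = np.percentile(v, [2.5, 97.5])
            if lo == hi:
                logger.warning("degenerate null distribution for %s (zero-width CI)", k)
            ci[k] = (float(lo), float(hi))
        return cls(samples=samples, ci=ci, config=config or {})

    def to_dict(self) -> dict:
        return {
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_samples": {k: int(len(v)) for k, v in self.samples.items()},
            "mean": {k: float(v.mean()) for k, v in self.samples.items()},
            "config": self.config,
        }


def _fitted_response(fit) -> ResponseParameters:
    return ResponseParameters(
        **{
            n: fit.get(n)
            for n in ("rho_c", "eta_c", "c0", "rho_s", "eta_s", "s0",
                      "rho_f", "eta_f", "f0")
        },
        sigma_f=fit.params.get("sigma_f", 0.1),
        sigma_r=fit.params["sigma_r"],
    )


def simulate_null_cohort(
    h0_fits: dict,
    cohort,
    n_replicates: int = 1,
    seed=0,
    redraw_design: bool = True,
) -> list[list]:
    """Mock cohorts driven by each subject's fitted H0 parameters.

    ``h0_fits`` maps subject_id -> extended-scope H0 fit (item values, rating
    noise SD and response parameters); behaviour is regenerated with all
    biases at zero under each subject's own design configuration.

    By default the *whole* paradigm is replayed per replicate -- fresh first
    ratings, fresh rank-based item exclusion, fresh force pairing -- with the
    fitted values as the latent truth.  That selection step is what creates
    the regression-to-the-mean confound, so replaying it is what makes the
    null distribution an estimate of the effect size expected from chance.
    ``redraw_design=False`` instead freezes the original item partition and
    pairing (a design-conditional null, without the selection confound).
    """
    missing = [ds.subject_id for ds in cohort if ds.subject_id not in h0_fits]
    if missing:
        raise ValueError(f"missing H0 fits for subjects: {missing}")
    null_model = ModelSpec("H0", structure="H3")
    ss = np.random.SeedSequence(seed)
    replicates = []
    for child in ss.spawn(n_replicates):
        seeds = child.spawn(len(cohort))
        mock = []
        for ds, sub_seed in zip(cohort, seeds):
            fit = h0_fits[ds.subject_id]
            resp = _fitted_response(fit)
            v1 = np.asarray(fit.params["v"], dtype=float)
            if redraw_design:
                cfg = GeneratorConfig(
                    n_subjects=1,
                    n_items=len(v1),
                    experiment=ds.experiment,
                    model=null_model,
                    bias=BiasParameters(),
                    resp=resp,
                    n_extreme_excluded=len(ds.item_partition.get("excluded_extreme", [])),
                    n_random_excluded=len(ds.item_partition.get("excluded_random", [])),
                    n_presented=len(ds.presented_items),
                )
                mock.append(
                    simulate_subject(
                        cfg, seed=sub_seed, subject_id=ds.subject_id, v1=v1
                    )
                )
            else:
                mock.append(
                    resimulate_subject(
                        ds, v1, resp,
                        rng=np.random.default_rng(sub_seed),
                        model=null_model,
                    )
                )
        replicates.append(mock)
    return replicates


def build_null_distribution(
    mock_bma_tables,
    params=("b_choice", "b_success", "b_force", "b_time"),
    config: dict | None = None,
) -> NullDistribution:
    """Pool per-subject BMA estimates across mock cohorts into null samples."""
    pools: dict[str, list[float]] = {p: [] for p in params}
    for table in mock_bma_tables:
        for p in params:
            if p in table:
                pools[p].extend(np.asarray(table[p], dtype=float))
    pools = {p: v for p, v in pools.items() if v}
    if not pools:
        raise ValueError("no null samples supplied")
    return NullDistribution.from_samples(pools, config)


def welch_compare(
    real: dict[str, np.ndarray] | "pd.DataFrame",
    null: NullDistribution,
    n_draws: int | None = None,
    n_repetitions: int = 1000,
    seed=0,
    statistic: str = "mean",
) -> dict[str, float]:
    """Average Welch p over repeated draws of null values.

    Each repetition draws ``n_draws`` values (default: as many as there are
    real values) from the null pool without replacement (with replacement if
    the pool is smaller), runs a two-tailed Welch test against the real
    values, and the p-values are averaged over repetitions (``statistic`` may
    be set to ``"median"`` for the median-p variant).
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for param, values in _iter_columns(real):
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            raise ValueError("need at least two real values per parameter")
        pool = null.samples.get(param)
        if pool is None or len(pool) == 0:
            raise ValueError(f"empty null pool for {param}")
        k = n_draws or len(values)
        ps = np.empty(n_repetitions)
        for rep in range(n_repetitions):
            draw = rng.choice(pool, size=k, replace=len(pool) < k)
            ps[rep] = group_ttest(
                values, mode="welch_two_sample", other=draw, factor=param
            ).p
        out[param] = float(np.mean(ps) if statistic == "mean" else np.median(ps))
    return out


def classify_subjects(real, null: NullDistribution) -> dict[str, np.ndarray]:
    """Flag which subjects' estimates fall inside the null 95% CI."""
    flags = {}
    for param, values in _iter_columns(real):
        lo, hi = null.ci[param]
        v = np.asarray(values, dtype=float)
        flags[param] = (v >= lo) & (v <= hi)
    return flags


def _iter_columns(table):
    if hasattr(table, "columns"):  # DataFrame
        for c in table.columns:
            yield c, table[c].to_numpy()
    else:
        yield from table.items()
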