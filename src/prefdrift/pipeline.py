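"""End-to-end orchestration: load -> code -> model-free -> fit -> compare ->
null check, with every artifact serialized and stamped with config hash and
seed so each report cell is re-derivable."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core_data, model_free, null_validation, selection
from .coding import build_regressors
from .inversion import PriorSpec, fit_cohort
from .models import ModelSpec, enumerate_model_space

logger = logging.getLogger("prefdrift")


@dataclass
class PipelineConfig:
    ratings_path: str
    trials_path: str
    out_dir: str
    seed: int = 0
    scope: str = "extended"
    scheme: str = "signed"
    hypotheses: tuple = ("H0", "H1", "H2", "H3")
    models: list | None = None  # explicit list of ModelSpec dicts; overrides hypotheses
    n_restarts: int = 1
    min_failures: int = core_data.DEFAULT_MIN_FAILURES
    null_replicates: int = 0  # 0 disables the bootstrap stage
    welch_repetitions: int = 1000
    xp_samples: int = selection.DEFAULT_XP_SAMPLES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for p in (cfg.ratings_path, cfg.trials_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def model_space_from_config(cfg: PipelineConfig) -> list[ModelSpec]:
    if cfg.models:
        return [ModelSpec.from_dict(d) for d in cfg.models]
    return enumerate_model_space(cfg.hypotheses, scope=cfg.scope)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; on stage failure, emit a partial bundle plus manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.digest(), "seed": cfg.seed}
    manifest: dict = {"stamp": stamp, "stages": {}}
    bundle: dict = {"stamp": stamp}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            logger.error("stage %s failed: %s", name, exc)
            return None

    # --- load ---
    cohort = stage(
        "load",
        lambda: core_data.apply_failure_exclusion(
            core_data.load_dataset(cfg.ratings_path, cfg.trials_path),
            cfg.min_failures,
        )[0],
    )
    if cohort is None:
        core_data.save_json(manifest, out / "manifest.json")
        return {"manifest": manifest}

    # --- coding ---
    def _code():
        frames = []
        for ds in cohort:
            t = build_regressors(ds, cfg.scheme).table.copy()
            t.insert(0, "subject_id", ds.subject_id)
            frames.append(t)
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "regressors.csv", index=False)
        return df

    stage("code", _code)

    # --- model-free ---
    def _modelfree():
        betas = model_free.cohort_delta_betas(cohort)
        betas.to_csv(out / "betas.csv")
        tests = {
            f"beta_{c}": model_free.group_ttest(betas[c].to_numpy(), factor=c).to_dict()
            for c in betas.columns
        }
        core_data.save_json({**stamp, "tests": tests}, out / "group_tests.json")
        return betas

    betas = stage("modelfree", _modelfree)

    # --- fit ---
    space = model_space_from_config(cfg)

    def _fit():
        ev, fits, failures = fit_cohort(
            cohort,
            space,
            priors=PriorSpec(),
            scope=cfg.scope,
            n_restarts=cfg.n_restarts,
            seed=cfg.seed,
        )
        ev.to_csv(out / "evidence_matrix.csv")
        fit_dir = out / "fits"
        fit_dir.mkdir(exist_ok=True)
        for (sid, label), fit in fits.items():
            core_data.save_json(
                {**stamp, **fit.to_dict()},
                fit_dir / f"{sid}_{label.replace('[', '_').strip(']')}.json",
            )
        if failures:
            core_data.save_json(failures, out / "fit_failures.json")
        return ev, fits

    fit_result = stage("fit", _fit)
    if fit_result is None:
        core_data.save_json(manifest, out / "manifest.json")
        return {"manifest": manifest, "betas": betas}
    evidence, fits = fit_result

    # --- compare ---
    def _compare():
        clean = evidence.dropna(axis=0)
        fams = selection.hypothesis_families(space)
        bms = selection.family_bms(
            clean, fams, xp_samples=cfg.xp_samples, seed=cfg.seed
        )
        report_rows = []
        bma_frames = {}
        for hyp, members in fams.items():
            if hyp == "H0":
                continue
            bma = selection.cohort_bma(fits, members, scope_label=hyp)
            bma_frames[hyp] = bma
            for factor, col in (
                ("Choice", "b_choice"),
                ("Success", "b_success"),
                ("Force", "b_force"),
                ("Time", "b_time"),
            ):
                fam_split = selection.factor_families(
                    [m for m in space if m.label in members or m.family == "H0"],
                    col.removeprefix("b_"),
                )
                sub = clean[[m.label for m in space if m.label in members or m.family == "H0"]]
                fbms = selection.family_bms(
                    sub, fam_split, xp_samples=cfg.xp_samples, seed=cfg.seed
                )
                test = model_free.group_ttest(bma[col].to_numpy(), factor=factor)
                report_rows.append(
                    {
                        "family": hyp,
                        "factor": factor,
                        "xp": fbms.family_exceedance_probability.get("with", 0.0),
                        "ef": fbms.family_expected_frequency.get("with", 0.0),
                        "bma_mean": test.mean,
                        "bma_sem": test.sem,
                        "p": test.p,
                    }
                )
        core_data.save_json({**stamp, **bms.to_dict()}, out / "bms.json")
        pd.concat(bma_frames, names=["family"]).to_csv(out / "bma.csv")
        report = pd.DataFrame(report_rows)
        report.to_csv(out / "report.csv", index=False)
        return bms, bma_frames, report

    compare_result = stage("compare", _compare)

    # --- null check ---
    def _nullcheck():
        h0_label = ModelSpec("H0", structure=space[-1].structure).label
        h0_fits = {
            sid: fit for (sid, label), fit in fits.items() if label == h0_label
        }
        mocks = null_validation.simulate_null_cohort(
            h0_fits, cohort, n_replicates=cfg.null_replicates, seed=cfg.seed + 1
        )
        fams = selection.hypothesis_families(space)
        target_fam = next(h for h in ("H3", "H2", "H1") if h in fams)
        tables = []
        for mock in mocks:
            _, mock_fits, _ = fit_cohort(
                cohort=mock,
                model_space=[m for m in space if m.label in fams[target_fam]],
                scope=cfg.scope,
                n_restarts=1,
                seed=cfg.seed + 2,
            )
            tables.append(selection.cohort_bma(mock_fits, fams[target_fam]))
        null = null_validation.build_null_distribution(tables, config=stamp)
        real_bma = compare_result[1][target_fam]
        pvals = null_validation.welch_compare(
            real_bma, null, n_repetitions=cfg.welch_repetitions, seed=cfg.seed + 3
        )
        flags = null_validation.classify_subjects(real_bma, null)
        core_data.save_json({**stamp, **null.to_dict()}, out / "null_distribution.json")
        core_data.save_json({**stamp, "p": pvals}, out / "welch_p.json")
        pd.DataFrame(
            {k: v.astype(int) for k, v in flags.items()}, index=real_bma.index
        ).to_csv(out / "subject_flags.csv")
        return null, pvals

    if cfg.null_replicates > 0 and compare_result is not None:
        stage("nullcheck", _nullcheck)

    core_data.save_json(manifest, out / "manifest.json")
    bundle.update(
        manifest=manifest,
        evidence=evidence,
        betas=betas,
        compare=compare_result,
    )
    return bundle
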