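import numpy as np
import pandas as pd
import pytest

from prefdrift import (
    BiasParameters,
    GeneratorConfig,
    ModelSpec,
    ResponseParameters,
    SubjectDataset,
    simulate_cohort,
)


def small_config(**overrides) -> GeneratorConfig:
    """A scaled-down study (24 presented of 40 items) for fast unit tests."""
    base = dict(
        n_subjects=3,
        n_items=40,
        n_extreme_excluded=8,
        n_random_excluded=8,
        n_presented=24,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(), seed=11)


@pytest.fixture(scope="session")
def h0_small_cohort():
    cfg = small_config(model=ModelSpec("H0", structure="H3"), bias=BiasParameters())
    return simulate_cohort(cfg, seed=12)


def make_dataset(subject_id="T1", experiment=1, ratings=None, trials=None, partition=None):
    """Hand-built dataset from row dicts (defaults form a tiny valid design)."""
    rating_cols = ["item_id", "session", "rating", "excluded"]
    trial_cols = [
        "session", "trial_index", "item_id", "target_level",
        "accepted", "success", "peak_force", "hand",
    ]
    rdf = pd.DataFrame(ratings, columns=rating_cols)
    tdf = pd.DataFrame(trials if trials is not None else [], columns=trial_cols)
    if partition is None:
        presented = sorted(tdf["item_id"].unique()) if len(tdf) else []
        excluded = [i for i in rdf["item_id"].unique() if i not in presented]
        partition = {
            "presented": presented,
            "excluded_extreme": excluded,
            "excluded_random": [],
        }
    return SubjectDataset(
        subject_id=subject_id,
        experiment=experiment,
        ratings=rdf,
        trials=tdf,
        item_partition=partition,
    )


def toy_trial(item, session, L, accepted, success=None, peak=None, idx=0):
    return {
        "session": session,
        "trial_index": idx,
        "item_id": item,
        "target_level": L,
        "accepted": int(accepted),
        "success": (np.nan if success is None else int(success)),
        "peak_force": (np.nan if peak is None else float(peak)),
        "hand": "R",
    }
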