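"""Shared fixtures: synthetic cohorts and one reusable hierarchical fit.

The expensive posterior fit (15 simulated participants, reduced MCMC) is
session-scoped so parameter-recovery, shrinkage and posterior-predictive
tests share a single sampling run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import fairshare as fs
from fairshare.hba import HierarchicalChoiceModel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: Generating population for the recovery cohort: advantage-seeking in
#: first-party (alpha < 0), inequity-averse in third-party, beta positive
#: everywhere, moderately deterministic choices.
RECOVERY_HYPER = {
    "alpha": (np.array([-0.2, -0.2, 2.0, 2.0]), np.full(4, 0.5)),
    "beta": (np.full(4, 2.5), np.full(4, 0.5)),
}


@pytest.fixture(scope="session")
def recovery_cohort() -> fs.ChoiceDataset:
    spec = fs.CohortSpec(
        group="synthetic",
        n_participants=15,
        hyper={k: (v[0].copy(), v[1].copy()) for k, v in RECOVERY_HYPER.items()},
        lam_log_mean=np.log(0.2),
        lam_log_sd=0.4,
        seed=11,
    )
    return fs.simulate_cohort(spec, "M4")


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    with np.errstate(all="ignore"):
        return HierarchicalChoiceModel(recovery_cohort, "M4").fit(
            chains=2, warmup=500, samples=500, seed=3
        )


@pytest.fixture()
def small_dataset() -> fs.ChoiceDataset:
    """A quick 4-participant single-group cohort on a single token budget."""
    spec = fs.CohortSpec(
        group="g",
        n_participants=4,
        hyper={k: (v[0].copy(), v[1].copy()) for k, v in RECOVERY_HYPER.items()},
        token_pool=(12,),
        seed=2,
    )
    return fs.simulate_cohort(spec, "M4")


@pytest.fixture()
def two_group_dataset() -> fs.ChoiceDataset:
    """A small two-group cohort with distinct populations for ANOVA tests."""
    import pandas as pd

    specs = fs.default_cohort_specs(n_children=6, n_adults=6, seed=4)
    parts = [fs.simulate_cohort(s, "M4") for s in specs.values()]
    return fs.ChoiceDataset(
        pd.concat([p.table for p in parts], ignore_index=True),
        pd.concat([p.ground_truth for p in parts], ignore_index=True),
    )
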