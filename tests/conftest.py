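"""Shared fixtures: small seeded synthetic datasets used across test modules."""

import numpy as np
import pandas as pd
import pytest

import milknet as mn

GROUPS = ("M-C-", "M+C-", "M-C+", "M+C+")


@pytest.fixture(scope="session")
def small_config() -> mn.SyntheticConfig:
    """Censored dataset with a correlated block, a differential hub and a
    shifted keyword set — small enough for fast end-to-end runs."""
    return mn.SyntheticConfig(
        n_per_group=25,
        n_proteins=40,
        censor_quantile=0.3,
        block_spec=(mn.BlockSpec(start=0, size=6, rho=0.8, active_groups=("M+C+", "M+C-")),),
        hub_spec=(mn.HubSpec(index=12, neighbors={"M+C+": 6, "M-C-": 4}, rho=0.9),),
        shifted_set=mn.ShiftSpec(
            indices=tuple(range(25, 30)), keyword="Ig", group="M-C+", log10_shift=0.5
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mn.generate_lfq_dataset(small_config)


@pytest.fixture(scope="session")
def imputed_small(small_dataset):
    table, design, annotation, truth = small_dataset
    filtered = mn.filter_by_group_validity(table, design, min_valid=10)
    logged = mn.log10_transform(filtered)
    result = mn.impute_left_censored(logged, sweeps=6, seed=5)
    return result.table, design, annotation, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def brute_force_bh(p_values: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: sorted p_i * n / i, cumulative minimum
    from the largest rank down, clipped at 1, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return np.clip(adjusted, 0.0, 1.0)


def toy_design(n_per_group: int, groups=GROUPS) -> mn.StudyDesign:
    rows, ids = [], []
    for g in groups:
        for i in range(n_per_group):
            ids.append(f"{g}_{i:03d}")
            rows.append(("+" if "M+" in g else "-", "+" if "C+" in g else "-"))
    return mn.StudyDesign(
        pd.DataFrame(
            rows,
            index=pd.Index(ids, name="sample_id"),
            columns=["mother_allergy", "child_allergy"],
        )
    )
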