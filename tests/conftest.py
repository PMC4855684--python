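import numpy as np
import pandas as pd
import pytest

import dyadqap as dq


@pytest.fixture(scope="session")
def study1_schema() -> dq.ItemSchema:
    return dq.ItemSchema.study1()


@pytest.fixture(scope="session")
def study2_schema() -> dq.ItemSchema:
    return dq.ItemSchema.study2()


@pytest.fixture()
def small_strength(study1_schema) -> dq.DyadicMatrix:
    """A 12-actor scored strength matrix, fixed seed."""
    _, S = dq.simulate_strength_network(12, study1_schema, 0.5, seed=101)
    return S


@pytest.fixture(scope="session")
def two_group_study() -> list[dq.GroupData]:
    """A small two-classroom study with the default ground truth."""
    cfg = dq.SimulationConfig(
        groups=(dq.GroupSpec("g0", 12, 0), dq.GroupSpec("g1", 10, 1)),
        schema=dq.ItemSchema.study1(),
        reciprocity_rho=0.5,
        intercepts={"g0": 2.58, "g1": 2.35},
        betas={"strength": 4.82, "reciprocation": -0.17,
               "reciprocation:group": 2.64, "gender_giving": -1.18},
        noise_sd=2.0,
        seed=2024,
        budget=None,
    )
    groups, _ = dq.simulate_study(cfg)
    return groups


def full_dyad_table(ego_alter_pairs, schema, **item_values):
    """Build a long-format response table; item columns default to zero."""
    rows = []
    for ego, alter in ego_alter_pairs:
        rec = {"ego": ego, "alter": alter}
        for it in schema.items:
            rec[it.name] = item_values.get((ego, alter), {}).get(it.name, 0.0)
        rows.append(rec)
    return pd.DataFrame(rows)
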