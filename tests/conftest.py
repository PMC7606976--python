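"""Shared fixtures: small seeded synthetic cohorts and panels.

Expensive bundles are session-scoped; every test that mutates data copies
first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rosindex import scoring as sc
from rosindex import simulate as sim


@pytest.fixture(scope="session")
def iid_cohort():
    """Unstructured cohort (n = 2000) with expression and computed indexes."""
    cfg = sim.SyntheticConfig(seed=5, n_samples=2000)
    rng = cfg.rng()
    latents = sim.simulate_latents(cfg, rng=rng)
    collection = sim.make_collection(cfg)
    expression = sim.simulate_expression(latents, collection, cfg, rng)
    table = sc.compute_indexes(expression, collection)
    return {
        "config": cfg,
        "latents": latents,
        "collection": collection,
        "expression": expression,
        "table": table,
    }


@pytest.fixture(scope="session")
def archetype_cohort():
    """8-archetype cohort (100 samples per cluster) with computed indexes."""
    cfg = sim.SyntheticConfig(seed=11, samples_per_archetype=100)
    bundle = sim.simulate_cohort(cfg, structure="archetypes")
    table = sc.compute_indexes(bundle.expression, bundle.collection)
    return {"config": cfg, "bundle": bundle, "table": table}


@pytest.fixture(scope="session")
def drug_panel():
    """Small GDSC-like panel: 300 cell lines, 60 drugs (40 effective)."""
    cfg = sim.SyntheticConfig(
        seed=23, n_cell_lines=300, n_drugs=60, n_effective_drugs=40
    )
    panel = sim.simulate_drug_panel(cfg)
    table = sc.compute_indexes(panel.expression, panel.collection)
    return {"config": cfg, "panel": panel, "table": table}


@pytest.fixture()
def tiny_expression():
    """A 4-gene x 3-sample matrix with hand-checkable values."""
    return pd.DataFrame(
        {
            "sA": [1.0, 4.0, 2.0, 8.0],
            "sB": [2.0, 8.0, 4.0, 16.0],
            "sC": [1.0, 1.0, 1.0, 1.0],
        },
        index=["G1", "G2", "G3", "G4"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
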