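"""Shared fixtures.

The expensive simulated panels are session-scoped: the acceptance-scale
panel (wild type + 35 mutants, 5,000 genes) and its NDE classification are
computed once and reused by the recovery, separation, and invariant tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import devscreen as ds
from devscreen import nde as N

ACCEPTANCE_SEED = 1
DEV_TIMES = (6.0, 12.0, 18.0)


@pytest.fixture(scope="session")
def small_panel():
    """Fast panel: 300 genes, WT + 4 mutants."""
    params = ds.SimulationParams(n_genes=300, seed=7)
    design = ds.default_design(n_normal=2, n_delayed=1, n_no_development=1)
    return ds.simulate_panel(params, design)


@pytest.fixture(scope="session")
def acceptance_panel():
    """Study-scale panel: 36 strains x 4 times x 2 replicates, 5,000 genes."""
    return ds.simulate_panel(ds.SimulationParams(seed=ACCEPTANCE_SEED))


@pytest.fixture(scope="session")
def acceptance_tables(acceptance_panel):
    """NDE posterior tables for every (category, developmental time)."""
    panel, catalog, truth = acceptance_panel
    dispersions = N.estimate_panel_dispersions(panel)
    tables = {}
    for i, cat in enumerate(("normal", "delayed", "no_development")):
        for j, t in enumerate(DEV_TIMES):
            comp = N.make_category_comparison(panel, cat, t)
            tables[(cat, t)] = N.run_comparison(
                panel, comp, seed=ACCEPTANCE_SEED + 100 * i + j, dispersions=dispersions
            )
    return tables


@pytest.fixture(scope="session")
def acceptance_gene_sets(acceptance_panel, acceptance_tables):
    panel, catalog, truth = acceptance_panel
    return ds.build_gene_sets(acceptance_tables, catalog)


@pytest.fixture(scope="session")
def calibration_classification():
    """Two-condition calibration panel (10% planted DE) and its NDE calls."""
    panel, catalog, truth = ds.calibration_panel(seed=ACCEPTANCE_SEED)
    comp = N.make_category_comparison(panel, "normal", 12.0)
    table = N.run_comparison(panel, comp, seed=ACCEPTANCE_SEED)
    return panel, truth, table


@pytest.fixture(scope="session")
def acceptance_profiles(acceptance_panel):
    panel, catalog, truth = acceptance_panel
    return ds.mean_profiles(ds.compute_rpkm(panel, catalog))
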