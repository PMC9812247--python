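"""Shared fixtures: a small synthetic world reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import braintx as bx


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured synthetic study (~60 genes, 45 regions)."""
    return bx.SyntheticConfig(
        n_genes=60,
        n_regions_cortex=35,
        n_regions_subcortex=10,
        grid_shape=(14, 14, 10),
        planted_gene_fraction=0.15,
        n_categories=12,
        category_size_range=(5, 15),
        n_motifs=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Atlas, expression, activation, truth, annotations for small_config."""
    atlas = bx.generate_atlas(small_config)
    expr = bx.generate_expression(small_config, atlas)
    act, truth = bx.generate_activation(small_config, expr, atlas)
    cats, risk, db = bx.generate_annotations(small_config, truth)
    return {
        "config": small_config,
        "atlas": atlas,
        "expression": expr,
        "activation": act,
        "truth": truth,
        "categories": cats,
        "risk_genes": risk,
        "db": db,
    }


@pytest.fixture(scope="session")
def cortex_table(small_world):
    """Region-wise cortical correlation table for the small world."""
    prof = bx.split_profile(
        small_world["activation"], small_world["atlas"], "cortex"
    )
    expr = small_world["expression"].loc[:, prof.unit_ids]
    return bx.correlate_genes(expr, prof), prof


@pytest.fixture(scope="session")
def table_factory():
    """Factory building a CorrelationTable directly from rho values."""
    return make_table


def make_table(rhos, gene_ids=None, n_units=50):
    """Build a CorrelationTable directly from rho values (test helper)."""
    rhos = np.asarray(rhos, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(len(rhos))]
    df = pd.DataFrame({"gene_id": gene_ids, "rho": rhos})
    df = df.sort_values(
        ["rho", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["p_spatial"] = np.nan
    df["rank"] = np.arange(1, len(df) + 1)
    return bx.CorrelationTable(
        df[["gene_id", "rho", "p_spatial", "rank"]],
        compartment="cortex",
        granularity="region",
        n_units=n_units,
    )
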