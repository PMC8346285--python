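import numpy as np
import pandas as pd
import pytest

import coevonet as cn


@pytest.fixture
def tiny_species():
    return pd.DataFrame({
        "species_id": ["spA", "spB", "spC"],
        "clade": ["Mammalia", "Mammalia", "Fungi"],
        "phylo_distance": [0.1, 0.2, 1.4],
    })


@pytest.fixture
def tiny_genes():
    return pd.DataFrame({
        "gene_id": ["G1", "G2", "G3"],
        "symbol": ["A1", "A2", "A3"],
        "protein_length": [100, 200, 150],
        "chromosome": ["1", "2", "1"],
        "band": ["1p1", "2q1", "1p1"],
    })


# small standard panel for unit tests: scaled-down version of the defaults
SMALL_PARAMS = cn.SimulationParams(
    n_genes=120,
    clade_plan={"Mammalia": (8, 0.05, 0.45), "Fungi": (6, 1.4, 2.0)},
    module_sizes=(6, 6),
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """(thresholded matrix, gene table, truth, species panel) for a small run."""
    raw, genes, truth = cn.simulate_scores(SMALL_PARAMS)
    matrix = cn.apply_threshold(raw, cn.DEFAULT_BIT_MIN)
    panel = cn.simulate_species_panel(SMALL_PARAMS.clade_plan, SMALL_PARAMS.seed)
    return matrix, genes, truth, panel


@pytest.fixture(scope="session")
def small_npp(small_sim):
    matrix, genes, _, _ = small_sim
    return cn.npp(matrix, genes)


def make_bundle(tmp_path, params=None, seed=11):
    """Write a full synthetic input bundle for pipeline tests; returns paths."""
    params = params or cn.SimulationParams(
        n_genes=150,
        clade_plan={"Mammalia": (8, 0.05, 0.45), "Fungi": (7, 1.4, 2.0)},
        module_sizes=(6, 6, 6),
        seed=seed,
    )
    raw, genes, truth = cn.simulate_scores(params)
    panel = cn.simulate_species_panel(params.clade_plan, params.seed)
    drug_df = cn.simulate_drug_table(genes, params.seed, frac_druggable=0.2)
    raw.to_tsv(tmp_path / "raw_matrix.tsv")
    cn.write_table(genes, tmp_path / "genes.tsv")
    cn.write_table(panel, tmp_path / "species.tsv")
    cn.write_table(drug_df, tmp_path / "drugs.tsv")
    query = truth.module_members(0)[0]
    return {
        "raw_matrix": tmp_path / "raw_matrix.tsv",
        "gene_table": tmp_path / "genes.tsv",
        "species_table": tmp_path / "species.tsv",
        "drug_table": tmp_path / "drugs.tsv",
        "query": query,
        "truth": truth,
    }
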