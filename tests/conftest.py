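"""Shared fixtures: small synthetic datasets and on-disk atlas fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from dprule.pipeline import run_synthetic_analysis
from dprule.synthetic_data import GeneratorConfig, generate_dataset


def small_config(**overrides) -> GeneratorConfig:
    """A fast, fully structured generator configuration for unit tests."""
    base = dict(seed=0, n_genes=200, cells_per_coordinate=10)
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline on the small dataset (mediator scan included)."""
    return run_synthetic_analysis(small_config(), mediator_min_cells=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_atlas_files(tmp_path, counts, cell_rows, gene_rows):
    """Write a MatrixMarket + TSV triplet; returns the three paths."""
    import scipy.sparse as sp
    from scipy.io import mmwrite

    matrix = tmp_path / "matrix.mtx"
    mmwrite(str(matrix), sp.coo_matrix(np.asarray(counts)), field="integer")
    cells = tmp_path / "cells.tsv"
    cells.write_text("cell_id\tcell_type\tembryo_time\n" + "".join(
        f"{cid}\t{ct}\t{t}\n" for cid, ct, t in cell_rows
    ))
    genes = tmp_path / "genes.tsv"
    genes.write_text("gene_id\n" + "".join(f"{g}\n" for g in gene_rows))
    return matrix, cells, genes
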