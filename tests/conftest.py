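import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ilripe import ExpressionMatrix, PanelConfig
from ilripe.synthetic_panel import generate_il_design, generate_panel_expression


def make_matrix(values: np.ndarray, gene_ids, sample_ids, genotypes=None,
                stages=None) -> ExpressionMatrix:
    genotypes = genotypes or ["G"] * len(sample_ids)
    stages = stages or ["S"] * len(sample_ids)
    meta = pd.DataFrame(
        {"genotype": genotypes, "stage": stages,
         "replicate": list(range(1, len(sample_ids) + 1))},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids),
        meta,
    )


@pytest.fixture(scope="session")
def small_cfg() -> PanelConfig:
    """A fast, fully-featured panel: 2 chromosomes, 12 ILs, 400 genes."""
    return PanelConfig(
        n_chromosomes=2,
        chromosome_length=10_000_000,
        n_ils=12,
        n_genes=400,
        n_cis_eqtl=25,
        n_trans_pairs=6,
        noise_sd_log2=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    design = generate_il_design(small_cfg)
    matrix, truth = generate_panel_expression(small_cfg, design)
    return design, matrix, truth


@pytest.fixture(scope="session")
def noiseless_panel(small_cfg):
    from dataclasses import replace

    cfg = replace(small_cfg, noise_sd_log2=0.0)
    design = generate_il_design(cfg)
    matrix, truth = generate_panel_expression(cfg, design)
    return design, matrix, truth
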