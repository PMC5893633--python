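import numpy as np
import pandas as pd
import pytest

import coexkit as ck


@pytest.fixture
def toy_compendium() -> ck.Compendium:
    """5 samples from 2 series; 2 samples have an 'adult liver' source."""
    rng = np.random.default_rng(0)
    expr = rng.integers(0, 50, size=(4, 5)).astype(np.int64)
    meta = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4", "S5"],
            "series_id": ["SER1", "SER1", "SER2", "SER2", "SER2"],
            "title": [
                "Pancreatic Islet profiling rep1",
                "islet control",
                "liver tumor",
                "hepatocyte culture",
                "kidney biopsy",
            ],
            "source": ["pancreas", "pancreas", "adult liver", "adult liver", "kidney"],
            "characteristics": ["", "", "", "", ""],
            "organism": ["human"] * 5,
            "instrument": ["HiSeq"] * 5,
            "submission_date": ["2020-01-01"] * 5,
            "institute": ["inst"] * 5,
        }
    )
    return ck.Compendium(
        expression=expr,
        gene_symbols=["Gapdh", "ACTB", "Tp53", "MYC"],
        sample_ids=list(meta["sample_id"]),
        metadata=meta,
        species="human",
    )


@pytest.fixture(scope="session")
def standard_synthetic():
    """The standard planted-structure compendium: 200 genes in 10 modules,
    500 samples, within-module correlation target 0.7."""
    cfg = ck.SyntheticConfig(seed=0)
    comp, truth = ck.generate_compendium(cfg)
    return cfg, comp, truth


@pytest.fixture(scope="session")
def standard_correlation(standard_synthetic):
    """Gene-gene correlation matrix of the standard synthetic compendium,
    built on quantile-normalized log2 counts."""
    _, comp, _ = standard_synthetic
    nm = ck.normalize(comp.expression)
    return ck.gene_correlation_matrix(nm, gene_symbols=comp.gene_symbols)
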