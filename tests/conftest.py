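import numpy as np
import pandas as pd
import pytest

from cytodet import (
    ExpressionMatrix,
    SampleMetadata,
    SimScenario,
    PlantedOutlier,
    default_paper_scenario,
    simulate_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """5 probes x 6 samples with detection P-values and gene symbols."""
    rs = np.random.default_rng(7)
    probes = [f"P{i}" for i in range(5)]
    samples = ["HC1", "HC2", "HC3", "CD1", "CD2", "CD3"]
    values = pd.DataFrame(rs.normal(8, 0.5, (5, 6)), index=probes, columns=samples)
    det = pd.DataFrame(rs.uniform(0, 0.009, (5, 6)), index=probes, columns=samples)
    genes = pd.Series([f"G{i}" for i in range(5)], index=probes)
    return ExpressionMatrix(values=values, detection_p=det, gene_symbols=genes)


@pytest.fixture
def small_metadata(small_matrix):
    t = pd.DataFrame(
        {
            "cohort": ["control"] * 3 + ["case"] * 3,
            "batch": ["B1", "B2", "B1", "B2", "B1", "B2"],
            "stimulation": "unstimulated",
        },
        index=pd.Index(small_matrix.sample_ids, name="sample_id"),
    )
    return SampleMetadata(t)


@pytest.fixture(scope="session")
def small_planted_cohort():
    """A reduced planted-outlier cohort (fast to generate, full structure)."""
    sc = default_paper_scenario(seed=11)
    sc.n_probes = 300
    sc.__post_init__()
    return simulate_expression(sc)
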