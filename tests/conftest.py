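import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_counts():
    """Minimal valid paired design: 1 species, 2 lines, control + 1 ug/mL."""
    from fibroseq.io import CountMatrix

    counts = pd.DataFrame(
        {
            "s1": [100, 200, 1000],
            "s2": [110, 190, 1050],
            "s3": [400, 210, 980],
            "s4": [420, 205, 1020],
        },
        index=pd.Index(["g1", "g2", "Gapdh"], name="feature_id"),
    )
    meta = pd.DataFrame(
        {
            "species": ["Pleucopus"] * 4,
            "cell_line": ["L1", "L2", "L1", "L2"],
            "condition": ["control", "control", "agonist", "agonist"],
            "dose_ug_per_ml": [0.0, 0.0, 1.0, 1.0],
            "passage": [2] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return CountMatrix(counts, meta)


@pytest.fixture
def tiny_annot():
    return pd.DataFrame(
        {"gene_symbol": ["g1", "g2", "Gapdh"], "cds_length_bp": [1000, 2000, 1002]},
        index=pd.Index(["g1", "g2", "Gapdh"], name="feature_id"),
    )
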