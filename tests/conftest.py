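import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tocopls.containers import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(columns: dict[str, list], genes: dict[str, str] | None = None,
                prefix: str = "P") -> GenotypeMatrix:
    """Build a small GenotypeMatrix from explicit dosage vectors."""
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    frame.index = [f"{prefix}{i + 1:03d}" for i in range(len(frame))]
    annotation = None
    if genes is not None:
        annotation = pd.DataFrame(
            {"snp_id": list(columns), "gene": [genes.get(s, "") for s in columns],
             "alleles": "A>G", "alt_freq": 0.3, "region": "intron",
             "reg_score": np.nan}
        ).set_index("snp_id")
    return GenotypeMatrix(frame, annotation)


@pytest.fixture
def rng():
    return np.random.default_rng(20240803)


@pytest.fixture
def hwe_counts_42():
    """Dosage vector with genotype counts (10, 22, 10): consistent with HWE."""
    return np.array([0.0] * 10 + [1.0] * 22 + [2.0] * 10)
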