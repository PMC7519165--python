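import numpy as np
import pandas as pd
import pytest

from omicfuse import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: fewer features, no missingness, fast to analyse."""
    return CohortConfig(
        n_subjects_asd=16, n_subjects_control=10,
        n_features={"mrna": 120, "mirna": 60, "meth": 80, "acetyl": 100},
        n_diff_features={"mrna": 20, "mirna": 10, "meth": 12, "acetyl": 15},
        missingness_pattern={l: 0.0 for l in ("mrna", "mirna", "meth", "acetyl")},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_cohort(CohortConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def paired_metadata(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Two samples per subject with a subject-level binary diagnosis."""
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        diag = "ASD" if i < n_subjects // 2 else "control"
        for reg in ("frontal", "temporal"):
            rows.append({"sample_id": f"s{i:02d}_{reg[0]}", "brain_id": f"b{i:02d}",
                         "diagnosis": diag, "region": reg,
                         "age": float(r.uniform(10, 60)),
                         "sex": "M" if r.random() < 0.5 else "F"})
    return pd.DataFrame(rows).set_index("sample_id")
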