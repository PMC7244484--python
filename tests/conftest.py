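import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from macrotime.datamodel import ExpressionMatrix, validate_annotation
from macrotime.synthetic import SimConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    config = SimConfig(n_genes=300, seed=11)
    return generate_cohort(config)


@pytest.fixture
def tiny_annotation():
    """Hand-written annotation: 2 patients x 2 days, paired control/LPS."""
    rows = []
    for patient, bpd in (("P1", "mild"), ("P2", "severe")):
        for day in (1, 7):
            for treatment, tag in (("control", "c"), ("LPS", "l")):
                rows.append(
                    {
                        "sample_id": f"{patient}d{day}{tag}",
                        "patient_id": patient,
                        "day_of_life": day,
                        "treatment": treatment,
                        "bpd_group": bpd,
                    }
                )
    return validate_annotation(pd.DataFrame(rows))


@pytest.fixture
def tiny_matrix(tiny_annotation):
    """3 genes x 8 samples with simple hand-checkable values."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.uniform(4, 12, size=(3, len(tiny_annotation))).round(2),
        index=["GA", "GB", "GC"],
        columns=list(tiny_annotation["sample_id"]),
    )
    return ExpressionMatrix(data)
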