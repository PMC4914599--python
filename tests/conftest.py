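import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mrsrepro.study_data import StudyTable
from mrsrepro.synthetic import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (9 x 4 x 4 regions x 6 metabolites)."""
    return generate_study(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def synth_table(default_study):
    return default_study["table"]


@pytest.fixture()
def toy_table():
    """Two subjects x two sessions, one cell: values {1, 3} and {2, 4}."""
    rows = [
        ("a", 1, "aMCC", "Glu", 1.0),
        ("a", 2, "aMCC", "Glu", 3.0),
        ("b", 1, "aMCC", "Glu", 2.0),
        ("b", 2, "aMCC", "Glu", 4.0),
    ]
    frame = pd.DataFrame(rows, columns=["subject", "session", "region", "metabolite", "concentration"])
    frame["crlb_percent"] = 5.0
    return StudyTable(frame)


def make_table(values: np.ndarray, region="aMCC", metabolite="Glu") -> StudyTable:
    """StudyTable for one cell from an (n_subjects, n_sessions) array."""
    n, S = values.shape
    rows = [
        {"subject": f"s{i}", "session": j + 1, "region": region,
         "metabolite": metabolite, "concentration": values[i, j], "crlb_percent": 5.0}
        for i in range(n) for j in range(S)
    ]
    return StudyTable(pd.DataFrame(rows))
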