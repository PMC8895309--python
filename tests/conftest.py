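import numpy as np
import pandas as pd
import pytest

from tractpls import Cohort, SimConfig, TractMetricTable, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort() -> Cohort:
    return Cohort(
        data=pd.DataFrame(
            {
                "subject_id": ["s001", "s002", "s003", "s004", "s005",
                               "s006", "s007", "s008", "s009", "s010"],
                "age": [4.5, 5.2, 6.1, 6.9, 7.4, 8.3, 9.0, 10.2, 11.1, 11.8],
                "sex": ["F", "M", "F", "M", "F", "M", "F", "M", "F", "M"],
                "sdfr": [5, 6, 6, 7, 8, 9, 9, 10, 11, 12],
                "ldfr": [5, 5, 7, 7, 8, 8, 10, 10, 11, 13],
                "ldcr": [6, 6, 7, 8, 8, 9, 10, 11, 12, 13],
                "discrimination": [0.9, 1.1, 1.2, 1.4, 1.5, 1.5, 1.7, 1.9, 2.0, 2.2],
            }
        )
    )


@pytest.fixture
def small_metrics(small_cohort, rng) -> TractMetricTable:
    rows = []
    for sid in small_cohort.subject_ids:
        for tract in ("uncinate_fasciculus", "fornix"):
            for hemi in ("left", "right"):
                rows.append(
                    {
                        "subject_id": sid,
                        "tract": tract,
                        "hemisphere": hemi,
                        "fa": float(rng.uniform(0.3, 0.5)),
                        "rd": float(rng.uniform(5e-4, 8e-4)),
                        "ad": float(rng.uniform(1.0e-3, 1.3e-3)),
                    }
                )
    return TractMetricTable(data=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default synthetic cohort (n=37)."""
    return generate_cohort(SimConfig(seed=11))
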