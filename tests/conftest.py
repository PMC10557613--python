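import numpy as np
import pandas as pd
import pytest

from hemimorph import CohortConfig, generate_cohort

SMALL_REGIONS = ("precentral", "postcentral", "insula", "cuneus")


@pytest.fixture(scope="session")
def small_cohort():
    """A study-sized null cohort restricted to four cortical regions."""
    cfg = CohortConfig(seed=11, cortical_regions=SMALL_REGIONS)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_tidy(records) -> pd.DataFrame:
    return pd.DataFrame(
        records, columns=["subject_id", "hemisphere", "region", "measure", "value"]
    )
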