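import numpy as np
import pytest

import lifespanvol as lv


@pytest.fixture(scope="session")
def small_cohort():
    """~1,100-row cohort with the full 88-site structure (fast tests)."""
    cfg = lv.default_sim_config(scale=0.06, seed=42)
    return lv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    """QC'd and ICV-adjusted version of the small cohort."""
    table, _ = lv.filter_complete(small_cohort)
    table, _ = lv.mahalanobis_exclude(table)
    table, _ = lv.adjust_icv(table)
    return table


@pytest.fixture(scope="session")
def harmonized_cohort(clean_cohort):
    table, _ = lv.harmonize_table(clean_cohort)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
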