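import numpy as np
import pytest

from rigc.scoring import score_cohort
from rigc.cohort import sample_cohort
from rigc.tables import builtin_table, table_for_task
from rigc.tasks import TASKS


@pytest.fixture(scope="session")
def bin1d():
    return builtin_table("bin1d")


@pytest.fixture(scope="session")
def bin2d():
    return builtin_table("bin2d")


@pytest.fixture(scope="session")
def task_tables():
    return {tid: table_for_task(tid) for tid in TASKS}


@pytest.fixture(scope="session")
def scored_cohort(task_tables):
    """A mid-size scored cohort reused by analysis tests (seed fixed)."""
    cohort = sample_cohort(600, seed=11)
    return score_cohort(cohort.table, task_tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
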