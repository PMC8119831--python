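import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import wmnet


@pytest.fixture(scope="session")
def parcellation():
    return wmnet.default_parcellation()


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort (40 subjects) for pipeline-level tests."""
    cfg = wmnet.default_config(seed=7)
    return dataclasses.replace(
        cfg, group_sizes={"control": 12, "pure_adci": 8, "pure_lbci": 8, "mixed": 12}
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    records, raws = wmnet.generate_cohort(small_config)
    return wmnet.records_to_frame(records), raws


def make_raw(counts, fa, volumes, icv=1.4e6, subject_id="s1"):
    return wmnet.SubjectRaw(
        counts=np.asarray(counts, dtype=np.int64),
        mean_fa=np.asarray(fa, float),
        volumes=np.asarray(volumes, float),
        icv=icv,
        subject_id=subject_id,
    )
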