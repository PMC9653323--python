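import numpy as np
import pandas as pd
import pytest

from hublong.atlas import parcellation_from_frame
from hublong.synthetic_cohort import default_config


@pytest.fixture
def toy_parcellation():
    """6-region atlas: 2 DMN, 1 FTPN, 3 no-hub regions."""
    df = pd.DataFrame(
        {
            "region_id": [1, 2, 3, 4, 5, 6],
            "region_name": ["d1", "d2", "f1", "v1", "v2", "v3"],
            "network": ["Default", "Default", "FrontoParietal", "Visual", "Visual", "Visual"],
            "n_voxels": [100, 150, 120, 200, 180, 160],
        }
    )
    return parcellation_from_frame(df)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def small_sim_config(**overrides):
    """A desk-scale cohort (8 subjects, 24 regions, short scans)."""
    base = dict(
        n_subjects=8,
        n_lgg=4,
        n_left=4,
        n_left_lgg=2,
        n_regions=24,
        network_sizes=(("Default", 6), ("FrontoParietal", 5), ("Visual", 7), ("SMhand", 6)),
        n_timepoints=80,
        n_males_lgg=3,
        n_males_hgg=3,
        n_idh_lgg=1,
        n_idh_hgg=1,
        n_mgmt_lgg=0,
        n_mgmt_hgg=2,
        who_grades_lgg=(1, 2, 2, 2),
        who_grades_hgg=(3, 3, 4, 4),
    )
    base.update(overrides)
    return default_config(**base)


@pytest.fixture
def small_config():
    return small_sim_config()
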