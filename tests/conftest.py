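import pandas as pd
import pytest

from aclpv.jars import JarsEntry, JarsRegistry
from aclpv.smq import example_dictionary
from aclpv.tables import CaseProfile, DrugEntry


@pytest.fixture(scope="session")
def registry():
    """Small risk registry: one drug per score plus a second score-3."""
    return JarsRegistry(
        [
            JarsEntry("atropine", 3),
            JarsEntry("biperiden", 3),
            JarsEntry("amitriptyline", 2),
            JarsEntry("loratadine", 1),
        ]
    )


@pytest.fixture(scope="session")
def smq():
    return example_dictionary()


def make_profile(case_id="C1", sex="female", age_band="60s", drugs=(),
                 pts=(), indications=()):
    """Build a CaseProfile; drugs are (name, involvement, route, score)."""
    return CaseProfile(
        case_id=case_id,
        sex=sex,
        age_band=age_band,
        drugs=tuple(DrugEntry(*d) for d in drugs),
        pts=frozenset(pts),
        indications=frozenset(indications),
    )


@pytest.fixture
def profile_factory():
    return make_profile


def frames_from_rows(demo_rows, drug_rows, reac_rows=(), ind_rows=()):
    """Build the four raw frames from row dicts (missing tables empty)."""
    demo = pd.DataFrame(demo_rows, columns=["case_id", "sex", "age_band"])
    drug = pd.DataFrame(
        drug_rows, columns=["case_id", "drug_name", "involvement", "route"]
    )
    reac = pd.DataFrame(reac_rows, columns=["case_id", "preferred_term"])
    ind = pd.DataFrame(ind_rows, columns=["case_id", "indication"])
    return demo, drug, reac, ind
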