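import numpy as np
import pandas as pd
import pytest

from readmitwx.cdm import CdmBundle
from readmitwx.simulate import SimConfig, generate_study


def make_bundle(
    persons=None, visits=None, conditions=None, drugs=None, locations=None, site_id="A"
) -> CdmBundle:
    """Hand-built bundle helper with sane defaults for omitted tables."""
    if locations is None:
        locations = pd.DataFrame(
            {"location_id": ["L1"], "postal_code": ["03080"], "region_id": ["R1"]}
        )
    if persons is None:
        persons = pd.DataFrame(
            {"person_id": ["P1"], "gender": ["female"], "year_of_birth": [1940],
             "location_id": ["L1"]}
        )
    if visits is None:
        visits = pd.DataFrame(
            {
                "visit_id": ["V1"],
                "person_id": ["P1"],
                "visit_kind": ["inpatient"],
                "admit_date": [pd.Timestamp("2017-05-01")],
                "discharge_date": [pd.Timestamp("2017-05-04")],
                "discharged_alive": [True],
                "site_id": [site_id],
            }
        )
    if conditions is None:
        conditions = pd.DataFrame(
            {"person_id": ["P1"], "icd10_code": ["I50"],
             "start_date": [pd.Timestamp("2017-05-01")]}
        )
    if drugs is None:
        drugs = pd.DataFrame(
            {
                "person_id": ["P1"],
                "ingredient_code": ["C09AA05"],
                "start_date": [pd.Timestamp("2017-02-01")],
                "end_date": [pd.Timestamp("2017-03-01")],
            }
        )
    for df, cols in ((visits, ["admit_date", "discharge_date"]),
                     (conditions, ["start_date"]), (drugs, ["start_date", "end_date"])):
        for c in cols:
            df[c] = pd.to_datetime(df[c])
    return CdmBundle(persons, visits, conditions, drugs, locations, site_id=site_id)


@pytest.fixture
def tiny_bundle() -> CdmBundle:
    return make_bundle()


@pytest.fixture(scope="session")
def small_study():
    """One modest two-site study shared across read-only tests."""
    return generate_study(SimConfig(seed=42, n_persons_per_site=150))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
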