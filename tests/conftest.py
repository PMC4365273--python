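import numpy as np
import pytest

from bevtmdd.dataset import (
    Analyte,
    DoseEvent,
    Observation,
    PatientCovariates,
    Sex,
    StudyDataset,
    Subject,
)
from bevtmdd.estimation import ObjectiveSettings
from bevtmdd.reference import TMDD_TYPICAL, pk_reference_spec, tmdd_reference_spec


@pytest.fixture(scope="session")
def tmdd_typical():
    return TMDD_TYPICAL


@pytest.fixture(scope="session")
def pk_spec():
    return pk_reference_spec()


@pytest.fixture(scope="session")
def tmdd_spec():
    return tmdd_reference_spec()


@pytest.fixture(scope="session")
def fast_settings():
    """Estimation settings with looser outer tolerance for small tests."""
    return ObjectiveSettings(outer_tol=1e-5)


@pytest.fixture
def reference_covariates():
    return PatientCovariates(weight=70.0, age=60.0, sex=Sex.M)


def make_subject(
    sid="S01",
    weight=70.0,
    doses=((0.0, 350.0, 90.0 / 1440.0),),
    observations=(),
):
    return Subject(
        id=sid,
        covariates=PatientCovariates(weight=weight, age=60.0, sex=Sex.M),
        doses=tuple(DoseEvent(*d) for d in doses),
        observations=tuple(observations),
    )


@pytest.fixture
def two_subject_dataset():
    obs1 = (
        Observation(0.0625, Analyte.TOTAL_DRUG, 95.0),
        Observation(7.0, Analyte.FREE_TARGET, 80.0),
    )
    obs2 = (
        Observation(0.0625, Analyte.TOTAL_DRUG, 120.0),
        Observation(13.9, Analyte.TOTAL_DRUG, 60.0),
    )
    return StudyDataset((
        make_subject("A", 65.0, observations=obs1),
        make_subject("B", 82.0, observations=obs2),
    ))
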