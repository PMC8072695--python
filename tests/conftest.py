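import numpy as np
import pytest

from nutrigap.adequacy import default_reference_table
from nutrigap.cohort import ClinicalPanel, SubjectRecord
from nutrigap.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def reference_table():
    return default_reference_table()


def make_subject(
    sid="S1", sex="female", age=45.0, weight=70.0, height=165.0,
    centre="bologna", clinical=None, **intakes,
):
    """A valid subject with every intake at its recommended value unless
    overridden (so the default gap vector is exactly zero)."""
    base = dict(
        energy=8.45 if sex == "female" else 10.45,
        carb=52.5, sugars=10.0, fat=27.5, sfa=10.0, ufa=17.5, pufa=8.5,
        protein=0.745 * weight, fibre=25.0,
        alcohol=1.0 if sex == "female" else 2.0,
    )
    base.update(intakes)
    return SubjectRecord(
        id=sid, sex=sex, age=age, weight=weight, height=height,
        centre=centre, clinical=clinical, **base,
    )


def make_panel(**overrides):
    base = dict(bmi=28.0, wc=95.0, tg=140.0, total_chol=190.0, hdl_c=55.0,
                ldl_c=120.0, glucose=92.0, insulin=10.0, hba1c=5.4,
                sbp=125.0, dbp=80.0)
    base.update(overrides)
    return ClinicalPanel(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort at reduced size (seeded)."""
    cfg = GeneratorConfig(n_female=40, n_male=40, seed=11,
                          misreporter_fraction=0.2)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Full default study conditions: 94 F + 121 M complete subjects."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
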