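import numpy as np
import pytest

from famclock.pedigree import IndividualRecord, RelativePair, RelationshipType


def make_person(iid="p1", fam="f1", study="s1", sex="female", age=30.0, dnam=32.0, **kw):
    return IndividualRecord(
        individual_id=iid, family_id=fam, study_id=study, sex=sex,
        chronological_age=age, dnam_age=dnam, **kw,
    )


def make_pair(rel, age_a, age_b, separation=None, offspring=None, fam="f1"):
    a = make_person("a", fam=fam, age=age_a)
    b = make_person("b", fam=fam, age=age_b)
    return RelativePair(
        a=a, b=b, relationship=RelationshipType(rel),
        separation_time=separation, offspring=offspring,
    )


def bivariate_pairs(rng, n, rho, var=1.0):
    """Draw n mean-zero pairs with correlation rho and equal variance."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    sd = np.sqrt(var)
    return sd * z1, sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
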