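import numpy as np
import pytest
from hypothesis import settings

from famvar.pedigree import build_pedigree, kinship_matrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def _rec(iid, fam="F1", father=None, mother=None, sex="1", household=None,
         proband=0):
    return dict(id=iid, family_id=fam, father_id=father, mother_id=mother,
                sex=sex, household_id=household, proband=proband)


@pytest.fixture
def trio():
    return build_pedigree([
        _rec("dad", sex="1"),
        _rec("mom", sex="2"),
        _rec("kid", father="dad", mother="mom", sex="1"),
    ])


@pytest.fixture
def nuclear_family():
    """Founder couple with two children."""
    return build_pedigree([
        _rec("dad", sex="1", household="h1"),
        _rec("mom", sex="2", household="h1"),
        _rec("kid1", father="dad", mother="mom", sex="1", household="h1"),
        _rec("kid2", father="dad", mother="mom", sex="2", household="h1"),
    ])


@pytest.fixture
def double_first_cousins():
    """Two brothers married to two sisters, one child each."""
    rows = [
        _rec("gpa1", sex="1"), _rec("gma1", sex="2"),
        _rec("gpa2", sex="1"), _rec("gma2", sex="2"),
        _rec("bro1", father="gpa1", mother="gma1", sex="1"),
        _rec("bro2", father="gpa1", mother="gma1", sex="1"),
        _rec("sis1", father="gpa2", mother="gma2", sex="2"),
        _rec("sis2", father="gpa2", mother="gma2", sex="2"),
        _rec("cuz1", father="bro1", mother="sis1", sex="1"),
        _rec("cuz2", father="bro2", mother="sis2", sex="2"),
    ]
    return build_pedigree(rows)


@pytest.fixture
def half_sib_triad():
    """Shared father, two mothers."""
    return build_pedigree([
        _rec("dad", sex="1"),
        _rec("mom1", sex="2"),
        _rec("mom2", sex="2"),
        _rec("kidA", father="dad", mother="mom1", sex="1"),
        _rec("kidB", father="dad", mother="mom2", sex="2"),
    ])


@pytest.fixture
def four_generations():
    """Twelve members over four generations."""
    rows = [
        _rec("g1a", sex="1"), _rec("g1b", sex="2"),
        _rec("g2a", father="g1a", mother="g1b", sex="1"),
        _rec("g2b", sex="2"),
        _rec("g2c", father="g1a", mother="g1b", sex="2"),
        _rec("g3a", father="g2a", mother="g2b", sex="1"),
        _rec("g3b", sex="2"),
        _rec("g3c", father="g2a", mother="g2b", sex="2"),
        _rec("g4a", father="g3a", mother="g3b", sex="1"),
        _rec("g4b", father="g3a", mother="g3b", sex="2"),
        _rec("g4c", father="g3a", mother="g3b", sex="1"),
        _rec("g4d", father="g3a", mother="g3b", sex="2"),
    ]
    rng = np.random.default_rng(4)
    rows = [rows[i] for i in rng.permutation(len(rows))]  # scrambled input order
    return build_pedigree(rows)


@pytest.fixture(scope="session")
def small_study():
    """A small generated study shared across slow-ish tests."""
    from famvar.simulate import generate_pedigree

    ped = generate_pedigree(n_families=8, seed=42)
    return ped, kinship_matrix(ped)
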