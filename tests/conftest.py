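import pytest

from pgxcohort.panel import GenotypeCall, GenotypeClass, PatientGenotype, load_default_panel
from pgxcohort.phenotype import load_default_translation_table


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def translation_table():
    return load_default_translation_table()


def make_genotype(panel, overrides=None, patient_id="P1", cn=2, fill=GenotypeClass.REF_HOMOZYGOUS):
    """Patient genotype with every panel site set to `fill`, selected
    sites overridden."""
    calls = {r: GenotypeCall(r, fill) for r in panel.rsids}
    for rsid, cls in (overrides or {}).items():
        calls[rsid] = GenotypeCall(rsid, cls)
    return PatientGenotype(patient_id=patient_id, calls=calls, cyp2d6_copy_number=cn)


@pytest.fixture
def all_ref_genotype(panel):
    return make_genotype(panel)
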