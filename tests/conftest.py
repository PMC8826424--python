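import pytest

from evallr import (
    CoARecord,
    EvidenceCondition,
    Finding,
    ReferenceSummary,
    VerbalScale,
)

DIASTASE_CSV = (
    "parameter,mode,value,units,lod,loq,mu,condition_direction,"
    "condition_threshold,ref_n,ref_k,ref_population,ref_source\n"
    "diastase activity,quantitative,4.4,DN,,,,le,8,20000,1600,bee-keeper,"
    "Bogdanov et al. 1999\n"
)


@pytest.fixture(scope="session")
def enfsi():
    return VerbalScale.builtin("ENFSI")


@pytest.fixture(scope="session")
def literature():
    return VerbalScale.builtin("literature")


@pytest.fixture
def diastase_record():
    """The worked low-diastase finding: DN 4.4 against the bee-keeper survey."""
    finding = Finding(
        parameter="diastase activity",
        mode="quantitative",
        condition=EvidenceCondition(direction="le", threshold=8.0, units="DN"),
        value=4.4,
        units="DN",
        mu=0.05,
        loq=1.0,
    )
    reference = ReferenceSummary(n=20000, k=1600, population="bee-keeper", source="Bogdanov et al. 1999")
    return CoARecord(finding=finding, reference=reference)


@pytest.fixture
def diastase_csv(tmp_path):
    path = tmp_path / "coa.csv"
    path.write_text(DIASTASE_CSV)
    return path
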