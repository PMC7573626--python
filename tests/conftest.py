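import pytest

from cnaml.schema import (
    ClinicalCovariates,
    Cohort,
    EventHistory,
    MutationCall,
    PatientRecord,
)
from cnaml.simulate import GeneratorConfig, generate_cohort


def make_patient(
    pid="P1",
    mutations=(),
    age=45.0,
    sex="female",
    wcc=12.0,
    cr1_time=1.0,
    relapse_time=None,
    hsct_time=None,
    death_time=None,
    death_context="none",
    last_followup=60.0,
    induction_given=True,
    cr1_via_salvage=False,
):
    """Hand-built patient record for targeted scenarios."""
    if death_time is not None:
        last_followup = death_time
    return PatientRecord(
        patient_id=pid,
        covariates=ClinicalCovariates(age=age, sex=sex, wcc=wcc,
                                      dauno_dose="60", regimen="7+3"),
        mutations=tuple(
            MutationCall(pid, gene, subtype, vaf) for gene, subtype, vaf in mutations
        ),
        history=EventHistory(
            induction_given=induction_given,
            cr1_time=cr1_time,
            cr1_via_salvage=cr1_via_salvage,
            relapse_time=relapse_time,
            hsct_time=hsct_time,
            death_time=death_time,
            death_context=death_context,
            last_followup=last_followup,
        ),
    )


@pytest.fixture
def two_patient_cohort():
    """Two patients, three mutations — the minimal round-trip fixture."""
    p1 = make_patient("A1", [("NPM1", "typeA", 0.45), ("FLT3", "ITD", 0.12)],
                      relapse_time=13.0, death_time=20.0,
                      death_context="death_in_relapse")
    p2 = make_patient("A2", [("DNMT3A", "R882", 0.47)], cr1_time=1.5,
                      hsct_time=5.0, last_followup=48.0)
    return Cohort((p1, p2), provenance="imported")


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=7))
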