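import pytest

from ravarkit import (
    AssociationRecord,
    Coverage,
    PopulationLabel,
    RiskMarker,
    StudyDesign,
    load_table1_fixture,
    load_table1_loci,
)


@pytest.fixture(scope="session")
def table1_records():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_loci():
    return load_table1_loci()


def make_record(
    variant="rsX",
    study="S1",
    population=PopulationLabel.EUROPEAN,
    p_value=1e-9,
    odds_ratio=1.2,
    risk_allele="A",
    n_cases=1000,
    n_controls=1000,
    coverage=Coverage.GENOME_WIDE,
    design=StudyDesign.GWAS,
):
    return AssociationRecord(
        study_id=study,
        variant_id=variant,
        risk_allele=risk_allele,
        p_value=p_value,
        odds_ratio=odds_ratio,
        n_cases=n_cases,
        n_controls=n_controls,
        population=population,
        coverage=coverage,
        design=design,
    )


def make_marker(variant="rsX", r=1.5, p=0.3, p_value=1e-9, locus="L1", allele="A"):
    return RiskMarker(
        variant_id=variant,
        risk_allele=allele,
        r=r,
        p=p,
        p_value=p_value,
        locus_id=locus,
        population=PopulationLabel.EUROPEAN,
    )


@pytest.fixture
def five_marker_panel():
    return [
        make_marker("rs1", r=1.3, p=0.25, locus="L1"),
        make_marker("rs2", r=2.0, p=0.5, locus="L2"),
        make_marker("rs3", r=0.8, p=0.6, locus="L3"),
        make_marker("rs4", r=1.1, p=0.1, locus="L4"),
        make_marker("rs5", r=1.8, p=0.75, locus="L5"),
    ]
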