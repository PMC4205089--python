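from datetime import date

import pytest

from ctgaudit import FuzzyDate, DatePrecision, OverallStatus, Gender
from ctgaudit.registry_io import ContactInfo, TrialLocation, TrialRecord, Corpus
from ctgaudit.synthetic_data import default_corpus_spec, generate_corpus


@pytest.fixture(scope="session")
def default_corpus():
    """The four-domain synthetic corpus with published-table structure."""
    return generate_corpus(default_corpus_spec(seed=11))


@pytest.fixture
def sample_record():
    """A fully populated hand-built record."""
    return TrialRecord(
        nct_id="NCT01234567",
        domain_tag="gleevec",
        overall_status=OverallStatus.RECRUITING,
        first_received=FuzzyDate(2010, 3, 5, DatePrecision.DAY),
        last_update=FuzzyDate(2013, 5, 1, DatePrecision.DAY),
        completion_date=FuzzyDate(2012, 6, None, DatePrecision.MONTH),
        eligibility_text=(
            "Inclusion Criteria:\n\n"
            "  -  Histologically confirmed chronic myeloid leukemia\n"
            "  -  ECOG performance status 0-2\n\n"
            "Exclusion Criteria:\n\n"
            "  -  Pregnancy or breastfeeding"
        ),
        minimum_age="18 Years",
        maximum_age="75 Years",
        gender=Gender.ALL,
        healthy_volunteers=False,
        locations=(
            TrialLocation(
                facility="Boston Medical Center 1",
                city="Boston",
                country="United States",
                latitude=42.36,
                longitude=-71.06,
                contact=ContactInfo("Rivera, A.", phone="+1-617-555-0001"),
            ),
        ),
        overall_contact=ContactInfo("Chen, B.", email="overall@example.org"),
        backup_contact=None,
    )


@pytest.fixture
def mini_corpus(sample_record):
    return Corpus(
        records=[sample_record],
        reference_dates={"gleevec": date(2013, 6, 6)},
    )
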