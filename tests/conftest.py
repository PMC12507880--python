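import pytest

from fibrovig.cohort import DrugDictionary, TermLists, build_cohort, apply_exclusions
from fibrovig.io import dedup_by_key_variables, retain_latest_version
from fibrovig.simulate import ScenarioConfig, DrugSpec, default_scenario, generate_reports


@pytest.fixture(scope="session")
def dictionary():
    return DrugDictionary.from_csv()


@pytest.fixture(scope="session")
def terms():
    return TermLists.default()


@pytest.fixture(scope="session")
def small_scenario():
    """Modest default-style scenario with duplicates and missingness."""
    return default_scenario(n_reports=8_000, seed=11)


@pytest.fixture(scope="session")
def small_reports(small_scenario, dictionary):
    reports, truth = generate_reports(small_scenario, dictionary)
    return reports, truth


@pytest.fixture(scope="session")
def clean_reports(small_reports, terms):
    reports, _ = small_reports
    reports = dedup_by_key_variables(retain_latest_version(reports))
    return apply_exclusions(reports, terms)


@pytest.fixture(scope="session")
def full_cohort(clean_reports, dictionary, terms):
    return build_cohort(clean_reports, "full_database_wide", dictionary, terms)


@pytest.fixture(scope="session")
def restricted_cohort(clean_reports, dictionary, terms):
    return build_cohort(clean_reports, "active_comparator_restricted", dictionary, terms)
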