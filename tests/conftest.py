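import pytest

import csurv


@pytest.fixture(scope="session")
def schema():
    return csurv.load_packaged_schema()


@pytest.fixture(scope="session")
def rulesets(schema):
    return csurv.load_packaged_mappings(schema)


@pytest.fixture(scope="session")
def presence_fixture():
    return csurv.load_presence_fixture()


@pytest.fixture(scope="session")
def raw_tables(schema):
    """Small synthetic cohorts shared across the suite (fixed seed)."""
    return csurv.generate_all(seed=11, n=120, schema=schema)


@pytest.fixture(scope="session")
def harmonised(schema, rulesets, raw_tables):
    """Harmonised tables + provenance for all four synthetic cohorts."""
    out = {}
    for cohort, raw in raw_tables.items():
        out[cohort] = csurv.harmonise_cohort(raw, schema, rulesets[cohort])
    return out
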