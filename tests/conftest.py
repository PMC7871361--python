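import pytest

from ca_ascertain import codes, cohort_synth


@pytest.fixture(scope="session")
def subgroup_table():
    return codes.default_subgroup_table()


@pytest.fixture(scope="session")
def code_map():
    return codes.default_code_map()


@pytest.fixture(scope="session")
def strategy():
    return cohort_synth.default_search_strategy()


@pytest.fixture(scope="session")
def variant_dictionary():
    return cohort_synth.default_variant_dictionary()


@pytest.fixture(scope="session")
def default_run():
    """One default-condition synthetic run shared by read-only tests."""
    from ca_ascertain import pipeline

    cfg = cohort_synth.SynthConfig(seed=20_260_925, n_fetuses=8000)
    registry, truth = cohort_synth.generate_cohort(cfg)
    tables = cohort_synth.emit_sources(registry, truth, cfg)
    result = pipeline.run_pipeline(registry, tables)
    return cfg, registry, truth, tables, result
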