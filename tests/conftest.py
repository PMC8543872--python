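import pytest

import bowtieflux as bf


@pytest.fixture(scope="session")
def specs():
    """All fixture cases, built once."""
    return {case: bf.make_fixture(case) for case in bf.CASES}


@pytest.fixture(scope="session")
def prepared(specs):
    """Preprocessed models per case (fixture models stay untouched)."""
    return {case: bf.preprocess(spec.model) for case, spec in specs.items()}


@pytest.fixture(scope="session")
def sweeps(specs, prepared):
    """Seed connectivity tables per case (the expensive LP sweeps)."""
    return {
        case: bf.sweep_connectivity(prepared[case], spec.seed)
        for case, spec in specs.items()
    }


@pytest.fixture(scope="session")
def fba_partitions(sweeps):
    return {case: bf.classify_bowtie(table) for case, table in sweeps.items()}


@pytest.fixture(scope="session")
def gba_partitions(specs):
    return {
        case: bf.bowtie_from_graph(bf.build_graph(spec.model))
        for case, spec in specs.items()
    }
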