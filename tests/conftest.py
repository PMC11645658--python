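import pytest

import milkpk as mk


@pytest.fixture(scope="session")
def examples():
    """Bundled literature-constant drugs, keyed by name."""
    return {d.name: d for d in mk.example_drugs()}


@pytest.fixture(scope="session")
def reg():
    return mk.registry()


@pytest.fixture()
def acid():
    return mk.DrugRecord("testacid", "acid", pka_values=[7.12], logp=1.0, fu_p=0.3)


@pytest.fixture()
def base():
    return mk.DrugRecord("testbase", "base", pka_values=[9.40], logp=2.9, fu_p=0.5)


@pytest.fixture()
def neutral():
    return mk.DrugRecord("testneutral", "neutral", logp=2.0, fu_p=0.4, psa=60.0)
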