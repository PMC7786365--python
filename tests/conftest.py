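import pytest

from npc_cea import evaluate_model, reference_fixture


@pytest.fixture()
def fixture():
    """Fresh copy of the two-arm reference model."""
    return reference_fixture()


@pytest.fixture(scope="session")
def base_case():
    """Base-case evaluation shared across tests (deterministic)."""
    model = reference_fixture()
    gp, tpf, comp = evaluate_model(model)
    return model, gp, tpf, comp
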