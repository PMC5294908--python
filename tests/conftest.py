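import pytest

from dxlattice.fixtures import build_example_fixture
from dxlattice.pipeline import bind_terminologies, build_model
from dxlattice.terminology import System, TerminologyCode, derive_icd10_behavior


@pytest.fixture(scope="session")
def bundle():
    """The worked-example fixture bundle (oracle-verified at build time)."""
    return build_example_fixture()


@pytest.fixture(scope="session")
def model(bundle):
    return build_model(bundle.onto)


@pytest.fixture(scope="session")
def bindings(bundle, model):
    icd10 = [
        TerminologyCode(code, System.ICD10, label, derive_icd10_behavior(code))
        for code, label in bundle.icd10
    ]
    return bind_terminologies(
        model,
        bundle.crosswalk_table(),
        icd10,
        [code for code, _ in bundle.icdo3_topo],
        [code for code, _ in bundle.icdo3_morph],
    )
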