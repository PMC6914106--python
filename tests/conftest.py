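import pytest

import dtxecon as dx

DISEASES = ("t2dm", "htn")


@pytest.fixture(params=DISEASES)
def disease(request):
    return request.param


@pytest.fixture
def params(disease):
    """Fresh, mutable base-case parameter set."""
    return dx.default_parameters(disease)


@pytest.fixture
def t2dm():
    return dx.default_parameters("t2dm")


@pytest.fixture
def htn():
    return dx.default_parameters("htn")


@pytest.fixture(scope="session")
def base_runs():
    """Read-only base-case model runs for both diseases."""
    return {d: dx.run_model(dx.default_parameters(d)) for d in DISEASES}


def make_null_effect(disease: str) -> dx.ModelParameters:
    """A parameter set in which the DTx does nothing and TAU is frozen:
    identity transitions in both arms and no category-2 deprescribing, so the
    two arms are exactly equivalent."""
    p = dx.default_parameters(disease)
    p.tau_spill_rule = "stay"
    p.cat2_unmedicated_fraction = 0.0
    p.synthesis.responder_fraction_y1 = 0.0
    p.synthesis.mean_change_y1 = 0.0
    p.synthesis.y2_improvement = 0.0
    p.synthesis.y3_improvement = 0.0
    p.transition_tables = None
    return p


@pytest.fixture
def null_effect(disease):
    return make_null_effect(disease)
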