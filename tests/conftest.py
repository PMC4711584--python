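import pytest

from sigiscan import load_seed_set, sigI3_model, sigI6_model
from sigiscan.motif_model import anchor_align


@pytest.fixture(scope="session")
def m6():
    """Calibrated sigma-I6 model trained on the ten validated promoters."""
    return sigI6_model()


@pytest.fixture(scope="session")
def m3():
    """Calibrated sigma-I3 model trained on the four validated promoters."""
    return sigI3_model()


@pytest.fixture(scope="session")
def table1():
    return load_seed_set("sigI_table1")


@pytest.fixture(scope="session")
def table2():
    return load_seed_set("ct_candidates_table2")


@pytest.fixture(scope="session")
def v6_aligned():
    return anchor_align(load_seed_set("sigI6_validated"))


@pytest.fixture(scope="session")
def m6_planter(m6):
    """Copy of the sigma-I6 model with every PWM column forced to its modal
    base, so sampled sites are the exact consensus (deterministic plants)."""
    import copy

    model = copy.deepcopy(m6)
    for pwm in (model.pwm_minus35, model.pwm_minus10, model.pwm_downstream):
        for col in pwm:
            best = max(col, key=col.get)
            for b in "ACGT":
                col[b] = 1.0 if b == best else 0.0
    return model
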