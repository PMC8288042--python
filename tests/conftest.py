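import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import apcontrib as ap

hyp_settings.register_profile("det", derandomize=True, deadline=None)
hyp_settings.load_profile("det")
from apcontrib.ratmodel import build_rat_model, rat_criteria, rat_protocol

# tight tolerances for the analytic fixtures: the oracle checks are at the
# 1e-6..1e-9 level and must not be solver-limited
TOY_OPTS = ap.SolverOptions(rtol=1e-12, atol=1e-14, output_dt=0.001)

TOY = dict(tau=2.0, x_inf=0.9, x0=0.0, theta=0.9 * (1.0 - np.exp(-1.0)))


@pytest.fixture(scope="session")
def toy_model():
    return ap.toy_threshold_model(**TOY, with_decoupled_gate=True)


@pytest.fixture(scope="session")
def toy_event():
    return ap.toy_event_time(TOY["tau"], TOY["x_inf"], TOY["x0"], TOY["theta"])


@pytest.fixture(scope="session")
def toy_traj(toy_model, toy_event):
    proto = ap.StimulusProtocol(amplitude=0.0, total_time=5.0 * toy_event)
    return ap.simulate(toy_model, proto, TOY_OPTS)


@pytest.fixture(scope="session")
def squid_model():
    return ap.squid_axon_model()


@pytest.fixture(scope="session")
def rat_model():
    return build_rat_model()


@pytest.fixture(scope="session")
def rat_traj(rat_model):
    opts = ap.SolverOptions(rtol=1e-8, atol=1e-10, output_dt=0.001)
    return ap.simulate(rat_model, rat_protocol(total_time=160.0), opts)


@pytest.fixture(scope="session")
def rat_phases(rat_traj):
    return ap.segment_phases(rat_traj, rat_criteria())
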