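import numpy as np
import pytest

from cav33sim import gating, neuron


@pytest.fixture(scope="session")
def shipped():
    """Shipped wild-type + variant gating parameter sets."""
    return gating.load_shipped_params()


@pytest.fixture(scope="session")
def wt(shipped):
    return shipped["WT"]


@pytest.fixture(scope="session")
def base_config():
    return neuron.load_base_config()


@pytest.fixture
def simple_params():
    """Small hand-checkable parameter set used by closed-form tests."""
    return gating.GatingParams(
        name="simple",
        v_half_act=-45.0, k_act=5.0,
        v_half_inact=-72.0, k_inact=4.0,
        tau_act_table=[(-60.0, 20.0), (-40.0, 10.0), (0.0, 5.0)],
        tau_inact_table=[(-100.0, 300.0), (-60.0, 200.0), (0.0, 100.0)],
        g_max=10.0,
    )


def random_gating_params(rng: np.random.Generator, name: str = "rand") -> gating.GatingParams:
    """Random but physiological channel: used by the recovery property suites.

    Time constants are kept in ranges where 5-s conditioning reaches steady
    state and activation is fast relative to inactivation at depolarized
    voltages, as for real T-type currents.
    """
    v_half_act = rng.uniform(-60.0, -40.0)
    k_act = rng.uniform(4.5, 7.5)
    v_half_inact = rng.uniform(-85.0, -68.0)
    k_inact = rng.uniform(3.5, 6.5)
    s_act = rng.uniform(0.6, 1.8)
    s_inact = rng.uniform(0.6, 1.6)
    wt_act = [(-70, 40), (-60, 25), (-50, 12), (-40, 6), (-30, 4), (-20, 3), (0, 2.5), (30, 2)]
    wt_inact = [(-120, 150), (-110, 200), (-100, 250), (-90, 400), (-80, 550),
                (-70, 500), (-60, 350), (-50, 220), (-40, 160), (-30, 150), (0, 150), (30, 150)]
    return gating.GatingParams(
        name=name,
        v_half_act=v_half_act, k_act=k_act,
        v_half_inact=v_half_inact, k_inact=k_inact,
        tau_act_table=[(v, t * s_act) for v, t in wt_act],
        tau_inact_table=[(v, t * s_inact) for v, t in wt_inact],
        tau_deact_table=[(-120, 1.0), (-110, 1.2), (-100, 1.5), (-90, 2.0), (-80, 2.8)],
        g_max=rng.uniform(5.0, 20.0),
    )
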