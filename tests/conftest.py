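import dataclasses

import numpy as np
import pytest

from epimark import iodata, pipeline, quantify, synth_degradome as sd


@pytest.fixture(scope="session")
def table1():
    return iodata.load_table1()


@pytest.fixture(scope="session")
def table2():
    return iodata.load_table2()


@pytest.fixture(scope="session")
def postmortem_sim(table1):
    """Default post-mortem liver/brain study, shared across tests."""
    return sd.simulate_study(sd.default_config("postmortem", seed=1), table=table1)


@pytest.fixture(scope="session")
def postmortem_matrices(postmortem_sim, table1):
    return pipeline.quantify_stage(
        postmortem_sim.peaks, postmortem_sim.uv, postmortem_sim.meta,
        table1, quantify.ISTDSpec())


@pytest.fixture(scope="session")
def braintissues_sim(table1):
    return sd.simulate_study(sd.default_config("braintissues", seed=3), table=table1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_table():
    """A 3-modification panel, one of them without a heavy channel."""
    rows = []
    for name, silis in (("m5C", True), ("m6,6A", True), ("Q", False)):
        rows.append(iodata.Transition(name, 300.0, 150.0, 80, 10, 2, 10.0, 5.0,
                                      "positive", "C12"))
        if silis:
            rows.append(iodata.Transition(name, 310.0, 155.0, 80, 10, 2, 10.0,
                                          5.0, "positive", "C13"))
    return iodata.TransitionTable(rows)


@pytest.fixture()
def small_panel():
    return tiny_table()
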