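import numpy as np
import pytest

from boutloop import controller as ct
from boutloop import reafference as rf
from boutloop import synth as sy


@pytest.fixture(scope="session")
def unique_conditions():
    return rf.enumerate_conditions()


@pytest.fixture(scope="session")
def reference_summary():
    """36-value duration table of the frozen reference controller."""
    return ct.condition_summary(ct.REFERENCE_PARAMS)


@pytest.fixture(scope="session")
def short_protocol():
    """Long-term adaptation protocol with a scaled-down adaptation phase."""
    return rf.build_protocol("long_term_adaptation", "lag_trained", n_adaptation=20)


@pytest.fixture(scope="session")
def scripted_session(short_protocol):
    return sy.gen_tail_session(short_protocol, seed=1)


@pytest.fixture(scope="session")
def imaging_session():
    """Controller-driven whole-brain-imaging session (full protocol)."""
    proto = rf.build_protocol("whole_brain_imaging")
    rec, truth = sy.gen_tail_session(proto, seed=3, behaver=ct.REFERENCE_PARAMS)
    return proto, rec, truth


@pytest.fixture(scope="session")
def pc_session():
    proto = rf.build_protocol("pc_imaging", "lag_trained")
    rec, truth = sy.gen_tail_session(proto, seed=4, behaver=ct.REFERENCE_PARAMS)
    return proto, rec, truth


def qualitative_suite(summary, labels):
    """The acute-reaction ordering relations the controller must reproduce."""
    b = dict(zip(labels, summary[:18]))
    i = dict(zip(labels, summary[18:]))
    lag_seq = [b["normal"], b["lag_75"], b["lag_150"], b["lag_225"],
               b["lag_300"], b["open_loop"]]
    return {
        "bout_open_loop_gt_normal": b["open_loop"] > b["normal"],
        "interbout_open_loop_gt_normal": i["open_loop"] > i["normal"],
        "interbout_gain2_gt_normal": i["gain_2"] > i["normal"],
        "bout_monotone_in_lag": bool(np.all(np.diff(lag_seq) >= 0)),
        "interbout_lag300_gt_shunted": i["lag_300"] > i["lag_300_shunted"],
        "bout_0111_gt_1110": b["lag_75_shunted"] > b["drop_1110"],
        "interbout_1100_lt_0011": i["drop_1100"] < i["lag_150_shunted"],
    }
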