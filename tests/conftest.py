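"""Shared fixtures: a short Simon session and its simulated trial records.

Unit tests run on a 20-trial session (16 congruent / 4 incongruent, the
Session-I class ratio) so synthesis and filtering stay fast; full-scale
cohorts are built only where a check is about cohort-level recovery.
"""

import pytest

from arcsim.behavior_sim import AgentParams, records_to_frame, simulate_session
from arcsim.task_design import SessionDesign


@pytest.fixture(scope="session")
def agent() -> AgentParams:
    return AgentParams()


@pytest.fixture(scope="session")
def short_design() -> SessionDesign:
    return SessionDesign(label="I", n_congruent=16, n_incongruent=4, seed=11)


@pytest.fixture(scope="session")
def short_records(short_design, agent):
    return simulate_session(short_design, agent, 5)


@pytest.fixture(scope="session")
def short_events(short_records):
    events = records_to_frame(short_records)
    events["step_side"] = events["final_side"]
    return events[events["event_condition"] != "UNDEFINED"].reset_index(drop=True)
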