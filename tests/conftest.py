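"""Shared fixtures: synthetic subjects and their full pipeline analyses.

The expensive artifacts (30 min recordings, per-subject analyses) are
session-scoped and reused across test modules.
"""

import numpy as np
import pytest

from lfpstates import pipeline, synth

CTRL_SEED = 42
ELS_SEED = 43
FIXTURE_DURATION_S = 1800.0


@pytest.fixture(scope="session")
def ctrl_subject():
    return synth.make_subject(synth.ctrl_spec(duration_s=FIXTURE_DURATION_S),
                              "ctrl-fix", CTRL_SEED)


@pytest.fixture(scope="session")
def els_subject():
    return synth.make_subject(synth.els_spec(duration_s=FIXTURE_DURATION_S),
                              "els-fix", ELS_SEED)


@pytest.fixture(scope="session")
def ctrl_analysis(ctrl_subject):
    rec, _ = ctrl_subject
    return pipeline.analyze_subject(rec, seed=1)


@pytest.fixture(scope="session")
def els_analysis(els_subject):
    rec, _ = els_subject
    return pipeline.analyze_subject(rec, seed=1)


@pytest.fixture(scope="session")
def plain_ctrl_recording():
    """Un-jittered CTRL recording with known states (planted = preset values)."""
    spec = synth.ctrl_spec(duration_s=FIXTURE_DURATION_S)
    states = synth.sample_state_sequence(spec, 7, require_all_states=True)
    rec, truth = synth.synthesize_recording(spec, states, 8)
    return spec, rec, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
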