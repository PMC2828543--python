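import numpy as np
import pytest

from satlab import (
    AgentParams,
    CalibrationProfile,
    TaskVersion,
    build_schedule,
    emit_behavior,
    simulate_cohort,
)


@pytest.fixture
def calibration():
    return CalibrationProfile(mean_rt_ms=300.0, sdf_ms=20.0)


@pytest.fixture
def blue_version():
    return TaskVersion.from_high_feature("blue")


@pytest.fixture(scope="session")
def example_log():
    """One deterministic synthetic subject, reused across read-only tests."""
    calib = CalibrationProfile(mean_rt_ms=300.0, sdf_ms=20.0)
    version = TaskVersion.from_high_feature("blue")
    schedule = build_schedule(version, seed=7, calibration=calib)
    return emit_behavior(schedule, AgentParams(), calib, seed=11, subject_id="sub-ex")


@pytest.fixture(scope="session")
def example_cohort():
    return simulate_cohort(19, master_seed=42)


def make_trial(rewarded=True, probe_duration_ms=340.0, block=1, index=1):
    """A standalone trial for payout tests."""
    from satlab import CueStimulus, TrialSpec

    return TrialSpec(
        block=block,
        index_in_block=index,
        cue=CueStimulus("blue", "animal", 1),
        rewarded=rewarded,
        probe_delay_s=4.0,
        probe_duration_ms=probe_duration_ms,
        onset_s=0.0,
    )
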