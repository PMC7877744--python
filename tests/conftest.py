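import dataclasses

import numpy as np
import pytest

from kinclust.config import AnalysisConfig, CohortConfig, RunConfig
from kinclust.recording import EventPair, TrialRecording
from kinclust.synthetic import identity_effects


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """A deliberately small cohort for fast structural tests."""
    return CohortConfig(
        n_norm=4,
        n_bp=2,
        n_dk=2,
        n_trials=1,
        tasks=("JHFT1", "JHFT2"),
        segment_counts={"JHFT1": 2, "JHFT2": 5},
        segment_frames=80,
        gap_frames=30,
        lead_frames=20,
    )


@pytest.fixture(scope="session")
def tiny_run_config(tiny_cohort_config) -> RunConfig:
    return RunConfig(
        master_seed=7,
        cohort=tiny_cohort_config,
        analysis=AnalysisConfig(n_iterations=2),
    ).validate()


@pytest.fixture(scope="session")
def null_effects():
    return {c: identity_effects(c) for c in ("Norm", "BP", "DK")}


@pytest.fixture()
def flat_trial() -> TrialRecording:
    """A 300-frame all-zero trial with one event pair, for window arithmetic."""
    return TrialRecording(
        participant_id="Norm01",
        condition="Norm",
        task="JHFT1",
        trial_index=1,
        angles=np.zeros((300, 14)),
        events=[EventPair(1, 100, 200)],
    )


def make_trial(angles: np.ndarray, events, **kw) -> TrialRecording:
    defaults = dict(
        participant_id="Norm01", condition="Norm", task="JHFT1", trial_index=1
    )
    defaults.update(kw)
    return TrialRecording(angles=angles, events=events, **defaults)


@pytest.fixture()
def restrict_analysis():
    """Helper to narrow a RunConfig's analysis to one condition."""

    def _restrict(cfg: RunConfig, *conditions: str) -> RunConfig:
        return dataclasses.replace(
            cfg, analysis=dataclasses.replace(cfg.analysis, conditions=conditions)
        )

    return _restrict
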