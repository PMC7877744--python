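"""Synthetic joint-angle cohorts with the statistical structure the analysis assumes.

Each trial is a sequence of object manipulations. Per manipulation, every DOF
performs a smooth out-and-back excursion whose position profile is the
minimum-jerk polynomial 10*tau^3 - 15*tau^4 + 6*tau^5 (bell-shaped velocity,
the standard model of point-to-point reaching), on top of a participant-specific
baseline posture. Bypass conditions add configurable compensatory effects per
(task, DOF): a postural offset, an amplitude rescaling, a windowed oscillation
(tremor-like), and a movement-speed rescaling. I.i.d. Gaussian sensor noise is
added last, before any filtering, so the downstream low-pass is exercised.

The generator emulates group structure, not biomechanics: DOFs are generated
independently (no joint coupling) and no marker-level artifacts are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import CohortConfig
from .inventory import DOFS, dof_index, validate_condition, validate_task
from .recording import Cohort, EventPair, TrialRecording
from .rng import substream

# Resting posture and default excursion amplitude per DOF, degrees. Right-arm
# DOFs carry the task; the left arm is mostly idle; torso and neck move little.
BASE_ANGLE_DEG: dict[str, float] = {
    "r_elbow_flex_ext": 70.0,
    "l_elbow_flex_ext": 65.0,
    "r_shoulder_flex_ext": 35.0,
    "r_shoulder_ab_ad": 15.0,
    "r_shoulder_rot": 10.0,
    "l_shoulder_flex_ext": 10.0,
    "l_shoulder_ab_ad": 8.0,
    "l_shoulder_rot": 5.0,
    "torso_flex_ext": 8.0,
    "torso_lat_flex": 2.0,
    "torso_rot": 3.0,
    "neck_flex_ext": 12.0,
    "neck_lat_flex": 2.0,
    "neck_rot": 3.0,
}

BASE_AMPLITUDE_DEG: dict[str, float] = {
    "r_elbow_flex_ext": 25.0,
    "l_elbow_flex_ext": 4.0,
    "r_shoulder_flex_ext": 30.0,
    "r_shoulder_ab_ad": 12.0,
    "r_shoulder_rot": 10.0,
    "l_shoulder_flex_ext": 4.0,
    "l_shoulder_ab_ad": 4.0,
    "l_shoulder_rot": 3.0,
    "torso_flex_ext": 6.0,
    "torso_lat_flex": 3.0,
    "torso_rot": 5.0,
    "neck_flex_ext": 6.0,
    "neck_lat_flex": 2.0,
    "neck_rot": 4.0,
}


@dataclass(frozen=True)
class EffectParams:
    """Compensatory-movement effect for one (task, DOF) cell of one condition."""

    offset_shift: float = 0.0  # degrees, added to the whole trace
    amplitude_scale: float = 1.0  # dimensionless, >= 0
    oscillation_amp: float = 0.0  # degrees
    oscillation_freq: float = 0.0  # Hz, must stay below Nyquist
    velocity_scale: float = 1.0  # dimensionless, > 0; rescales movement speed

    def validate(self, nyquist_hz: float) -> None:
        if self.amplitude_scale < 0:
            raise ValueError(
                f"amplitude_scale must be >= 0, got {self.amplitude_scale}"
            )
        if self.velocity_scale <= 0:
            raise ValueError(
                f"velocity_scale must be > 0, got {self.velocity_scale}"
            )
        if self.oscillation_amp < 0:
            raise ValueError("oscillation_amp must be >= 0")
        if self.oscillation_amp > 0 and not 0 < self.oscillation_freq < nyquist_hz:
            raise ValueError(
                f"oscillation_freq {self.oscillation_freq} Hz must lie in "
                f"(0, {nyquist_hz}) Hz"
            )

    @property
    def is_identity(self) -> bool:
        return self == EffectParams()


IDENTITY_EFFECT = EffectParams()


@dataclass
class GroupEffectSpec:
    """Per-condition map of (task, DOF) -> EffectParams.

    The Norm condition is the reference and must carry no effects.
    """

    condition: str
    effects: dict[tuple[str, str], EffectParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_condition(self.condition)
        if self.condition == "Norm" and any(
            not e.is_identity for e in self.effects.values()
        ):
            raise ValueError("the Norm condition must have identity effects")
        for (task, dof) in self.effects:
            validate_task(task)
            dof_index(dof)

    def validate(self, nyquist_hz: float) -> "GroupEffectSpec":
        for params in self.effects.values():
            params.validate(nyquist_hz)
        return self

    def get(self, task: str, dof: str) -> EffectParams:
        return self.effects.get((task, dof), IDENTITY_EFFECT)


def identity_effects(condition: str = "Norm") -> GroupEffectSpec:
    return GroupEffectSpec(condition=condition)


def single_cell_effects(
    condition: str, task: str, dof: str, **params
) -> GroupEffectSpec:
    """Effect spec that perturbs exactly one (task, DOF) cell."""
    return GroupEffectSpec(
        condition=condition, effects={(task, dof): EffectParams(**params)}
    )


def default_effect_spec() -> dict[str, GroupEffectSpec]:
    """Built-in compensatory-movement preset for the two bypass conditions.

    Magnitudes are illustrative (the underlying study reports no effect sizes):
    postural offsets of 6-10 degrees, amplitude inflation of 20-40%, and small
    1.5-2 Hz oscillations. The body-powered preset loads the torso, right
    shoulder and contralateral shoulder; the DEKA preset additionally loads the
    neck, mimicking the device-specific patterns such systems tend to elicit.
    """
    bp = {
        ("JHFT2", "torso_rot"): EffectParams(offset_shift=8.0, amplitude_scale=1.4),
        ("JHFT3", "torso_rot"): EffectParams(offset_shift=7.0, amplitude_scale=1.3),
        ("JHFT5", "torso_rot"): EffectParams(offset_shift=6.0, amplitude_scale=1.3),
        ("JHFT2", "r_shoulder_ab_ad"): EffectParams(
            offset_shift=8.0, amplitude_scale=1.3
        ),
        ("JHFT6", "r_shoulder_ab_ad"): EffectParams(
            offset_shift=7.0, amplitude_scale=1.2
        ),
        ("JHFT4", "r_shoulder_flex_ext"): EffectParams(
            offset_shift=9.0, velocity_scale=0.8
        ),
        ("TBBT_SIT", "r_shoulder_ab_ad"): EffectParams(
            offset_shift=7.0, amplitude_scale=1.3
        ),
        ("TBBT_SIT", "l_shoulder_ab_ad"): EffectParams(
            offset_shift=6.0, oscillation_amp=2.0, oscillation_freq=1.5
        ),
        ("TBBT_STAND", "l_shoulder_ab_ad"): EffectParams(offset_shift=6.0),
        ("JHFT7", "torso_flex_ext"): EffectParams(
            offset_shift=6.0, amplitude_scale=1.3
        ),
    }
    dk = {
        ("JHFT2", "neck_flex_ext"): EffectParams(offset_shift=8.0),
        ("JHFT3", "neck_flex_ext"): EffectParams(offset_shift=7.0),
        ("JHFT2", "neck_rot"): EffectParams(offset_shift=6.0, amplitude_scale=1.4),
        ("JHFT5", "neck_rot"): EffectParams(offset_shift=6.0),
        ("JHFT4", "r_shoulder_ab_ad"): EffectParams(
            offset_shift=8.0, amplitude_scale=1.3
        ),
        ("JHFT4", "r_shoulder_rot"): EffectParams(
            offset_shift=7.0, oscillation_amp=2.0, oscillation_freq=2.0
        ),
        ("JHFT6", "r_shoulder_ab_ad"): EffectParams(
            offset_shift=7.0, amplitude_scale=1.2
        ),
        ("TBBT_SIT", "l_shoulder_ab_ad"): EffectParams(offset_shift=7.0),
        ("JHFT1", "torso_rot"): EffectParams(offset_shift=6.0, velocity_scale=0.8),
        ("JHFT7", "torso_flex_ext"): EffectParams(offset_shift=6.0),
    }
    return {
        "Norm": identity_effects("Norm"),
        "BP": GroupEffectSpec("BP", bp),
        "DK": GroupEffectSpec("DK", dk),
    }


def load_effect_spec(path: str | Path) -> dict[str, GroupEffectSpec]:
    """Read a YAML effect spec: {condition: [{task, dof, offset_shift, ...}, ...]}."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    specs: dict[str, GroupEffectSpec] = {"Norm": identity_effects("Norm")}
    for condition, rows in data.items():
        effects = {}
        for row in rows or []:
            row = dict(row)
            task, dof = row.pop("task"), row.pop("dof")
            effects[(task, dof)] = EffectParams(**row)
        specs[condition] = GroupEffectSpec(condition, effects)
    return specs


@dataclass
class ParticipantSpec:
    """Per-participant movement style: baseline posture and excursion amplitudes."""

    participant_id: str
    condition: str
    baseline_deg: np.ndarray  # (14,)
    amplitude_deg: np.ndarray  # (14,)

    def __post_init__(self) -> None:
        validate_condition(self.condition)
        self.baseline_deg = np.asarray(self.baseline_deg, dtype=float)
        self.amplitude_deg = np.asarray(self.amplitude_deg, dtype=float)
        if self.baseline_deg.shape != (len(DOFS),) or self.amplitude_deg.shape != (
            len(DOFS),
        ):
            raise ValueError("baseline_deg and amplitude_deg must have shape (14,)")


def draw_participant(
    participant_id: str,
    condition: str,
    master_seed: int,
    config: CohortConfig | None = None,
) -> ParticipantSpec:
    """Sample one participant's movement style from the population model.

    Style is drawn from the same distribution for every condition, so with
    identity effects the conditions are exchangeable by construction.
    """
    cfg = config or CohortConfig()
    rng = substream(master_seed, "participant", participant_id)
    base = np.array([BASE_ANGLE_DEG[d] for d in DOFS])
    amp = np.array([BASE_AMPLITUDE_DEG[d] for d in DOFS])
    baseline = base + rng.normal(0.0, cfg.participant_baseline_sd_deg, len(DOFS))
    factors = np.clip(
        rng.normal(1.0, cfg.participant_amplitude_frac_sd, len(DOFS)), 0.2, None
    )
    return ParticipantSpec(participant_id, condition, baseline, amp * factors)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]: 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _out_and_back(n: int) -> np.ndarray:
    """Reach out and return over n frames: minimum-jerk up then down, peak 1."""
    tau = np.linspace(0.0, 1.0, n)
    half = _minimum_jerk(np.where(tau <= 0.5, 2 * tau, 2 * (1 - tau)))
    return half


def generate_trial(
    participant: ParticipantSpec,
    task: str,
    effects: GroupEffectSpec,
    master_seed: int,
    trial_index: int = 1,
    config: CohortConfig | None = None,
) -> TrialRecording:
    """Generate one trial: per-segment minimum-jerk excursions on all 14 DOFs.

    Deterministic in (master_seed, participant_id, task, trial_index): the same
    seed reproduces the trial bit for bit.
    """
    cfg = config or CohortConfig()
    validate_task(task)
    nyquist = cfg.frame_rate_hz / 2
    effects.validate(nyquist)
    n_seg = cfg.segment_counts.get(task, 5)
    rng = substream(
        master_seed, "trial", participant.participant_id, task, trial_index
    )

    # Excursion lengths per DOF: the velocity_scale effect shortens or
    # lengthens the movement; lengthening is bounded so segments never overlap
    # and the +/-10 frame segment margins never clamp.
    base_len = cfg.segment_frames
    max_len = base_len + cfg.gap_frames - 2 * 10  # keep >=10-frame clearance
    dof_lengths: dict[str, int] = {}
    for dof in DOFS:
        eff = effects.get(task, dof)
        length = int(round(base_len / eff.velocity_scale))
        dof_lengths[dof] = int(np.clip(length, 4, max_len))
    event_len = max(dof_lengths.values())  # events bracket every DOF's excursion

    slot = max(base_len, event_len) + cfg.gap_frames
    starts = [cfg.lead_frames + j * slot for j in range(n_seg)]
    n_frames = starts[-1] + event_len + cfg.lead_frames

    angles = np.tile(participant.baseline_deg, (n_frames, 1))
    t = np.arange(n_frames) / cfg.frame_rate_hz

    for d, dof in enumerate(DOFS):
        eff = effects.get(task, dof)
        amp_base = participant.amplitude_deg[d] * eff.amplitude_scale
        length = dof_lengths[dof]
        profile = _out_and_back(length)
        for j, start in enumerate(starts):
            jitter = rng.normal(1.0, cfg.segment_amplitude_frac_sd)
            seg = amp_base * max(jitter, 0.0) * profile
            if eff.oscillation_amp > 0:
                tau = np.linspace(0.0, 1.0, length)
                window = np.sin(np.pi * tau) ** 2
                seg = seg + eff.oscillation_amp * window * np.sin(
                    2 * np.pi * eff.oscillation_freq * t[start : start + length]
                )
            angles[start : start + length, d] += seg
        angles[:, d] += eff.offset_shift

    events = [
        EventPair(
            object_index=j + 1,
            contact_frame=start,
            release_frame=start + event_len - 1,
        )
        for j, start in enumerate(starts)
    ]

    if cfg.noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, cfg.noise_sd_deg, angles.shape)

    return TrialRecording(
        participant_id=participant.participant_id,
        condition=participant.condition,
        task=task,
        trial_index=trial_index,
        angles=angles,
        events=events,
        frame_rate=cfg.frame_rate_hz,
    )


def cohort_participants(config: CohortConfig) -> list[tuple[str, str]]:
    """(participant_id, condition) pairs in canonical order."""
    out = []
    for i in range(config.n_norm):
        out.append((f"Norm{i + 1:02d}", "Norm"))
    for i in range(config.n_bp):
        out.append((f"BP{i + 1:02d}", "BP"))
    for i in range(config.n_dk):
        out.append((f"DK{i + 1:02d}", "DK"))
    return out


def generate_cohort(
    config: CohortConfig,
    master_seed: int,
    effect_specs: dict[str, GroupEffectSpec] | None = None,
    config_hash: str | None = None,
) -> Cohort:
    """Generate the full cohort: participants x tasks x trials recordings.

    ``effect_specs`` maps condition name to its GroupEffectSpec; conditions
    absent from the map get identity effects (the Norm condition always does).
    """
    config.validate()
    if effect_specs is None:
        effect_specs = default_effect_spec()
    recordings: list[TrialRecording] = []
    participants = cohort_participants(config)
    for pid, condition in participants:
        spec = draw_participant(pid, condition, master_seed, config)
        effects = (
            identity_effects(condition)
            if condition == "Norm"
            else effect_specs.get(condition, identity_effects(condition))
        )
        for task in config.tasks:
            for trial_index in range(1, config.n_trials + 1):
                recordings.append(
                    generate_trial(
                        spec, task, effects, master_seed, trial_index, config
                    )
                )
    manifest = {
        "seed": int(master_seed),
        "config_hash": config_hash,
        "participants": [
            {"participant_id": p, "condition": c} for p, c in participants
        ],
        "tasks": list(config.tasks),
        "n_trials": config.n_trials,
        "n_recordings": len(recordings),
    }
    return Cohort(
        recordings=recordings,
        seed=int(master_seed),
        config_hash=config_hash,
        manifest=manifest,
    )
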