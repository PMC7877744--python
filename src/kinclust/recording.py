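"""In-memory containers for joint-angle trial recordings.

A trial is one participant performing one task once: a frames x 14 matrix of
joint angles in degrees sampled at 100 Hz, plus the object contact/release
event pairs that delimit each manipulation segment. Frames are 0-based;
event intervals [contact, release] are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inventory import DOFS, validate_condition, validate_task


@dataclass(frozen=True)
class EventPair:
    """One object manipulation: 1-based object index and its contact/release frames."""

    object_index: int
    contact_frame: int
    release_frame: int

    def __post_init__(self) -> None:
        if self.object_index < 1:
            raise ValueError(f"object_index must be >= 1, got {self.object_index}")
        if self.contact_frame < 0:
            raise ValueError(f"contact_frame must be >= 0, got {self.contact_frame}")
        if self.release_frame <= self.contact_frame:
            raise ValueError(
                f"release_frame ({self.release_frame}) must exceed "
                f"contact_frame ({self.contact_frame})"
            )


@dataclass
class TrialRecording:
    """Joint-angle matrix (frames x 14 DOFs, degrees) with event annotations."""

    participant_id: str
    condition: str
    task: str
    trial_index: int
    angles: np.ndarray
    events: list[EventPair]
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        validate_condition(self.condition)
        validate_task(self.task)
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != len(DOFS):
            raise ValueError(
                f"angles must be (frames, {len(DOFS)}), got {self.angles.shape}"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain non-finite samples")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.events:
            raise ValueError(
                f"trial {self.key} has no event pairs; at least one is required"
            )
        self.events = sorted(self.events, key=lambda e: e.contact_frame)
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.contact_frame <= prev.release_frame:
                raise ValueError(
                    f"overlapping event pairs in trial {self.key}: "
                    f"{prev} then {nxt}"
                )
        last = self.events[-1]
        if last.release_frame + 10 > self.n_frames - 1:
            raise ValueError(
                f"trial {self.key}: last release frame {last.release_frame} leaves "
                f"fewer than 10 trailing frames ({self.n_frames} total)"
            )

    @property
    def n_frames(self) -> int:
        return int(self.angles.shape[0])

    @property
    def key(self) -> tuple[str, str, int]:
        """Unique (participant, task, trial) identifier within a dataset."""
        return (self.participant_id, self.task, self.trial_index)

    def dof_trace(self, dof: str) -> np.ndarray:
        from .inventory import dof_index

        return self.angles[:, dof_index(dof)]


@dataclass
class Cohort:
    """A generated or loaded dataset: recordings plus provenance metadata."""

    recordings: list[TrialRecording]
    seed: int | None = None
    config_hash: str | None = None
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def participants(self, condition: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.recordings:
            if condition is None or rec.condition == condition:
                seen.setdefault(rec.participant_id, None)
        return list(seen)

    def select(self, **where) -> list[TrialRecording]:
        """Recordings matching equality constraints on recording attributes."""
        out = self.recordings
        for attr, value in where.items():
            out = [r for r in out if getattr(r, attr) == value]
        return out
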