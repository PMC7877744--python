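"""Plain-text persistence for trial recordings, manifests and result tables.

Layout under a dataset root:

    manifest.json                       seed, config hash, file index
    <participant>/<task>_t<trial>_angles.csv   column "frame" + 14 DOF columns
    <participant>/<task>_t<trial>_events.csv   object_index, contact_frame, release_frame

CSV is UTF-8, '.'-decimal, headered; angles are written with enough digits to
round-trip well below 1e-9 degrees.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .inventory import DOFS
from .recording import Cohort, EventPair, TrialRecording

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def trial_file_stem(trial: TrialRecording) -> str:
    return f"{trial.task}_t{trial.trial_index}"


def write_trial(trial: TrialRecording, directory: str | Path) -> tuple[Path, Path]:
    """Write one recording as an angles CSV and an events CSV; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = trial_file_stem(trial)
    angles_path = directory / f"{stem}_angles.csv"
    events_path = directory / f"{stem}_events.csv"

    frame = pd.DataFrame(trial.angles, columns=list(DOFS))
    frame.insert(0, "frame", np.arange(trial.n_frames))
    frame.to_csv(angles_path, index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(
        [
            {
                "object_index": e.object_index,
                "contact_frame": e.contact_frame,
                "release_frame": e.release_frame,
            }
            for e in trial.events
        ]
    ).to_csv(events_path, index=False)
    return angles_path, events_path


def read_trial(
    angles_path: str | Path,
    events_path: str | Path,
    participant_id: str,
    condition: str,
    task: str,
    trial_index: int,
    frame_rate: float = 100.0,
) -> TrialRecording:
    angles_df = pd.read_csv(angles_path)
    missing = [c for c in DOFS if c not in angles_df.columns]
    if missing:
        raise ValueError(
            f"angles file {angles_path} is missing DOF column(s): {missing}"
        )
    events_df = pd.read_csv(events_path)
    events = [
        EventPair(
            object_index=int(row.object_index),
            contact_frame=int(row.contact_frame),
            release_frame=int(row.release_frame),
        )
        for row in events_df.itertuples()
    ]
    return TrialRecording(
        participant_id=participant_id,
        condition=condition,
        task=task,
        trial_index=trial_index,
        angles=angles_df[list(DOFS)].to_numpy(float),
        events=events,
        frame_rate=frame_rate,
    )


def write_dataset(cohort: Cohort, root: str | Path) -> Path:
    """Write every recording plus a manifest.json; return the manifest path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in cohort:
        directory = root / trial.participant_id
        angles_path, events_path = write_trial(trial, directory)
        entries.append(
            {
                "participant_id": trial.participant_id,
                "condition": trial.condition,
                "task": trial.task,
                "trial_index": trial.trial_index,
                "frame_rate": trial.frame_rate,
                "angles_file": str(angles_path.relative_to(root)),
                "events_file": str(events_path.relative_to(root)),
            }
        )
    manifest = dict(cohort.manifest)
    manifest.update(
        {
            "seed": cohort.seed,
            "config_hash": cohort.config_hash,
            "recordings": entries,
        }
    )
    manifest_path = root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest_path


def read_dataset(
    manifest_path: str | Path, expected_config_hash: str | None = None
) -> Cohort:
    """Load a dataset from its manifest; validates keys and file references."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    entries = manifest.get("recordings", [])
    if not entries:
        logger.warning("manifest %s lists no recordings", manifest_path)
    if expected_config_hash is not None and manifest.get("config_hash") not in (
        None,
        expected_config_hash,
    ):
        logger.warning(
            "manifest config hash %s does not match expected %s",
            manifest.get("config_hash"),
            expected_config_hash,
        )

    seen: set[tuple[str, str, int]] = set()
    recordings: list[TrialRecording] = []
    for entry in entries:
        key = (entry["participant_id"], entry["task"], int(entry["trial_index"]))
        if key in seen:
            raise ValueError(f"duplicate (participant, task, trial) key: {key}")
        seen.add(key)
        angles_path = root / entry["angles_file"]
        events_path = root / entry["events_file"]
        for p in (angles_path, events_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest references missing file: {p}"
                )
        recordings.append(
            read_trial(
                angles_path,
                events_path,
                participant_id=entry["participant_id"],
                condition=entry["condition"],
                task=entry["task"],
                trial_index=int(entry["trial_index"]),
                frame_rate=float(entry.get("frame_rate", 100.0)),
            )
        )

    cohort = Cohort(
        recordings=recordings,
        seed=manifest.get("seed"),
        config_hash=manifest.get("config_hash"),
        manifest=manifest,
    )
    counts: dict[tuple[str, str], int] = {}
    for r in recordings:
        counts[(r.condition, r.task)] = counts.get((r.condition, r.task), 0) + 1
    for (condition, task), n in sorted(counts.items()):
        logger.info("loaded %d recordings for condition=%s task=%s", n, condition, task)
    return cohort
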