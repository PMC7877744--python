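"""Run configuration: defaults, YAML/JSON loading, validation and hashing.

Defaults mirror the analysis parameters of the study design this package
implements: 100 Hz capture, 4th-order zero-lag 6 Hz low-pass, +/-10 frame
segment margins, binary k-means with k-means++ and five replicates, ten
randomized norm-control iterations, DfC threshold 25, alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inventory import BYPASS_CONDITIONS, DEFAULT_SEGMENT_COUNTS, TASKS


@dataclass
class CohortConfig:
    n_norm: int = 12
    n_bp: int = 6
    n_dk: int = 6
    n_trials: int = 2
    tasks: tuple[str, ...] = TASKS
    segment_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_COUNTS)
    )
    noise_sd_deg: float = 0.5  # additive sensor noise, degrees
    # between-participant variability of movement style
    participant_baseline_sd_deg: float = 2.0
    participant_amplitude_frac_sd: float = 0.10
    # within-participant, between-segment variability
    segment_amplitude_frac_sd: float = 0.05
    frame_rate_hz: float = 100.0
    segment_frames: int = 120  # one object manipulation, 1.2 s
    gap_frames: int = 40  # between release and next contact
    lead_frames: int = 30  # before first contact / after last release

    def validate(self) -> None:
        for name in ("n_norm", "n_bp", "n_dk"):
            if getattr(self, name) < 1:
                raise ValueError(f"cohort count {name} must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks in config: {sorted(unknown)}")
        for t in self.tasks:
            if self.segment_counts.get(t, 0) < 1:
                raise ValueError(f"task {t} needs a segment count >= 1")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        if self.gap_frames < 10 or self.lead_frames < 10:
            raise ValueError(
                "gap_frames and lead_frames must be >= 10 so segment margins "
                "never clamp"
            )


@dataclass
class FilterConfig:
    cutoff_hz: float = 6.0
    order: int = 4
    # "half_order_dual_pass": order/2 Butterworth applied forward-backward,
    # the biomechanics convention for an "Nth order zero lag" filter.
    # "literal_dual_pass": full order per pass.
    mode: str = "half_order_dual_pass"

    def validate(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.mode not in ("half_order_dual_pass", "literal_dual_pass"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.mode == "half_order_dual_pass" and self.order % 2:
            raise ValueError("half_order_dual_pass requires an even order")


@dataclass
class SegmentConfig:
    pre_frames: int = 10
    post_frames: int = 10

    def validate(self) -> None:
        if self.pre_frames < 0 or self.post_frames < 0:
            raise ValueError("segment margins must be >= 0")


@dataclass
class ResampleConfig:
    n: int = 101

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("resample length must be >= 2")


@dataclass
class ClusterConfig:
    k: int = 2
    replicates: int = 5
    max_iter: int = 100

    def validate(self) -> None:
        if self.k != 2:
            raise ValueError("only binary clustering (k=2) is supported")
        if self.replicates < 1 or self.max_iter < 1:
            raise ValueError("replicates and max_iter must be >= 1")


@dataclass
class AnalysisConfig:
    n_iterations: int = 10
    threshold: float = 25.0
    alpha: float = 0.05
    method: str = "ranksum_vs_threshold"  # or "signed_rank"
    average_trials: bool = False  # collapse two trials per participant to one row
    peak_velocity_abs: bool = False  # |.| instead of signed max of the derivative
    conditions: tuple[str, ...] = BYPASS_CONDITIONS
    bh_adjust: bool = False  # Benjamini-Hochberg across cells; study applied none

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.threshold <= 50:
            raise ValueError("threshold must lie in [0, 50]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.method not in ("ranksum_vs_threshold", "signed_rank"):
            raise ValueError(f"unknown test method {self.method!r}")
        unknown = set(self.conditions) - set(BYPASS_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown bypass conditions: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Complete configuration of a simulate/run/summarize pipeline."""

    master_seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    effect_spec_path: str | None = None  # None -> built-in preset

    def validate(self) -> "RunConfig":
        if self.master_seed < 0:
            raise ValueError("master_seed must be >= 0")
        for section in (
            self.cohort,
            self.filter,
            self.segment,
            self.resample,
            self.cluster,
            self.analysis,
        ):
            section.validate()
        nyquist = self.cohort.frame_rate_hz / 2
        if self.filter.cutoff_hz >= nyquist:
            raise ValueError(
                f"filter cutoff {self.filter.cutoff_hz} Hz must be below the "
                f"Nyquist frequency {nyquist} Hz"
            )
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON encoding (sorted keys)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def _merge_section(cls, defaults, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    merged = dataclasses.asdict(defaults)
    merged.update(data)
    # tuple-typed fields arrive from YAML as lists
    for f in dataclasses.fields(cls):
        if isinstance(getattr(defaults, f.name), tuple):
            merged[f.name] = tuple(merged[f.name])
    return cls(**merged)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file (or defaults) plus overrides.

    Top-level keys: master_seed, effect_spec_path, and the section names
    cohort / filter / segment / resample / cluster / analysis, each a mapping
    of that section's fields. Unknown keys are rejected.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    data.update(overrides)

    cfg = RunConfig()
    sections = {
        "cohort": CohortConfig,
        "filter": FilterConfig,
        "segment": SegmentConfig,
        "resample": ResampleConfig,
        "cluster": ClusterConfig,
        "analysis": AnalysisConfig,
    }
    kwargs: dict = {}
    for key, value in data.items():
        if key in sections:
            kwargs[key] = _merge_section(sections[key], getattr(cfg, key), value or {})
        elif key in ("master_seed", "effect_spec_path"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return dataclasses.replace(cfg, **kwargs).validate()
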