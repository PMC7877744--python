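"""Canonical inventories: degrees of freedom, tasks, participant conditions.

The analysis operates on 14 upper-body rotational degrees of freedom (DOFs)
and 9 functional tasks — the seven Jebsen-Taylor Hand Function Test items
plus the targeted Box and Blocks Test performed standing and seated. The
orderings below are fixed; file columns, feature tables and result grids all
use them.
"""

from __future__ import annotations

# Canonical DOF ordering: right then left elbow; right shoulder (3 axes);
# left shoulder (3 axes); torso (3 axes); neck (3 axes). Angles in degrees.
DOFS: tuple[str, ...] = (
    "r_elbow_flex_ext",
    "l_elbow_flex_ext",
    "r_shoulder_flex_ext",
    "r_shoulder_ab_ad",
    "r_shoulder_rot",
    "l_shoulder_flex_ext",
    "l_shoulder_ab_ad",
    "l_shoulder_rot",
    "torso_flex_ext",
    "torso_lat_flex",
    "torso_rot",
    "neck_flex_ext",
    "neck_lat_flex",
    "neck_rot",
)

TASKS: tuple[str, ...] = (
    "JHFT1",  # writing
    "JHFT2",  # page turning (five notecards)
    "JHFT3",  # picking up small objects
    "JHFT4",  # simulated feeding
    "JHFT5",  # stacking checkers
    "JHFT6",  # moving large light objects
    "JHFT7",  # moving large heavy objects
    "TBBT_STAND",  # targeted Box and Blocks, standing
    "TBBT_SIT",  # targeted Box and Blocks, seated
)

# Participant conditions: normative controls, body-powered bypass, DEKA bypass.
CONDITIONS: tuple[str, ...] = ("Norm", "BP", "DK")
BYPASS_CONDITIONS: tuple[str, ...] = ("BP", "DK")

# Objects manipulated per trial. Page turning fixes five segments; the tBBT
# transports sixteen blocks. The remaining JHFT items default to five
# manipulations and are configurable.
DEFAULT_SEGMENT_COUNTS: dict[str, int] = {
    "JHFT1": 5,
    "JHFT2": 5,
    "JHFT3": 5,
    "JHFT4": 5,
    "JHFT5": 5,
    "JHFT6": 5,
    "JHFT7": 5,
    "TBBT_STAND": 16,
    "TBBT_SIT": 16,
}

FEATURE_NAMES: tuple[str, ...] = (
    "peak_angle",
    "range_of_motion",
    "path_distance",
    "mean_angle",
    "peak_angular_velocity",
    "zero_crossings",
)


def dof_index(dof: str) -> int:
    try:
        return DOFS.index(dof)
    except ValueError:
        raise KeyError(f"unknown DOF {dof!r}; expected one of {DOFS}") from None


def validate_task(task: str) -> str:
    if task not in TASKS:
        raise KeyError(f"unknown task {task!r}; expected one of {TASKS}")
    return task


def validate_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise KeyError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return condition
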