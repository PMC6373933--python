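"""Trial designs and the method-of-adjustment task procedure.

Experiment 1 crosses 8 test-array conditions ({spatial, size, color,
motion} x {one group, two groups}) with 2 numerosities (16, 20) and 8
repetitions: 128 trials per subject.  The response array is fixed (blue,
0.50-deg stationary dots, one 8 x 8 deg group).

Experiment 2 fixes the test array (10/15/20 dots of 0.20 deg in 64 deg^2)
and varies the *response* array in a 3 x 3 factorial (area and dot size
each at 0.5x / 1x / 2x the test array), 3 repetitions per cell: 81
trials.  Half the subjects see yellow test dots and blue response dots,
the other half the reverse.

The adjustment procedure starts the response array at a random count and
applies unit increments/decrements (clamped to [0, 50]) until the
observer's stopping rule is satisfied; only the final setting enters any
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .stimulus import (
    BASELINE_DOT_DIAMETER_DEG,
    RegionGeometry,
    StimulusSpec,
)

__all__ = [
    "RESPONSE_MIN",
    "RESPONSE_MAX",
    "EXP1_FEATURES",
    "EXP1_NUMEROSITIES",
    "EXP2_NUMEROSITIES",
    "EXP2_FACTORS",
    "TrialSpec",
    "TrialRecord",
    "exp1_test_spec",
    "exp1_response_spec",
    "exp2_test_spec",
    "exp2_response_spec",
    "build_exp1_design",
    "build_exp2_design",
    "draw_initial_response",
    "apply_adjustment",
    "run_trial",
    "records_to_frame",
]

RESPONSE_MIN = 0
RESPONSE_MAX = 50

EXP1_FEATURES = ("spatial", "size", "color", "motion")
EXP1_NUMEROSITIES = (16, 20)
EXP1_REPETITIONS = 8

EXP2_NUMEROSITIES = (10, 15, 20)
EXP2_FACTORS = (0.5, 1.0, 2.0)  # response-array area and dot-size scalings
EXP2_REPETITIONS = 3
EXP2_TEST_DIAMETER_DEG = 0.20

MOTION_SPEED_DEG_PER_S = 1.5


@dataclass(frozen=True)
class TrialSpec:
    """Condition labels plus the test/response stimulus parameterizations."""

    experiment: int
    n_test: int
    test_spec: StimulusSpec
    response_spec: StimulusSpec
    grouping_feature: Optional[str] = None  # Exp 1
    n_groups: Optional[int] = None  # Exp 1
    response_area_factor: Optional[float] = None  # Exp 2
    response_dotsize_factor: Optional[float] = None  # Exp 2
    color_assignment: Optional[str] = None  # Exp 2: {test-yellow, test-blue}


@dataclass(frozen=True)
class TrialRecord:
    subject_id: int
    trial: TrialSpec
    initial_response: int
    final_response: int
    n_key_presses: int

    def __post_init__(self) -> None:
        if not (RESPONSE_MIN <= self.final_response <= RESPONSE_MAX):
            raise ValueError("final_response outside the response range")


# ---------------------------------------------------------------------------
# Stimulus specs per condition
# ---------------------------------------------------------------------------


def exp1_response_spec() -> StimulusSpec:
    """The fixed Exp-1 response array: blue, 0.50 deg, stationary, one group."""
    return StimulusSpec(
        n_dots=16,  # placeholder count; adjustable at runtime
        region=RegionGeometry.single_square(8.0),
        dot_diameter_deg=BASELINE_DOT_DIAMETER_DEG,
        color_labels=("blue",),
    )


def exp1_test_spec(feature: str, n_groups: int, n_dots: int) -> StimulusSpec:
    """Test array for one of the 8 Exp-1 conditions.

    One-group variants differ from the response array only in the named
    feature (size: 1.0 deg dots; color: yellow; motion: coherent drift at
    1.5 deg/s); the one-group spatial condition is the baseline.  The
    two-group variants segregate the dots by that feature.
    """
    if feature not in EXP1_FEATURES:
        raise ValueError(f"unknown grouping feature {feature!r}")
    if n_groups == 1:
        kwargs: dict = {}
        if feature == "size":
            kwargs["dot_diameter_deg"] = 1.0
        elif feature == "color":
            kwargs["color_labels"] = ("yellow",)
        elif feature == "motion":
            kwargs["motion_speed_deg_per_s"] = MOTION_SPEED_DEG_PER_S
            kwargs["motion_mode"] = "coherent"
        return StimulusSpec(
            n_dots=n_dots,
            region=RegionGeometry.single_square(8.0),
            dot_diameter_deg=kwargs.pop("dot_diameter_deg", BASELINE_DOT_DIAMETER_DEG),
            color_labels=kwargs.pop("color_labels", ("blue",)),
            **kwargs,
        )
    if n_groups != 2:
        raise ValueError("n_groups must be 1 or 2")
    common = dict(n_dots=n_dots, n_groups=2, grouping_feature=feature)
    if feature == "spatial":
        return StimulusSpec(
            region=RegionGeometry.two_squares(32.0, 8.0),
            randomize_rotation=True,
            **common,
        )
    if feature == "size":
        return StimulusSpec(dot_diameter_deg=(0.25, 1.0), **common)
    if feature == "color":
        return StimulusSpec(color_labels=("yellow", "blue"), **common)
    # motion
    return StimulusSpec(
        motion_speed_deg_per_s=MOTION_SPEED_DEG_PER_S,
        motion_mode="opposed-groups",
        **common,
    )


def exp2_test_spec(n_dots: int, color_assignment: str) -> StimulusSpec:
    color = "yellow" if color_assignment == "test-yellow" else "blue"
    return StimulusSpec(
        n_dots=n_dots,
        region=RegionGeometry.single_square(8.0),
        dot_diameter_deg=EXP2_TEST_DIAMETER_DEG,
        color_labels=(color,),
    )


def exp2_response_spec(
    area_factor: float, dotsize_factor: float, color_assignment: str
) -> StimulusSpec:
    color = "blue" if color_assignment == "test-yellow" else "yellow"
    side = math.sqrt(64.0 * area_factor)
    return StimulusSpec(
        n_dots=16,  # adjustable at runtime
        region=RegionGeometry.single_square(side),
        dot_diameter_deg=EXP2_TEST_DIAMETER_DEG * dotsize_factor,
        color_labels=(color,),
    )


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


def build_exp1_design(
    rng: np.random.Generator, repetitions: int = EXP1_REPETITIONS
) -> list[TrialSpec]:
    """Shuffled full crossing: 4 features x 2 group counts x 2 numerosities
    x ``repetitions`` (default 8; 128 trials)."""
    trials: list[TrialSpec] = []
    response = exp1_response_spec()
    for feature in EXP1_FEATURES:
        for n_groups in (1, 2):
            for n in EXP1_NUMEROSITIES:
                spec = exp1_test_spec(feature, n_groups, n)
                for _ in range(repetitions):
                    trials.append(
                        TrialSpec(
                            experiment=1,
                            n_test=n,
                            test_spec=spec,
                            response_spec=response,
                            grouping_feature=feature,
                            n_groups=n_groups,
                        )
                    )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def build_exp2_design(
    rng: np.random.Generator,
    subject_color_assignment: str,
    repetitions: int = EXP2_REPETITIONS,
) -> list[TrialSpec]:
    """Shuffled crossing: 3 numerosities x 3 area factors x 3 dot-size
    factors x ``repetitions`` (default 3; 81 trials), one color assignment
    per subject."""
    if subject_color_assignment not in ("test-yellow", "test-blue"):
        raise ValueError(
            f"color assignment must be 'test-yellow' or 'test-blue', "
            f"got {subject_color_assignment!r}"
        )
    trials: list[TrialSpec] = []
    for n in EXP2_NUMEROSITIES:
        test = exp2_test_spec(n, subject_color_assignment)
        for fa in EXP2_FACTORS:
            for fd in EXP2_FACTORS:
                resp = exp2_response_spec(fa, fd, subject_color_assignment)
                for _ in range(repetitions):
                    trials.append(
                        TrialSpec(
                            experiment=2,
                            n_test=n,
                            test_spec=test,
                            response_spec=resp,
                            response_area_factor=fa,
                            response_dotsize_factor=fd,
                            color_assignment=subject_color_assignment,
                        )
                    )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


# ---------------------------------------------------------------------------
# Adjustment procedure
# ---------------------------------------------------------------------------


def draw_initial_response(n_test: int, rng: np.random.Generator) -> int:
    """Uniform integer on [round(0.5 n), round(1.5 n)] (half-up rounding).

    Reproduces the stated starting ranges 8-24 for 16-dot tests and 10-30
    for 20-dot tests, and generalizes to other numerosities.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    lo = int(math.floor(0.5 * n_test + 0.5))
    hi = int(math.floor(1.5 * n_test + 0.5))
    return int(rng.integers(lo, hi + 1))


def apply_adjustment(current: int, delta: int) -> int:
    """One key press: +/- 1 dot, clamped to the response range [0, 50]."""
    if delta not in (-1, 1):
        raise ValueError("delta must be -1 or +1")
    return min(max(current + delta, RESPONSE_MIN), RESPONSE_MAX)


class AdjustmentOverrunError(RuntimeError):
    """The observer did not settle within the key-press cap."""


ObserverPolicy = Callable[[TrialSpec, np.random.Generator], int]


def run_trial(
    trial: TrialSpec,
    observer: ObserverPolicy,
    rng: np.random.Generator,
    subject_id: int = 0,
    max_presses: int = 200,
) -> TrialRecord:
    """Run one method-of-adjustment trial.

    ``observer`` maps the trial's stimulus attributes to an internal
    target count; the simulated subject then steps the response array one
    dot at a time toward that target (clamped to [0, 50]) and submits.
    """
    initial = draw_initial_response(trial.n_test, rng)
    target = int(observer(trial, rng))
    target = min(max(target, RESPONSE_MIN), RESPONSE_MAX)
    current = initial
    presses = 0
    while current != target:
        if presses >= max_presses:
            raise AdjustmentOverrunError(
                f"no convergence after {max_presses} presses "
                f"(current={current}, target={target})"
            )
        current = apply_adjustment(current, 1 if target > current else -1)
        presses += 1
    return TrialRecord(
        subject_id=subject_id,
        trial=trial,
        initial_response=initial,
        final_response=current,
        n_key_presses=presses,
    )


def records_to_frame(records: list[TrialRecord]):
    """Trial records -> tidy DataFrame, one row per trial.

    The schema is shared by simulated and (re-)loaded trial logs so the
    analysis layer cannot tell them apart.
    """
    import pandas as pd

    rows = []
    for r in records:
        t = r.trial
        rows.append(
            {
                "subject_id": r.subject_id,
                "experiment": t.experiment,
                "grouping_feature": t.grouping_feature,
                "n_groups": t.n_groups,
                "response_area_factor": t.response_area_factor,
                "response_dotsize_factor": t.response_dotsize_factor,
                "color_assignment": t.color_assignment,
                "n_test": t.n_test,
                "initial_response": r.initial_response,
                "final_response": r.final_response,
                "n_key_presses": r.n_key_presses,
            }
        )
    return pd.DataFrame(rows)
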