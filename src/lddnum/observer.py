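"""Synthetic observer population for the numerosity-adjustment task.

The observer model combines the statistical regularities the analysis
chain presupposes:

* scalar variability (Weber's law): the internal estimate of an n-dot
  array carries zero-mean Gaussian noise with standard deviation w * n;
* feature-driven biases as power laws: an array of total area A appears
  ``(A / A0)^alpha`` times more numerous (larger area -> more), and dots
  of diameter d make the array appear ``(d / d0)^(-beta)`` times more
  numerous (larger dots -> fewer), relative to the baseline area
  A0 = 64 deg^2 and diameter d0 = 0.50 deg;
* grouping-driven gains: when the test array is segregated into two
  groups by feature f, the estimate is multiplied by a gain g_f (below 1
  for color and motion: grouping makes the array appear less numerous);
* between-subject structure: all parameters are log-normal across
  subjects and (log g_color, log g_motion) are correlated, so the two
  grouping effects covary across subjects.

At response time the observer equates perceived numerosities: the target
count is the perceived test numerosity divided by the response array's
own feature bias, so manipulating the response array's area or dot size
moves the settings in the opposite direction to the test-side bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .stimulus import BASELINE_AREA_DEG2, BASELINE_DOT_DIAMETER_DEG, StimulusSpec
from .task import (
    ObserverPolicy,
    TrialSpec,
    build_exp1_design,
    build_exp2_design,
    records_to_frame,
    run_trial,
)

__all__ = [
    "GROUPING_FEATURES",
    "ObserverParams",
    "PopulationParams",
    "sample_subject",
    "perceived_numerosity",
    "response_target",
    "make_observer",
    "simulate_subject",
    "simulate_exp1",
    "simulate_exp2",
]

GROUPING_FEATURES = ("spatial", "size", "color", "motion")


@dataclass(frozen=True)
class ObserverParams:
    """One synthetic subject.

    weber_fraction
        w in the scalar-variability noise sd = w * n_true (w >= 0; 0
        gives a noise-free observer for closed-form checks).
    area_exponent
        alpha in the area bias (A / A0)^alpha; positive means larger
        arrays look more numerous.
    size_exponent
        beta in the dot-size bias (d / d0)^(-beta); positive means larger
        dots look less numerous.
    grouping_gains
        multiplicative gain per grouping feature, applied to the test
        estimate only when the array is seen as two groups.
    lapse_sd
        additive motor/response jitter (dots) on the final setting.
    """

    weber_fraction: float = 0.15
    area_exponent: float = 0.2
    size_exponent: float = 0.135
    grouping_gains: dict = field(
        default_factory=lambda: {
            "spatial": 1.08,
            "size": 1.0,
            "color": 0.95,
            "motion": 0.95,
        }
    )
    lapse_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be >= 0")
        if self.lapse_sd < 0:
            raise ValueError("lapse_sd must be >= 0")
        if any(g <= 0 for g in self.grouping_gains.values()):
            raise ValueError("grouping gains must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Between-subject distribution of :class:`ObserverParams`.

    All positive parameters are log-normal: ``*_mean`` fields are
    geometric means (the median subject) and ``*_logsd`` fields are
    standard deviations of the natural log.  ``rho_color_motion`` is the
    correlation of (log g_color, log g_motion); the other parameters are
    independent across subjects.
    """

    weber_fraction_mean: float = 0.15
    weber_fraction_logsd: float = 0.25
    area_exponent_mean: float = 0.2
    area_exponent_logsd: float = 0.3
    size_exponent_mean: float = 0.135
    size_exponent_logsd: float = 0.3
    grouping_gain_means: dict = field(
        default_factory=lambda: {
            "spatial": 1.08,
            "size": 1.0,
            "color": 0.95,
            "motion": 0.95,
        }
    )
    grouping_gain_logsd: float = 0.08
    rho_color_motion: float = 0.6
    lapse_sd_mean: float = 0.5
    lapse_sd_logsd: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_color_motion <= 1.0:
            raise ValueError("rho_color_motion must lie in [-1, 1]")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        return cls(**d)


def _lognormal(mean: float, logsd: float, rng: np.random.Generator) -> float:
    if mean == 0:
        return 0.0
    if logsd == 0:
        return float(mean)
    return float(mean * math.exp(rng.normal(0.0, logsd)))


def sample_subject(pop: PopulationParams, rng: np.random.Generator) -> ObserverParams:
    """Draw one subject's parameters from the population.

    (log g_color, log g_motion) are jointly Gaussian with correlation
    ``rho_color_motion``; everything else is independent log-normal.
    """
    s = pop.grouping_gain_logsd
    rho = pop.rho_color_motion
    mu = np.log([pop.grouping_gain_means["color"], pop.grouping_gain_means["motion"]])
    cov = np.array([[s * s, rho * s * s], [rho * s * s, s * s]])
    log_cm = rng.multivariate_normal(mu, cov, check_valid="raise")
    gains = {
        "spatial": _lognormal(pop.grouping_gain_means["spatial"], s, rng),
        "size": _lognormal(pop.grouping_gain_means["size"], s, rng),
        "color": float(np.exp(log_cm[0])),
        "motion": float(np.exp(log_cm[1])),
    }
    return ObserverParams(
        weber_fraction=_lognormal(pop.weber_fraction_mean, pop.weber_fraction_logsd, rng),
        area_exponent=_lognormal(pop.area_exponent_mean, pop.area_exponent_logsd, rng),
        size_exponent=_lognormal(pop.size_exponent_mean, pop.size_exponent_logsd, rng),
        grouping_gains=gains,
        lapse_sd=_lognormal(pop.lapse_sd_mean, pop.lapse_sd_logsd, rng),
    )


def _feature_bias(
    area_deg2: float, diameter_deg: float, params: ObserverParams
) -> float:
    return (area_deg2 / BASELINE_AREA_DEG2) ** params.area_exponent * (
        diameter_deg / BASELINE_DOT_DIAMETER_DEG
    ) ** (-params.size_exponent)


def perceived_numerosity(
    n_true: int,
    area_deg2: float,
    dot_diameter_deg: float,
    n_groups: int,
    grouping_feature: str,
    params: ObserverParams,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Noisy internal estimate of a test array's numerosity.

    E = n * (A/A0)^alpha * (d/d0)^(-beta) * g_f^[two groups]
    + N(0, (w n)^2), truncated below at 0.  For two-group size arrays
    ``dot_diameter_deg`` should be the geometric mean of the two
    diameters (see :attr:`StimulusSpec.mean_dot_diameter_deg`).
    """
    if n_true < 1:
        raise ValueError("n_true must be >= 1")
    estimate = n_true * _feature_bias(area_deg2, dot_diameter_deg, params)
    if n_groups == 2:
        estimate *= params.grouping_gains[grouping_feature]
    if rng is not None and params.weber_fraction > 0:
        estimate += rng.normal(0.0, params.weber_fraction * n_true)
    return max(estimate, 0.0)


def response_target(
    perceived_test: float,
    response_area_deg2: float,
    response_dot_diameter_deg: float,
    params: ObserverParams,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Count at which the response array perceptually matches the test.

    The observer stops adjusting when the response array's perceived
    numerosity (its count times its own feature bias) equals the
    perceived test numerosity, so the target is
    round(perceived_test / bias_response).  A larger response area or
    smaller response dots therefore pull the settings *down*.
    """
    if perceived_test < 0:
        raise ValueError("perceived_test must be >= 0")
    bias = _feature_bias(response_area_deg2, response_dot_diameter_deg, params)
    target = perceived_test / bias
    if rng is not None and params.lapse_sd > 0:
        target += rng.normal(0.0, params.lapse_sd)
    return int(math.floor(max(target, 0.0) + 0.5))


def make_observer(params: ObserverParams) -> ObserverPolicy:
    """Wrap subject parameters into a trial-level response policy."""

    def policy(trial: TrialSpec, rng: np.random.Generator) -> int:
        test: StimulusSpec = trial.test_spec
        perceived = perceived_numerosity(
            trial.n_test,
            test.total_area_deg2,
            test.mean_dot_diameter_deg,
            test.n_groups,
            test.grouping_feature,
            params,
            rng,
        )
        resp: StimulusSpec = trial.response_spec
        return response_target(
            perceived, resp.total_area_deg2, resp.mean_dot_diameter_deg, params, rng
        )

    return policy


# ---------------------------------------------------------------------------
# Population-level simulation
# ---------------------------------------------------------------------------


def simulate_subject(
    subject_id: int,
    design: list[TrialSpec],
    params: ObserverParams,
    rng: np.random.Generator,
):
    observer = make_observer(params)
    return [run_trial(t, observer, rng, subject_id=subject_id) for t in design]


def _subject_streams(seed: int, n_subjects: int) -> list[np.random.SeedSequence]:
    # one named substream per subject: adding subjects never perturbs
    # earlier subjects' data
    return np.random.SeedSequence(seed).spawn(n_subjects)


def simulate_exp1(
    n_subjects: int = 55,
    pop: Optional[PopulationParams] = None,
    seed: int = 0,
    repetitions: int = 8,
):
    """Simulate a full Experiment-1 dataset; returns a tidy DataFrame.

    Defaults to the analyzed sample size (55 subjects x 128 trials).
    """
    pop = pop or PopulationParams()
    records = []
    for i, ss in enumerate(_subject_streams(seed, n_subjects)):
        r_params, r_design, r_trials = [np.random.default_rng(s) for s in ss.spawn(3)]
        params = sample_subject(pop, r_params)
        design = build_exp1_design(r_design, repetitions=repetitions)
        records.extend(simulate_subject(i, design, params, r_trials))
    return records_to_frame(records)


def simulate_exp2(
    n_subjects: int = 86,
    pop: Optional[PopulationParams] = None,
    seed: int = 0,
    repetitions: int = 3,
):
    """Simulate a full Experiment-2 dataset; returns a tidy DataFrame.

    Subjects alternate between the two color assignments (even indices:
    yellow test dots / blue response dots; odd: the reverse), giving the
    half/half between-subject counterbalance.
    """
    pop = pop or PopulationParams()
    records = []
    for i, ss in enumerate(_subject_streams(seed, n_subjects)):
        r_params, r_design, r_trials = [np.random.default_rng(s) for s in ss.spawn(3)]
        params = sample_subject(pop, r_params)
        assignment = "test-yellow" if i % 2 == 0 else "test-blue"
        design = build_exp2_design(r_design, assignment, repetitions=repetitions)
        records.extend(simulate_subject(i, design, params, r_trials))
    return records_to_frame(records)
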