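"""Synthetic SAT subjects driven by feature-based reinforcement learning.

The SAT requires no choices, so the agent is a Rescorla-Wagner feature
learner whose state shapes response vigour and explicit probability
ratings.  Each of the four cue features (blue, red, animal, object)
carries a weight; the value of a compound cue is the mean of its two
feature weights, keeping values interpretable as reward-probability
estimates in [0, 1].  After each trial both presented feature weights move
by ``alpha * (reward - value)``.

Aberrant salience attribution is modelled as a stable individual trait: a
per-subject offset ``d`` (drawn with SD ``kappa``) is added antisymmetrically
to the values of the two task-irrelevant feature levels when the subject
produces explicit ratings, creating spurious value differences between
features with identical (50%) reward probability.

Behavioural output per trial: RT = base RT - beta_rt * value + Gaussian
noise, truncated to the response window; omissions and premature responses
are injected at fixed per-trial rates.  At the end of each block the agent
rates each cue type on a 100 mm visual-analogue scale tracking its learned
value plus the aberrant offset plus rating noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .task import (
    ALL_VERSIONS,
    CUE_TYPES,
    FEATURES,
    PREMATURE_CUTOFF_MS,
    CalibrationProfile,
    CueStimulus,
    TaskVersion,
    TrialResult,
    TrialSchedule,
    build_schedule,
    compute_payout,
)

__all__ = [
    "AgentParams",
    "SubjectLog",
    "rw_update",
    "cue_value",
    "emit_behavior",
    "simulate_cohort",
]

_MAX_TRUNCATION_DRAWS = 100


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters for one synthetic subject.

    alpha : learning rate of the delta rule, in [0, 1].
    kappa : SD of the per-subject aberrant offset added to the values of
        the irrelevant feature levels (value units, i.e. probability).
    beta_rt_ms : RT speeding per unit of cue value (ms).
    base_rt_ms : RT at zero cue value (ms).
    rt_noise_ms : SD of Gaussian trial-to-trial RT noise (ms).
    rating_noise_mm : SD of Gaussian rating noise on the 100 mm VAS.
    omission_rate, premature_rate : per-trial probabilities.
    """

    alpha: float = 0.25
    kappa: float = 0.14
    beta_rt_ms: float = 20.0
    base_rt_ms: float = 300.0
    rt_noise_ms: float = 30.0
    rating_noise_mm: float = 10.0
    omission_rate: float = 0.070
    premature_rate: float = 0.042

    def __post_init__(self) -> None:
        for name in ("alpha", "omission_rate", "premature_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("kappa", "rt_noise_ms", "rating_noise_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.base_rt_ms <= 0:
            raise ValueError("base_rt_ms must be positive")


def cue_value(weights: dict[str, float], cue: CueStimulus) -> float:
    """Compound-cue value: mean of the two presented feature weights."""
    return 0.5 * (weights[cue.color] + weights[cue.shape])


def rw_update(
    weights: dict[str, float],
    cue: CueStimulus,
    reward: float,
    alpha: float,
) -> dict[str, float]:
    """One delta-rule step; returns a new weight dict.

    Both presented features move by ``alpha * (reward - V(cue))`` where
    V(cue) is the mean of their weights.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not all(np.isfinite(list(weights.values()))):
        raise ValueError("weights must be finite")
    delta = alpha * (reward - cue_value(weights, cue))
    out = dict(weights)
    out[cue.color] += delta
    out[cue.shape] += delta
    return out


@dataclass
class SubjectLog:
    """Complete behavioural record of one (synthetic) subject."""

    subject_id: str
    version: TaskVersion
    calibration: CalibrationProfile
    schedule: TrialSchedule = field(repr=False)
    trial_results: list[list[TrialResult]] = field(repr=False)
    vas_ratings: dict[tuple[int, str], float]  # (block, cue_type) -> mm
    aberrant_offset: float = 0.0
    params: Optional[AgentParams] = None
    seed: Optional[int] = None

    def ratings_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject_id, "block": b, "cue_type": ct, "rating_mm": r}
            for (b, ct), r in sorted(self.vas_ratings.items())
        ]
        return pd.DataFrame(rows)

    def events_frame(self, block: int) -> pd.DataFrame:
        """Per-trial table for one block (1-based), BIDS-events style.

        ``onset`` is the cue onset in seconds from run start; ``rt_ms`` is
        measured from probe onset and ``response_time`` (s) from cue onset.
        """
        trials = self.schedule.blocks[block - 1]
        results = self.trial_results[block - 1]
        rows = []
        for t, r in zip(trials, results):
            resp = None if r.rt_ms is None else t.probe_delay_s + r.rt_ms / 1000.0
            rows.append(
                {
                    "onset": t.cue_onset_s,
                    "duration": t.probe_delay_s,  # cue alone before the probe
                    "trial_type": t.cue.cue_type,
                    "picture_id": t.cue.picture_id,
                    "rewarded": int(t.rewarded),
                    "probe_delay": t.probe_delay_s,
                    "probe_duration": t.probe_duration_ms / 1000.0,
                    "response_time": resp,
                    "rt_ms": r.rt_ms,
                    "classification": r.classification,
                    "payout": r.payout_pence,
                    "feedback": r.feedback,
                }
            )
        return pd.DataFrame(rows)


def _draw_rt(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Gaussian RT truncated to [lo, hi] by resampling, then clamping."""
    for _ in range(_MAX_TRUNCATION_DRAWS):
        rt = rng.normal(mean, sd)
        if lo <= rt <= hi:
            return float(rt)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def emit_behavior(
    schedule: TrialSchedule,
    params: AgentParams,
    calibration: CalibrationProfile,
    seed: int,
    subject_id: str = "sim",
    aberrant_offset: Optional[float] = None,
) -> SubjectLog:
    """Simulate one subject playing the given schedule.

    ``aberrant_offset`` overrides the subject's aberrant trait ``d``
    (otherwise drawn as N(0, kappa^2)); the first irrelevant level (in
    canonical order) receives +d/2 and the second -d/2 at rating time.
    """
    rng = np.random.default_rng(seed)
    d = float(rng.normal(0.0, params.kappa)) if aberrant_offset is None else float(aberrant_offset)
    version = schedule.version
    level_a, level_b = version.irrelevant_levels
    weights = {f: 0.0 for f in FEATURES}

    results: list[list[TrialResult]] = []
    ratings: dict[tuple[int, str], float] = {}
    for block in schedule.blocks:
        block_results = []
        for trial in block:
            v = cue_value(weights, trial.cue)
            u = rng.random()
            if u < params.omission_rate:
                result = compute_payout(trial, None, calibration)
            elif u < params.omission_rate + params.premature_rate:
                # response somewhere between 0.3 s post-cue and 100 ms post-probe
                resp_from_cue = rng.uniform(0.3, trial.probe_delay_s + 0.1)
                rt = (resp_from_cue - trial.probe_delay_s) * 1000.0
                rt = min(rt, PREMATURE_CUTOFF_MS - 1.0)
                payout = 5 if trial.rewarded else 0
                feedback = "TooEarly" if trial.rewarded else "NoMoney"
                result = TrialResult(rt, "premature", payout, feedback)
            else:
                rt = _draw_rt(
                    rng,
                    params.base_rt_ms - params.beta_rt_ms * v,
                    params.rt_noise_ms,
                    PREMATURE_CUTOFF_MS,
                    trial.probe_duration_ms,
                )
                result = compute_payout(trial, rt, calibration)
            block_results.append(result)
            weights = rw_update(weights, trial.cue, float(trial.rewarded), params.alpha)
        results.append(block_results)

        b = block[0].block
        for cue_type in CUE_TYPES:
            color, shape = cue_type.split("_")
            cue = CueStimulus(color, shape, 1)
            v = cue_value(weights, cue)
            level = cue.feature_on(version.irrelevant_dimension)
            offset = 0.5 * d if level == level_a else -0.5 * d
            noise = rng.normal(0.0, params.rating_noise_mm) if params.rating_noise_mm else 0.0
            ratings[(b, cue_type)] = float(np.clip(100.0 * (v + offset) + noise, 0.0, 100.0))

    return SubjectLog(
        subject_id=subject_id,
        version=version,
        calibration=calibration,
        schedule=schedule,
        trial_results=results,
        vas_ratings=ratings,
        aberrant_offset=d,
        params=params,
        seed=seed,
    )


def simulate_cohort(
    n: int,
    params: Union[AgentParams, Sequence[AgentParams]] = AgentParams(),
    master_seed: int = 0,
    mean_rt_population: tuple[float, float] = (300.0, 30.0),
    sdf_population: tuple[float, float] = (20.0, 5.0),
    version: Optional[TaskVersion] = None,
    aberrant_offsets: Optional[Sequence[float]] = None,
) -> list[SubjectLog]:
    """Simulate ``n`` independent subjects.

    Calibration profiles are drawn per subject from truncated-normal
    population distributions of practice mean RT and SDF.  Task versions
    are counterbalanced across the four variants unless one is given.
    ``params`` may be a single AgentParams applied to all subjects or one
    per subject; ``aberrant_offsets`` optionally fixes each subject's
    aberrant trait (useful for parameter-recovery studies).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(params, AgentParams):
        params_list = [params] * n
    else:
        params_list = list(params)
        if len(params_list) != n:
            raise ValueError("need one AgentParams per subject")
    if aberrant_offsets is not None and len(aberrant_offsets) != n:
        raise ValueError("need one aberrant offset per subject")

    root = np.random.SeedSequence(master_seed)
    pop_ss, *subject_ss = root.spawn(n + 1)
    rng_pop = np.random.default_rng(pop_ss)

    logs = []
    for i, ss in enumerate(subject_ss):
        mean_rt = float(max(150.0, rng_pop.normal(*mean_rt_population)))
        sdf = float(max(5.0, rng_pop.normal(*sdf_population)))
        calib = CalibrationProfile(mean_rt_ms=mean_rt, sdf_ms=sdf)
        ver = version if version is not None else ALL_VERSIONS[i % 4]
        sched_seed, behav_seed = (int(s) % (2**31) for s in ss.generate_state(2))
        schedule = build_schedule(ver, sched_seed, calib)
        logs.append(
            emit_behavior(
                schedule,
                params_list[i],
                calib,
                behav_seed,
                subject_id=f"sub-{i + 1:02d}",
                aberrant_offset=None if aberrant_offsets is None else aberrant_offsets[i],
            )
        )
    return logs
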