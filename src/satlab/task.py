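"""Salience Attribution Test (SAT) task engine.

The SAT is a speeded-response probabilistic reward game.  Compound cue
stimuli vary along two visual dimensions, colour (blue / red) and shape
(animal / household object).  One dimension is task-relevant: one of its
levels signals reward on 87.5% of its trials (28/32), the other on 12.5%
(4/32).  The other dimension is task-irrelevant: both of its levels are
rewarded on exactly 50% of trials.  Payout on rewarded trials scales with
response speed relative to a per-subject calibration obtained from a
practice session.

This module generates trial schedules, computes per-subject calibration
profiles, and scores individual trials (payout + feedback category).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "COLORS",
    "SHAPES",
    "FEATURES",
    "CUE_TYPES",
    "ITI_S",
    "CUE_ONSET_DELAY_S",
    "FEEDBACK_DELAY_S",
    "FEEDBACK_DURATION_S",
    "PROBE_DELAY_RANGE_S",
    "TRIALS_PER_BLOCK",
    "N_BLOCKS",
    "InsufficientDataError",
    "DegenerateCalibrationError",
    "TaskVersion",
    "CueStimulus",
    "TrialSpec",
    "TrialSchedule",
    "CalibrationProfile",
    "TrialResult",
    "calibrate",
    "build_schedule",
    "compute_payout",
]

COLORS = ("blue", "red")
SHAPES = ("animal", "object")
FEATURES = COLORS + SHAPES
#: canonical cue-type order used everywhere (schedules, designs, contrasts)
CUE_TYPES = ("blue_animal", "blue_object", "red_animal", "red_object")

ITI_S = 9.25            # constant trial-to-trial onset spacing
CUE_ONSET_DELAY_S = 1.0  # cue appears 1 s after trial (fixation) onset
FEEDBACK_DELAY_S = 2.25  # feedback 2.25 s after probe onset
FEEDBACK_DURATION_S = 1.5
PROBE_DELAY_RANGE_S = (3.5, 4.5)  # probe onset relative to cue onset
TRIALS_PER_BLOCK = 64
N_BLOCKS = 3
PICTURES_PER_CUE = 16
HIGH_REWARDED_PER_CUE = 14  # of 16 -> 87.5% per high-probability feature
LOW_REWARDED_PER_CUE = 2    # of 16 -> 12.5%
PREMATURE_CUTOFF_MS = 100.0  # responses faster than this after probe onset


class InsufficientDataError(ValueError):
    """Too few valid practice trials to calibrate."""


class DegenerateCalibrationError(ValueError):
    """The ten fastest practice trials have zero spread (SDF = 0)."""


@dataclass(frozen=True)
class TaskVersion:
    """One of the four counterbalanced task versions.

    ``high_feature`` is the level of the task-relevant dimension rewarded
    with high (87.5%) probability; the other level of that dimension is
    rewarded with low (12.5%) probability, and both levels of the other
    (irrelevant) dimension are rewarded at 50%.
    """

    relevant_dimension: str  # "color" or "shape"
    high_feature: str

    def __post_init__(self) -> None:
        if self.relevant_dimension not in ("color", "shape"):
            raise ValueError(f"unknown dimension {self.relevant_dimension!r}")
        pool = COLORS if self.relevant_dimension == "color" else SHAPES
        if self.high_feature not in pool:
            raise ValueError(
                f"high feature {self.high_feature!r} does not belong to the "
                f"{self.relevant_dimension} dimension"
            )

    @classmethod
    def from_high_feature(cls, feature: str) -> "TaskVersion":
        if feature in COLORS:
            return cls("color", feature)
        if feature in SHAPES:
            return cls("shape", feature)
        raise ValueError(f"unknown feature {feature!r}")

    @property
    def low_feature(self) -> str:
        pool = COLORS if self.relevant_dimension == "color" else SHAPES
        return pool[0] if pool[1] == self.high_feature else pool[1]

    @property
    def irrelevant_dimension(self) -> str:
        return "shape" if self.relevant_dimension == "color" else "color"

    @property
    def irrelevant_levels(self) -> tuple[str, str]:
        """The two 50%-rewarded levels, in canonical order."""
        return SHAPES if self.relevant_dimension == "color" else COLORS


#: all four counterbalanced versions, canonical order
ALL_VERSIONS = tuple(TaskVersion.from_high_feature(f) for f in FEATURES)


@dataclass(frozen=True)
class CueStimulus:
    color: str
    shape: str
    picture_id: int  # 1..16 within its cue set

    def __post_init__(self) -> None:
        if self.color not in COLORS or self.shape not in SHAPES:
            raise ValueError(f"invalid cue features ({self.color}, {self.shape})")
        if not 1 <= self.picture_id <= PICTURES_PER_CUE:
            raise ValueError(f"picture_id {self.picture_id} outside 1..16")

    @property
    def cue_type(self) -> str:
        return f"{self.color}_{self.shape}"

    @property
    def features(self) -> tuple[str, str]:
        return (self.color, self.shape)

    def feature_on(self, dimension: str) -> str:
        return self.color if dimension == "color" else self.shape


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial; times in seconds from run start unless noted."""

    block: int
    index_in_block: int  # 1-based
    cue: CueStimulus
    rewarded: bool
    probe_delay_s: float     # probe onset relative to cue onset
    probe_duration_ms: float
    onset_s: float           # trial (fixation) onset

    @property
    def cue_onset_s(self) -> float:
        return self.onset_s + CUE_ONSET_DELAY_S

    @property
    def probe_onset_s(self) -> float:
        return self.cue_onset_s + self.probe_delay_s

    @property
    def outcome_onset_s(self) -> float:
        return self.probe_onset_s + FEEDBACK_DELAY_S


@dataclass
class CalibrationProfile:
    """Per-subject timing calibration from the practice session.

    ``mean_rt_ms`` is the mean over all valid practice trials; ``sdf_ms``
    is the sample standard deviation of the ten fastest.  Both scale the
    payout and bound the probe duration.
    """

    mean_rt_ms: float
    sdf_ms: float

    def __post_init__(self) -> None:
        if not self.mean_rt_ms > 0:
            raise ValueError("mean_rt_ms must be positive")
        if not self.sdf_ms > 0:
            raise DegenerateCalibrationError("sdf_ms must be positive")

    @property
    def probe_duration_range_ms(self) -> tuple[float, float]:
        """Probe duration limits: 2 SDFs either side of the practice mean."""
        return (self.mean_rt_ms - 2 * self.sdf_ms, self.mean_rt_ms + 2 * self.sdf_ms)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial.

    ``rt_ms`` is measured from probe onset; it is ``None`` for omissions and
    may be negative for responses emitted before the probe appeared (stored
    by the simulator; classified premature).
    """

    rt_ms: Optional[float]
    classification: str  # valid | premature | missed | omitted
    payout_pence: int
    feedback: str  # Missed | TooEarly | Hit | Quick | VeryQuick | NoMoney


def calibrate(practice_rts: Sequence[Optional[float]]) -> CalibrationProfile:
    """Compute the calibration profile from practice reaction times.

    Non-responses (``None``/NaN) and premature responses (< 100 ms) are
    discarded; at least 10 valid RTs must remain.  The mean is taken over
    all valid trials and the SDF is the sample SD (n-1 denominator) of the
    ten fastest.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 valid practice RTs.
    DegenerateCalibrationError
        The ten fastest RTs are all identical (SDF = 0).
    """
    rts = np.asarray(
        [r for r in practice_rts if r is not None and np.isfinite(r)], dtype=float
    )
    rts = rts[rts >= PREMATURE_CUTOFF_MS]
    if rts.size < 10:
        raise InsufficientDataError(
            f"need at least 10 valid practice RTs, got {rts.size}"
        )
    fastest = np.sort(rts)[:10]
    sdf = float(np.std(fastest, ddof=1))
    if sdf == 0.0:
        raise DegenerateCalibrationError("ten fastest practice RTs are identical")
    return CalibrationProfile(mean_rt_ms=float(np.mean(rts)), sdf_ms=sdf)


@dataclass
class TrialSchedule:
    """Full 3-block x 64-trial design for one subject."""

    version: TaskVersion
    blocks: list[list[TrialSpec]] = field(repr=False)
    seed: int = 0

    def all_trials(self):
        for block in self.blocks:
            yield from block

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _rewarded_count(version: TaskVersion, cue_type: str) -> int:
    color, shape = cue_type.split("_")
    relevant = color if version.relevant_dimension == "color" else shape
    return HIGH_REWARDED_PER_CUE if relevant == version.high_feature else LOW_REWARDED_PER_CUE


def build_schedule(
    version: TaskVersion,
    seed: int,
    calibration: CalibrationProfile,
    n_blocks: int = N_BLOCKS,
) -> TrialSchedule:
    """Generate a trial schedule honouring the SAT reward contingencies.

    Per block, each of the 64 stimuli (4 cue types x 16 pictures) is
    presented once; reward flags are drawn without replacement within each
    cue type (14/16 for cue types bearing the high-probability feature,
    2/16 otherwise), the trial order is uniformly shuffled, the probe delay
    is uniform on [3.5, 4.5] s from cue onset and the probe duration is
    uniform within 2 SDFs of the practice mean RT.  Trial onsets are spaced
    by the constant 9.25 s inter-trial interval.

    Reproducibility: a master seed feeds three named substreams (schedule
    order/reward flags, probe delays, probe durations), each spawning one
    child per block.
    """
    if not isinstance(version, TaskVersion):
        raise TypeError("version must be a TaskVersion")
    root = np.random.SeedSequence(seed)
    sched_ss, delay_ss, dur_ss = root.spawn(3)
    lo_dur, hi_dur = calibration.probe_duration_range_ms

    blocks: list[list[TrialSpec]] = []
    for b, (b_sched, b_delay, b_dur) in enumerate(
        zip(sched_ss.spawn(n_blocks), delay_ss.spawn(n_blocks), dur_ss.spawn(n_blocks)),
        start=1,
    ):
        rng = np.random.default_rng(b_sched)
        rng_delay = np.random.default_rng(b_delay)
        rng_dur = np.random.default_rng(b_dur)
        pool: list[tuple[CueStimulus, bool]] = []
        for cue_type in CUE_TYPES:
            color, shape = cue_type.split("_")
            k = _rewarded_count(version, cue_type)
            flags = np.zeros(PICTURES_PER_CUE, dtype=bool)
            flags[rng.choice(PICTURES_PER_CUE, size=k, replace=False)] = True
            for pic in range(1, PICTURES_PER_CUE + 1):
                pool.append((CueStimulus(color, shape, pic), bool(flags[pic - 1])))
        order = rng.permutation(len(pool))
        trials = []
        for i, j in enumerate(order):
            cue, rewarded = pool[j]
            trials.append(
                TrialSpec(
                    block=b,
                    index_in_block=i + 1,
                    cue=cue,
                    rewarded=rewarded,
                    probe_delay_s=float(rng_delay.uniform(*PROBE_DELAY_RANGE_S)),
                    probe_duration_ms=float(rng_dur.uniform(lo_dur, hi_dur)),
                    onset_s=i * ITI_S,
                )
            )
        blocks.append(trials)
    return TrialSchedule(version=version, blocks=blocks, seed=seed)


def _classify(rt_ms: Optional[float], probe_duration_ms: float) -> str:
    if rt_ms is None:
        return "omitted"
    if rt_ms < PREMATURE_CUTOFF_MS:
        return "premature"
    if rt_ms > probe_duration_ms:
        return "missed"
    return "valid"


def compute_payout(
    trial: TrialSpec,
    rt_ms: Optional[float],
    calibration: CalibrationProfile,
) -> TrialResult:
    """Score one trial: classification, payout in pence, feedback category.

    Non-rewarded trials pay nothing ("Sorry - no money available")
    regardless of speed.  On rewarded trials, misses and omissions pay 5p,
    premature responses (< 100 ms after probe onset) pay 5p, responses
    slower than the practice mean pay 10p ("Hit - good"), and faster
    responses pay ``X = 10 + 90 * (mean RT - RT) / (3 * SDF)`` pence capped
    at 100, labelled "Quick" below 1.5 SDFs of advantage and "Very quick"
    at or above.  X is rounded half-up to whole pence.
    """
    if rt_ms is not None and rt_ms < 0:
        raise ValueError("rt_ms must be non-negative (measured from probe onset)")
    cls = _classify(rt_ms, trial.probe_duration_ms)
    if not trial.rewarded:
        return TrialResult(rt_ms, cls, 0, "NoMoney")
    if cls in ("omitted", "missed"):
        return TrialResult(rt_ms, cls, 5, "Missed")
    if cls == "premature":
        return TrialResult(rt_ms, cls, 5, "TooEarly")
    advantage = calibration.mean_rt_ms - rt_ms
    if advantage <= 0:
        return TrialResult(rt_ms, cls, 10, "Hit")
    x = 10.0 + 90.0 * advantage / (3.0 * calibration.sdf_ms)
    payout = min(100, int(math.floor(x + 0.5)))
    feedback = "Quick" if advantage < 1.5 * calibration.sdf_ms else "VeryQuick"
    return TrialResult(rt_ms, cls, payout, feedback)
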