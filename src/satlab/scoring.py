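"""Behavioural outcome measures for the SAT.

Four learning measures are computed per block and averaged:

* explicit adaptive  — VAS rating (mm) for the high-probability relevant
  feature minus the low-probability one;
* explicit aberrant  — absolute VAS rating difference (mm) between the two
  task-irrelevant levels (both rewarded at 50%);
* implicit adaptive  — RT speeding (ms): mean valid RT on low- minus
  high-probability trials;
* implicit aberrant  — absolute mean-RT difference (ms) between the two
  irrelevant levels.

A feature level's rating is the mean of the two cue-type ratings
containing it (the VAS probes cue types, not features).  Implicit measures
use valid responses only.  The module also provides the per-block
subjective relabeling of the irrelevant levels (which defines the aberrant
fMRI contrast), binary cue-outcome entropy, leave-one-out outlier
exclusion, earnings summaries, and simple cohort statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .task import TaskVersion
from .agents import SubjectLog

__all__ = [
    "LearningMeasures",
    "EarningsSummary",
    "ExclusionReport",
    "score_subject",
    "subjective_relabel",
    "outcome_entropy",
    "exclude_outliers",
    "summarize_earnings",
    "cohort_stats",
]

MEASURES = (
    "adaptive_explicit_mm",
    "aberrant_explicit_mm",
    "adaptive_implicit_ms",
    "aberrant_implicit_ms",
)


@dataclass(eq=False)
class LearningMeasures:
    """Per-block and averaged reward-learning measures for one subject."""

    subject_id: str
    per_block: pd.DataFrame = field(repr=False)  # index block, cols MEASURES + signed
    relabel: dict[int, dict] = field(repr=False)  # block -> relabel mapping

    @property
    def means(self) -> pd.Series:
        """Across-block means (NaN-aware) of the four measures."""
        return self.per_block[list(MEASURES)].mean()

    def __getattr__(self, name):
        if name in MEASURES:
            return float(self.means[name])
        raise AttributeError(name)


@dataclass(eq=False)
class EarningsSummary:
    subject_id: str
    money_per_rewarded_trial: pd.DataFrame  # index block, columns conditions
    total_per_block: pd.Series
    error_counts: pd.DataFrame  # block x cue_type, premature & omission


def outcome_entropy(p):
    """Binary outcome entropy H(p) = -(p ln p + (1-p) ln(1-p)), in nats.

    The reward uncertainty of a cue: 0.377 nats for the 87.5%/12.5%
    relevant features, maximal 0.693 nats for the 50% irrelevant ones.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    h = -(special.xlogy(arr, arr) + special.xlogy(1.0 - arr, 1.0 - arr))
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


def _level_rating(ratings: dict, block: int, version: TaskVersion, dimension: str, level: str) -> float:
    """Mean rating over the two cue types containing `level` of `dimension`."""
    from .task import CUE_TYPES

    vals = []
    for ct in CUE_TYPES:
        color, shape = ct.split("_")
        if (color if dimension == "color" else shape) == level:
            vals.append(ratings[(block, ct)])
    return float(np.mean(vals))


def subjective_relabel(log: SubjectLog, block: int) -> dict:
    """Assign the irrelevant levels to subjective high/low for one block.

    The level with the higher mean VAS rating becomes 'subjective-high'.
    Exact ties are broken toward the first level in canonical order and
    flagged with ``tie=True``.
    """
    version = log.version
    dim = version.irrelevant_dimension
    level_a, level_b = version.irrelevant_levels
    missing = [
        ct for ct in ("blue_animal", "blue_object", "red_animal", "red_object")
        if (block, ct) not in log.vas_ratings
    ]
    if missing:
        raise ValueError(f"block {block} missing ratings for {missing}")
    ra = _level_rating(log.vas_ratings, block, version, dim, level_a)
    rb = _level_rating(log.vas_ratings, block, version, dim, level_b)
    if ra >= rb:
        high, low = level_a, level_b
    else:
        high, low = level_b, level_a
    return {
        "subjective_high": high,
        "subjective_low": low,
        "tie": bool(ra == rb),
        "signed_difference_mm": ra - rb,  # level_a minus level_b
    }


def _mean_valid_rt(events: pd.DataFrame, mask: pd.Series) -> float:
    sel = events[mask & (events["classification"] == "valid")]
    return float(sel["rt_ms"].mean()) if len(sel) else float("nan")


def score_subject(log: SubjectLog) -> LearningMeasures:
    """Compute the four learning measures per block plus relabel directions.

    Implicit measures use valid RTs only; a block lacking valid responses
    in a required condition yields NaN for that measure (flagged absent).
    """
    version = log.version
    rel_dim, irr_dim = version.relevant_dimension, version.irrelevant_dimension
    level_a, level_b = version.irrelevant_levels
    rows = []
    relabels = {}
    for b in range(1, log.schedule.n_blocks + 1):
        relabels[b] = subjective_relabel(log, b)
        r_high = _level_rating(log.vas_ratings, b, version, rel_dim, version.high_feature)
        r_low = _level_rating(log.vas_ratings, b, version, rel_dim, version.low_feature)
        r_a = _level_rating(log.vas_ratings, b, version, irr_dim, level_a)
        r_b = _level_rating(log.vas_ratings, b, version, irr_dim, level_b)

        ev = log.events_frame(b)
        feature = ev["trial_type"].str.split("_", expand=True)
        ev = ev.assign(color=feature[0], shape=feature[1])
        rel_col = "color" if rel_dim == "color" else "shape"
        irr_col = "color" if irr_dim == "color" else "shape"
        rt_high = _mean_valid_rt(ev, ev[rel_col] == version.high_feature)
        rt_low = _mean_valid_rt(ev, ev[rel_col] == version.low_feature)
        rt_a = _mean_valid_rt(ev, ev[irr_col] == level_a)
        rt_b = _mean_valid_rt(ev, ev[irr_col] == level_b)

        rows.append(
            {
                "block": b,
                "adaptive_explicit_mm": r_high - r_low,
                "aberrant_explicit_mm": abs(r_a - r_b),
                "aberrant_explicit_signed_mm": r_a - r_b,
                "adaptive_implicit_ms": rt_low - rt_high,
                "aberrant_implicit_ms": abs(rt_a - rt_b),
            }
        )
    per_block = pd.DataFrame(rows).set_index("block")
    return LearningMeasures(subject_id=log.subject_id, per_block=per_block, relabel=relabels)


@dataclass(eq=False)
class ExclusionReport:
    retained: np.ndarray  # indices (or ids) kept
    excluded: np.ndarray
    z_scores: np.ndarray  # leave-one-out z per subject


def exclude_outliers(
    values: Sequence[float],
    threshold_sd: float = 3.5,
    ids: Optional[Sequence] = None,
) -> ExclusionReport:
    """Leave-one-out outlier exclusion.

    Subject i is excluded when its value lies more than ``threshold_sd``
    standard deviations from the mean of the *remaining* subjects (SD also
    computed leaving i out).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    idx = np.asarray(ids if ids is not None else np.arange(x.size))
    z = np.empty(x.size)
    for i in range(x.size):
        rest = np.delete(x, i)
        sd = rest.std(ddof=1)
        z[i] = (x[i] - rest.mean()) / sd if sd > 0 else (0.0 if x[i] == rest.mean() else math.inf)
    out = np.abs(z) > threshold_sd
    return ExclusionReport(retained=idx[~out], excluded=idx[out], z_scores=z)


def summarize_earnings(log: SubjectLog) -> EarningsSummary:
    """Money per rewarded trial by condition, block totals, error tallies."""
    version = log.version
    rel_dim = version.relevant_dimension
    irr_dim = version.irrelevant_dimension
    level_a, level_b = version.irrelevant_levels
    per_cond_rows, totals = [], {}
    counts_rows = []
    for b in range(1, log.schedule.n_blocks + 1):
        ev = log.events_frame(b)
        feature = ev["trial_type"].str.split("_", expand=True)
        ev = ev.assign(color=feature[0], shape=feature[1])
        rel_col = "color" if rel_dim == "color" else "shape"
        irr_col = "color" if irr_dim == "color" else "shape"
        rewarded = ev[ev["rewarded"] == 1]
        per_cond_rows.append(
            {
                "block": b,
                "high_relevant": rewarded.loc[
                    rewarded[rel_col] == version.high_feature, "payout"
                ].mean(),
                "low_relevant": rewarded.loc[
                    rewarded[rel_col] == version.low_feature, "payout"
                ].mean(),
                level_a: rewarded.loc[rewarded[irr_col] == level_a, "payout"].mean(),
                level_b: rewarded.loc[rewarded[irr_col] == level_b, "payout"].mean(),
            }
        )
        totals[b] = int(ev["payout"].sum())
        for ct, grp in ev.groupby("trial_type"):
            counts_rows.append(
                {
                    "block": b,
                    "cue_type": ct,
                    "premature": int((grp["classification"] == "premature").sum()),
                    "omission": int((grp["classification"] == "omitted").sum()),
                }
            )
    return EarningsSummary(
        subject_id=log.subject_id,
        money_per_rewarded_trial=pd.DataFrame(per_cond_rows).set_index("block"),
        total_per_block=pd.Series(totals, name="total_pence"),
        error_counts=pd.DataFrame(counts_rows).set_index(["block", "cue_type"]),
    )


def cohort_stats(measures: Sequence[LearningMeasures]) -> dict[str, pd.DataFrame]:
    """Cohort-level inferential statistics on the learning measures.

    Returns three tables: one-sample t-tests of each averaged measure
    against zero (zero-variance measures flagged, no test), Pearson
    correlations between the averaged measures, and paired t-tests between
    blocks for each measure.
    """
    if len(measures) < 3:
        raise ValueError("need at least 3 subjects")
    table = pd.DataFrame({m.subject_id: m.means for m in measures}).T

    rows = []
    for name in MEASURES:
        x = table[name].dropna().to_numpy()
        if x.size < 3 or np.std(x, ddof=1) == 0:
            rows.append({"measure": name, "n": x.size, "mean": x.mean() if x.size else np.nan,
                         "t": np.nan, "df": np.nan, "p": np.nan, "flag": "zero_variance"})
            continue
        t, p = stats.ttest_1samp(x, 0.0)
        rows.append({"measure": name, "n": x.size, "mean": float(x.mean()),
                     "t": float(t), "df": x.size - 1, "p": float(p), "flag": ""})
    one_sample = pd.DataFrame(rows).set_index("measure")

    corr_r = pd.DataFrame(index=MEASURES, columns=MEASURES, dtype=float)
    for a in MEASURES:
        for b in MEASURES:
            sub = table[[a, b]].dropna()
            if a == b:
                corr_r.loc[a, b] = 1.0
            elif sub[a].std() == 0 or sub[b].std() == 0:
                corr_r.loc[a, b] = np.nan
            else:
                corr_r.loc[a, b] = float(stats.pearsonr(sub[a], sub[b])[0])

    pair_rows = []
    blocks = sorted(measures[0].per_block.index)
    for name in MEASURES:
        for i, bi in enumerate(blocks):
            for bj in blocks[i + 1:]:
                xi = np.array([m.per_block.loc[bi, name] for m in measures])
                xj = np.array([m.per_block.loc[bj, name] for m in measures])
                ok = np.isfinite(xi) & np.isfinite(xj)
                diff = xi[ok] - xj[ok]
                if ok.sum() < 3 or np.std(diff, ddof=1) == 0:
                    t = p = np.nan
                else:
                    t, p = stats.ttest_rel(xi[ok], xj[ok])
                pair_rows.append({"measure": name, "block_a": bi, "block_b": bj,
                                  "n": int(ok.sum()), "t": float(t) if t == t else np.nan,
                                  "p": float(p) if p == p else np.nan})
    block_pairs = pd.DataFrame(pair_rows)
    return {"one_sample": one_sample, "correlations": corr_r, "block_pairs": block_pairs}
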