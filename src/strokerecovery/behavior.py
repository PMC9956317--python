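"""Sensorimotor readouts, recovery rates and good/poor dichotomization.

Three readouts quantify the post-stroke deficit: the percentage of foot
faults on the grid-walk test, the walking speed on the rotating beam, and the
number of hindlimb drops on the beam.  Per animal, the ordinary-least-squares
slope of each readout over post-stroke days 3-14 serves as a surrogate
"recovery rate"; the cohort median of each readout's slopes splits the stroke
animals into good and poor recoverers, and a 2-of-3 vote across readouts
yields the final label (conflicting or incomplete votes -> neutral).

Recovery scores normalize each deficit trajectory to 0% at day 3 (maximal
deficit) and 100% at the time-matched sham level, giving curves comparable
across readouts and animals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

from .errors import NoStepsError

__all__ = [
    "READOUTS",
    "foot_fault_pct",
    "beam_speed",
    "daily_readouts",
    "SlopeResult",
    "recovery_rate",
    "RecoveryClassifier",
    "classify_cohort",
    "sham_reference",
    "recovery_scores",
    "WardResult",
    "ward_cluster",
]

logger = logging.getLogger(__name__)

READOUTS = ("foot_fault_pct", "speed_cm_s", "hl_drops")

#: Readouts where a more negative slope (fewer faults/drops over time) is better.
_GOOD_IS_NEGATIVE = {"foot_fault_pct": True, "speed_cm_s": False, "hl_drops": True}


def foot_fault_pct(foot_faults: int, clean_steps: int) -> float:
    """Percentage of foot faults: ``100 * f / (f + c)``.

    Parameters
    ----------
    foot_faults : int
        Steps counted as faults (missed, slipped, or unsupported).
    clean_steps : int
        Non-fault steps.

    Raises
    ------
    NoStepsError
        If the animal took no steps at all; a silent 0 would look like a
        perfect trial.
    """
    if foot_faults < 0 or clean_steps < 0:
        raise ValueError("step counts must be non-negative")
    total = foot_faults + clean_steps
    if total == 0:
        raise NoStepsError("no steps recorded in this trial")
    return 100.0 * foot_faults / total


def beam_speed(distance_cm: float, duration_s: float) -> float:
    """Walking speed on the rotating beam in cm/s."""
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    if distance_cm < 0:
        raise ValueError(f"distance must be non-negative, got {distance_cm}")
    return distance_cm / duration_s


def daily_readouts(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-animal, per-day readouts averaged over the day's trials.

    Parameters
    ----------
    trials : DataFrame
        Trial records with columns ``animal_id, cohort, day, test, trial,
        duration_s, distance_cm, hindlimb_drops, steps, foot_faults``.

    Returns
    -------
    DataFrame
        Long format ``animal_id, cohort, readout, day, value``; a day with no
        usable trials for a readout is simply absent (never imputed).
    """
    cohort_counts = trials.groupby("animal_id")["cohort"].nunique()
    bad = cohort_counts[cohort_counts > 1]
    if len(bad):
        raise ValueError(f"conflicting cohort labels for animals: {list(bad.index)}")

    rows = []
    grid = trials[trials["test"] == "grid_walk"]
    for (animal, day), grp in grid.groupby(["animal_id", "day"], sort=True):
        vals = []
        for _, t in grp.iterrows():
            faults = int(t["foot_faults"])
            steps = int(t["steps"])
            vals.append(foot_fault_pct(faults, steps - faults))
        rows.append((animal, grp["cohort"].iloc[0], "foot_fault_pct", day, float(np.mean(vals))))

    beam = trials[trials["test"] == "rotating_beam"]
    for (animal, day), grp in beam.groupby(["animal_id", "day"], sort=True):
        speeds = [beam_speed(t["distance_cm"], t["duration_s"]) for _, t in grp.iterrows()]
        drops = grp["hindlimb_drops"].astype(float)
        cohort = grp["cohort"].iloc[0]
        rows.append((animal, cohort, "speed_cm_s", day, float(np.mean(speeds))))
        rows.append((animal, cohort, "hl_drops", day, float(drops.mean())))

    out = pd.DataFrame(rows, columns=["animal_id", "cohort", "readout", "day", "value"])
    return out.sort_values(["animal_id", "readout", "day"], ignore_index=True)


@dataclass(frozen=True)
class SlopeResult:
    """OLS recovery-rate slope and the number of days it used."""

    slope: float
    n_points: int

    @property
    def missing(self) -> bool:
        return self.n_points < 2


def recovery_rate(values: Mapping[int, float], days: Sequence[int] = (3, 7, 14)) -> SlopeResult:
    """Recovery-rate surrogate: OLS slope of readout value vs. day.

    Uses whichever of the requested days are present in ``values``; with
    fewer than two the result is flagged missing (``slope`` NaN) and feeds a
    missing vote downstream.
    """
    present = [d for d in days if d in values]
    if len(present) < 2:
        return SlopeResult(float("nan"), len(present))
    x = np.asarray(present, dtype=float)
    y = np.asarray([values[d] for d in present], dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    return SlopeResult(slope, len(present))


def _series_map(readouts: pd.DataFrame) -> dict:
    """Nest the long readout table into {animal: {readout: {day: value}}}."""
    out: dict = {}
    for row in readouts.itertuples(index=False):
        out.setdefault(row.animal_id, {}).setdefault(row.readout, {})[row.day] = row.value
    return out


class RecoveryClassifier(BaseEstimator):
    """Median-split 2-of-3 vote classifier for post-stroke recovery.

    For each readout, the per-animal recovery-rate slope over days 3-14 is
    compared against the cohort median: for foot faults and hindlimb drops a
    slope below the median (faster decrease of the deficit) votes ``good``,
    for beam speed a slope above the median votes ``good``.  An animal is
    labelled ``good`` (``poor``) when at least two readouts agree; any other
    configuration — including 1-1 splits with a missing readout — is
    ``neutral``.

    Parameters
    ----------
    slope_mode : {"three_point_preferred", "two_point", "three_point"}
        Which regression feeds the median split: days 3-7-14 when all three
        are present falling back to 3-14 (default), always 3-14, or strictly
        3-7-14.
    tie_vote : {"poor", "good"}
        Vote of an animal whose slope equals the median exactly (default
        conservative ``poor``).

    Attributes
    ----------
    slopes_ : DataFrame, animals x readouts
    n_points_ : DataFrame, days used per slope
    medians_ : Series, per-readout reference median
    votes_ : DataFrame of {"good", "poor", "missing"}
    labels_ : Series, final {"good", "poor", "neutral"} per animal
    """

    def __init__(self, slope_mode: str = "three_point_preferred", tie_vote: str = "poor"):
        self.slope_mode = slope_mode
        self.tie_vote = tie_vote

    def _slope_days(self, present: set) -> list[int] | None:
        if self.slope_mode == "three_point_preferred":
            if {3, 7, 14} <= present:
                return [3, 7, 14]
            if {3, 14} <= present:
                return [3, 14]
            return None
        if self.slope_mode == "two_point":
            return [3, 14] if {3, 14} <= present else None
        if self.slope_mode == "three_point":
            return [3, 7, 14] if {3, 7, 14} <= present else None
        raise ValueError(f"unknown slope_mode {self.slope_mode!r}")

    def fit(self, readouts: pd.DataFrame, y=None):
        """Compute slopes, votes and labels from a long readout table.

        ``readouts`` must contain stroke animals only (columns ``animal_id,
        readout, day, value``); sham animals have no recovery class.
        """
        if self.tie_vote not in ("poor", "good"):
            raise ValueError(f"tie_vote must be 'poor' or 'good', got {self.tie_vote!r}")
        series = _series_map(readouts)
        if len(series) < 2:
            raise ValueError("need at least two stroke animals to form a median reference")
        animals = sorted(series)

        slopes = pd.DataFrame(index=animals, columns=list(READOUTS), dtype=float)
        n_points = pd.DataFrame(0, index=animals, columns=list(READOUTS), dtype=int)
        for animal in animals:
            for readout in READOUTS:
                days_map = series[animal].get(readout, {})
                use = self._slope_days(set(days_map))
                if use is None:
                    res = SlopeResult(float("nan"), 0)
                else:
                    res = recovery_rate(days_map, use)
                slopes.loc[animal, readout] = res.slope
                n_points.loc[animal, readout] = res.n_points

        medians = slopes.median(axis=0, skipna=True)

        votes = pd.DataFrame("missing", index=animals, columns=list(READOUTS))
        for readout in READOUTS:
            med = medians[readout]
            for animal in animals:
                s = slopes.loc[animal, readout]
                if np.isnan(s) or np.isnan(med):
                    continue
                if s == med:
                    votes.loc[animal, readout] = self.tie_vote
                elif _GOOD_IS_NEGATIVE[readout]:
                    votes.loc[animal, readout] = "good" if s < med else "poor"
                else:
                    votes.loc[animal, readout] = "good" if s > med else "poor"

        labels = {}
        for animal in animals:
            v = votes.loc[animal]
            n_good = int((v == "good").sum())
            n_poor = int((v == "poor").sum())
            if n_good >= 2:
                labels[animal] = "good"
            elif n_poor >= 2:
                labels[animal] = "poor"
            else:
                labels[animal] = "neutral"
                if (v == "missing").all():
                    logger.warning("animal %s: all recovery-rate slopes missing", animal)

        self.slopes_ = slopes
        self.n_points_ = n_points
        self.medians_ = medians
        self.votes_ = votes
        self.labels_ = pd.Series(labels, name="label")
        return self

    def fit_predict(self, readouts: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(readouts).labels_


def classify_cohort(readouts: pd.DataFrame, slope_mode: str = "three_point_preferred",
                    tie_vote: str = "poor") -> pd.DataFrame:
    """Classify the stroke cohort; thin wrapper over :class:`RecoveryClassifier`.

    Returns a DataFrame with per-readout slopes, days used, votes and the
    final label, one row per stroke animal.
    """
    clf = RecoveryClassifier(slope_mode=slope_mode, tie_vote=tie_vote).fit(readouts)
    out = pd.DataFrame({"animal_id": clf.labels_.index})
    for readout, tag in zip(READOUTS, ("ff", "speed", "hld")):
        out[f"slope_{tag}"] = clf.slopes_[readout].to_numpy()
        out[f"n_points_{tag}"] = clf.n_points_[readout].to_numpy()
        out[f"vote_{tag}"] = clf.votes_[readout].to_numpy()
    out["label"] = clf.labels_.to_numpy()
    return out


def sham_reference(readouts: pd.DataFrame) -> pd.DataFrame:
    """Per-readout, per-day mean over sham animals (full-recovery reference)."""
    sham = readouts[readouts["cohort"] == "sham"]
    if sham.empty:
        raise ValueError("no sham animals found to build the recovery reference")
    ref = sham.groupby(["readout", "day"], as_index=False)["value"].mean()
    return ref.rename(columns={"value": "sham_mean"})


def recovery_scores(readouts: pd.DataFrame, reference: pd.DataFrame | None = None,
                    atol: float = 1e-9) -> pd.DataFrame:
    """Normalize deficit trajectories to recovery scores.

    Per readout the score at day ``t`` is the improvement since day 3
    expressed as a percentage of the day-3 deficit relative to the
    time-matched sham mean ``s(t)``::

        deficit readouts (foot faults, drops): 100 * (x(3) - x(t)) / (x(3) - s(t))
        speed:                                 100 * (x(t) - x(3)) / (s(t) - x(3))

    so the score is 0% at day 3 by construction and 100% when the animal
    reaches the sham level.  The composite score is the unweighted mean of
    the available per-readout scores.  A readout without a day-3 deficit
    (``x(3)`` at or beyond the sham level) cannot be normalized and is
    excluded with a warning.

    Parameters
    ----------
    readouts : DataFrame
        Long readout table including the sham animals (used for the
        reference) unless ``reference`` is given.
    reference : DataFrame, optional
        Precomputed ``readout, day, sham_mean`` table.

    Returns
    -------
    DataFrame
        ``animal_id, day, score_foot_fault_pct, score_speed_cm_s,
        score_hl_drops, score`` for stroke animals on days >= 3.
    """
    if reference is None:
        reference = sham_reference(readouts)
    ref = {(r.readout, r.day): r.sham_mean for r in reference.itertuples(index=False)}

    stroke = readouts[readouts["cohort"] == "stroke"]
    series = _series_map(stroke)
    rows = []
    for animal in sorted(series):
        per_readout = series[animal]
        days = sorted({d for m in per_readout.values() for d in m if d >= 3})
        for day in days:
            scores = {}
            for readout in READOUTS:
                vals = per_readout.get(readout, {})
                if 3 not in vals or day not in vals or (readout, day) not in ref:
                    continue
                x3, xt, s = vals[3], vals[day], ref[(readout, day)]
                denom = (x3 - s) if _GOOD_IS_NEGATIVE[readout] else (s - x3)
                if denom <= atol:
                    logger.warning(
                        "animal %s readout %s: no day-3 deficit vs sham at day %s; excluded",
                        animal, readout, day)
                    continue
                num = (x3 - xt) if _GOOD_IS_NEGATIVE[readout] else (xt - x3)
                scores[readout] = 100.0 * num / denom
            if scores:
                row = dict(animal_id=animal, day=day)
                for readout in READOUTS:
                    row[f"score_{readout}"] = scores.get(readout, np.nan)
                row["score"] = float(np.mean(list(scores.values())))
                if day == 3:
                    row["score"] = 0.0
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class WardResult:
    """Agglomerative Ward clustering output.

    ``linkage`` is the scipy linkage matrix (merge history); heights are
    Euclidean Ward distances, so the increase in within-cluster sum of
    squares of a merge is ``height**2 / 2``.  ``kept`` lists the row labels
    that entered the clustering (rows with missing features are excluded).
    """

    labels: pd.Series
    linkage: np.ndarray
    kept: list


def ward_cluster(features: pd.DataFrame, k: int) -> WardResult:
    """Ward's-method hierarchical clustering of per-animal feature vectors.

    Parameters
    ----------
    features : DataFrame
        Animals x features; rows containing NaN are dropped with a warning.
    k : int
        Number of flat clusters to cut (2-4 in typical use).
    """
    complete = features.dropna(axis=0)
    dropped = set(features.index) - set(complete.index)
    if dropped:
        logger.warning("ward_cluster: dropping rows with missing features: %s", sorted(dropped))
    n = len(complete)
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} complete rows")
    if n < 2:
        raise ValueError("need at least two complete rows to cluster")
    Z = linkage(complete.to_numpy(dtype=float), method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return WardResult(pd.Series(flat, index=complete.index, name="cluster"),
                      Z, list(complete.index))
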