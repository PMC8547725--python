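"""Exclusion pipeline for staircase trial tables.

Three rules, applied in order:

1. *Wrong-button trials* — trials whose comparison speed exceeds 1.5x the
   (unsigned) standard speed are dropped; these are early accidental
   responses that drive the staircase far above its start range.
2. *Non-converged staircases* — for each staircase pair, the mean comparison
   speed over the last ten trials of each thread is computed; if the two
   thread means differ by more than 3 m/s the staircase never settled and
   all its trials are dropped.
3. *Self-motion rating criterion* — a participant passes a condition when
   their mean rating lies within 0.4 of the expected pole of the scale
   (the "I moved" pole for the regular and blank-wall stimuli, the "the
   wall moved" pole for the moving-wall stimulus).  Failing participants
   are flagged, not removed, unless strict mode is requested.

``modelling_subject_filter`` additionally restricts to participants with no
excluded staircases (required by the effect-decomposition models, which need
every condition cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .observers import RATING_POLES

__all__ = [
    "ExclusionReport",
    "filter_wrong_button_trials",
    "filter_nonconverged_staircases",
    "rating_criterion",
    "modelling_subject_filter",
    "run_exclusions",
]


@dataclass
class ExclusionReport:
    """Bookkeeping for the exclusion pipeline; fractions are of the input."""

    n_trials_in: int = 0
    n_trials_removed: int = 0
    n_staircases_in: int = 0
    n_staircases_removed: int = 0
    excluded_staircase_ids: list = field(default_factory=list)
    subjects_with_any_removed_staircase: set = field(default_factory=set)
    subjects_flagged_by_rating: set = field(default_factory=set)
    subjects_missing_ratings: set = field(default_factory=set)
    short_threads: list = field(default_factory=list)

    @property
    def trial_fraction_removed(self) -> float:
        return self.n_trials_removed / self.n_trials_in if self.n_trials_in else 0.0

    @property
    def staircase_fraction_removed(self) -> float:
        if not self.n_staircases_in:
            return 0.0
        return self.n_staircases_removed / self.n_staircases_in

    def to_dict(self) -> dict:
        return {
            "n_trials_in": self.n_trials_in,
            "n_trials_removed": self.n_trials_removed,
            "trial_fraction_removed": self.trial_fraction_removed,
            "n_staircases_in": self.n_staircases_in,
            "n_staircases_removed": self.n_staircases_removed,
            "staircase_fraction_removed": self.staircase_fraction_removed,
            "excluded_staircase_ids": sorted(self.excluded_staircase_ids),
            "subjects_with_any_removed_staircase": sorted(
                self.subjects_with_any_removed_staircase
            ),
            "subjects_flagged_by_rating": sorted(self.subjects_flagged_by_rating),
            "subjects_missing_ratings": sorted(self.subjects_missing_ratings),
            "short_threads": list(self.short_threads),
        }


def filter_wrong_button_trials(
    trials: pd.DataFrame, threshold_ratio: float = 1.5
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop trials with comparison speed strictly above 1.5x the standard."""
    report = ExclusionReport(n_trials_in=len(trials))
    if trials.empty:
        return trials.copy(), report
    bad = trials["comparison_speed_mps"] > threshold_ratio * trials[
        "standard_speed_mps"
    ].abs()
    report.n_trials_removed = int(bad.sum())
    return trials.loc[~bad].copy(), report


def filter_nonconverged_staircases(
    trials: pd.DataFrame,
    max_thread_gap: float = 3.0,
    last_n: int = 10,
    report: ExclusionReport | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop staircases whose two threads' last-10-trial means differ > 3 m/s.

    A thread with fewer than ``last_n`` trials contributes the mean of all
    its trials (logged in the report).  Staircases with a single thread are
    kept (there is no gap to measure).
    """
    report = report or ExclusionReport()
    report.n_staircases_in = trials["staircase_id"].nunique() if len(trials) else 0
    if trials.empty:
        return trials.copy(), report

    excluded = []
    for sc_id, grp in trials.groupby("staircase_id", sort=False):
        means = {}
        for thread, tgrp in grp.groupby("thread", sort=False):
            tail = tgrp.sort_values("trial_index").tail(last_n)
            if len(tgrp) < last_n:
                report.short_threads.append((str(sc_id), str(thread), int(len(tgrp))))
            means[thread] = tail["comparison_speed_mps"].mean()
        if len(means) >= 2:
            vals = sorted(means.values())
            if vals[-1] - vals[0] > max_thread_gap:
                excluded.append(sc_id)

    report.n_staircases_removed = len(excluded)
    report.excluded_staircase_ids = [str(s) for s in excluded]
    kept = trials.loc[~trials["staircase_id"].isin(excluded)].copy()
    removed_subjects = set(
        trials.loc[trials["staircase_id"].isin(excluded), "subject_id"].unique()
    )
    report.subjects_with_any_removed_staircase |= removed_subjects
    return kept, report


def rating_criterion(
    ratings: pd.DataFrame, band: float = 0.4
) -> pd.DataFrame:
    """Per subject x condition pass/fail of the self-motion rating criterion.

    Pass iff ``|mean rating - expected pole| <= band``; the pole is -1
    ("perceived self-motion") for the regular and blank-wall conditions and
    +1 ("perceived wall motion") for the moving-wall condition.  Subjects
    with no ratings in a condition are flagged missing (pass = False).
    """
    rows = []
    subjects = ratings["subject_id"].unique()
    for subject in subjects:
        for condition, pole in RATING_POLES.items():
            sel = ratings[
                (ratings["subject_id"] == subject)
                & (ratings["condition"] == condition)
            ]
            if sel.empty:
                rows.append((subject, condition, float("nan"), False, True))
                continue
            mean = float(sel["rating"].mean())
            rows.append((subject, condition, mean, abs(mean - pole) <= band, False))
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "mean_rating", "passed", "missing"]
    )


def modelling_subject_filter(trials: pd.DataFrame, report: ExclusionReport) -> list:
    """Subjects eligible for the effect models: no excluded staircases."""
    subjects = set(trials["subject_id"].unique())
    kept = sorted(subjects - set(report.subjects_with_any_removed_staircase))
    if not kept:
        import warnings

        warnings.warn("all subjects had at least one excluded staircase")
    return kept


def run_exclusions(
    trials: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
    strict_rating: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full pipeline: trial filter, staircase filter, rating criterion."""
    kept, report = filter_wrong_button_trials(trials)
    kept, report = filter_nonconverged_staircases(kept, report=report)
    report.n_trials_in = len(trials)
    report.n_trials_removed = len(trials) - len(kept)
    if ratings is not None and len(ratings):
        table = rating_criterion(ratings)
        failed = set(table.loc[~table["passed"], "subject_id"].unique())
        report.subjects_flagged_by_rating = failed
        report.subjects_missing_ratings = set(
            table.loc[table["missing"], "subject_id"].unique()
        )
        if strict_rating:
            kept = kept.loc[~kept["subject_id"].isin(failed)].copy()
    return kept, report
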