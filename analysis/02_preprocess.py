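#!/usr/bin/env python
"""Apply the exclusion pipeline: wrong-button trials (comparison > 1.5x the
standard), staircases whose thread means diverge by > 3 m/s, and the
self-motion rating criterion (|mean - pole| <= 0.4, flag-only by default).

Reads results/trials.csv (+ratings), writes results/trials_clean.csv and
results/exclusions.json.
"""

import argparse
import json
from pathlib import Path

from flowparse import io as fio
from flowparse.preprocess import modelling_subject_filter, run_exclusions

parser = argparse.ArgumentParser()
parser.add_argument("--dir", type=Path, default=Path("results"))
args = parser.parse_args()

trials = fio.read_trials(args.dir / "trials.csv")
ratings_path = args.dir / "ratings.csv"
ratings = fio.read_ratings(ratings_path) if ratings_path.exists() else None

kept, report = run_exclusions(trials, ratings)
fio.write_trials(kept, args.dir / "trials_clean.csv")
(args.dir / "exclusions.json").write_text(json.dumps(report.to_dict(), indent=2))

eligible = modelling_subject_filter(kept, report)
print(
    f"removed {report.n_trials_removed}/{report.n_trials_in} trials "
    f"({100 * report.trial_fraction_removed:.1f}%) and "
    f"{report.n_staircases_removed}/{report.n_staircases_in} staircases "
    f"({100 * report.staircase_fraction_removed:.1f}%)"
)
print(
    f"{len(report.subjects_flagged_by_rating)} participants flagged by the "
    f"rating criterion; {len(eligible)} eligible for the effect models"
)
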