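#!/usr/bin/env python
"""Simulate a full synthetic experiment: staircase-driven 2IFC sessions and
self-motion ratings for a cohort of cumulative-Gaussian observers.

Writes results/trials.csv and results/ratings.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from flowparse import io as fio
from flowparse.observers import (
    GenerativeConfig,
    sample_observer,
    simulate_experiment_session,
    simulate_ratings,
)

parser = argparse.ArgumentParser()
parser.add_argument("--n-participants", type=int, default=30)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
rng = np.random.default_rng(args.seed)
config = GenerativeConfig()

frames, rframes = [], []
for i in range(args.n_participants):
    observer = sample_observer(config, f"s{i + 1:02d}", rng)
    frames.append(simulate_experiment_session(config, observer, rng))
    rframes.append(simulate_ratings(observer.participant_id, rng))

trials = pd.concat(frames, ignore_index=True)
ratings = pd.concat(rframes, ignore_index=True)
fio.write_trials(trials, args.out_dir / "trials.csv")
fio.write_ratings(ratings, args.out_dir / "ratings.csv")

n_staircases = trials["staircase_id"].nunique() * 2  # two threads each
print(
    f"simulated {args.n_participants} participants: {len(trials)} trials, "
    f"{n_staircases} PEST threads, {len(ratings)} ratings"
)
print(f"wrote {args.out_dir / 'trials.csv'} and {args.out_dir / 'ratings.csv'}")
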