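#!/usr/bin/env python
"""Fit the per-participant accuracy and precision decomposition models.

Accuracy: PSE = PSE_static + E_self * C_self + E_induced * C_induced.
Precision: SD = SD_static + E_self_sd * C_self_prec + E_retinal * R.
Participants with excluded staircases or unusable cells are dropped (the
models need every condition cell).  Writes results/effects.csv and
results/effects_summary.json, and reports the correlation between the two
self-motion effects.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from flowparse.effects import effect_correlation, fit_all_participants

parser = argparse.ArgumentParser()
parser.add_argument("--dir", type=Path, default=Path("results"))
args = parser.parse_args()

fits = pd.read_csv(args.dir / "psychometric_fits.csv")
ok = fits[fits["converged"]]

required = {
    (c, p, s)
    for c in ("main", "blank_wall", "moving_wall")
    for p in ("static", "same", "opposite")
    for s in sorted(ok["standard_speed_mps"].unique())
}
complete = [
    sid
    for sid, grp in ok.groupby("subject_id")
    if required
    <= set(
        map(
            tuple,
            grp[["condition", "motion_profile", "standard_speed_mps"]].itertuples(
                index=False
            ),
        )
    )
]

estimates = fit_all_participants(ok, subjects=complete)
estimates.to_csv(args.dir / "effects.csv", index=False)

summary = {
    col: {"mean": float(estimates[col].mean()), "median": float(estimates[col].median())}
    for col in estimates.columns
    if col != "subject_id"
}
print(f"fitted effect models for {len(estimates)} participants")
for name in ("effect_selfmotion", "effect_induced", "effect_selfmotion_sd",
             "effect_retinal", "rmse_accuracy", "rmse_precision"):
    s = summary[name]
    print(f"  {name:>22}: mean {s['mean']:+.4f}, median {s['median']:+.4f}")

try:
    r, p = effect_correlation(estimates)
    summary["effect_correlation"] = {"r": r, "p": p}
    print(f"correlation(E_self_PSE, E_self_SD): r = {r:.2f}, p = {p:.3f}")
except ValueError as exc:
    summary["effect_correlation"] = {"error": str(exc)}
    print(f"effect correlation undefined: {exc}")

(args.dir / "effects_summary.json").write_text(json.dumps(summary, indent=2))
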