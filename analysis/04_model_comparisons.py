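#!/usr/bin/env python
"""Hierarchical probit model comparisons on the cleaned trial table.

For each backdrop condition, fits the precision test/null pair (does
self-motion change the psychometric slope?) and the accuracy test/null pair
(does the motion profile shift the PSE?), runs the likelihood-ratio tests,
and converts the motion-profile coefficients to self-motion compensation
percentages.  Writes results/inference.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from flowparse import io as fio
from flowparse.probit import (
    accuracy_null_spec,
    accuracy_test_spec,
    compensation_percentage,
    fit_probit_mixed,
    likelihood_ratio_test,
    precision_null_spec,
    precision_test_spec,
)

parser = argparse.ArgumentParser()
parser.add_argument("--dir", type=Path, default=Path("results"))
parser.add_argument("--conditions", nargs="*", default=["main"])
args = parser.parse_args()

trials = fio.read_trials(args.dir / "trials_clean.csv")
payload = {}
for condition in args.conditions:
    sub = trials[trials["condition"] == condition]
    block = {}
    for label, null_spec, test_spec in (
        ("precision", precision_null_spec(), precision_test_spec()),
        ("accuracy", accuracy_null_spec(), accuracy_test_spec()),
    ):
        fit_null = fit_probit_mixed(sub, null_spec)
        warm = np.log(np.maximum(list(fit_null.random_sd.values()), 1e-4))
        fit_test = fit_probit_mixed(sub, test_spec, theta0=warm)
        lrt = likelihood_ratio_test(fit_null, fit_test)
        block[label] = {
            "coefficients": fit_test.coefficients,
            "standard_errors": fit_test.standard_errors,
            "random_sd": fit_test.random_sd,
            "chi2": lrt.chi2,
            "df": lrt.df,
            "p_value": lrt.p_value,
        }
        print(
            f"{condition}/{label}: chi2({lrt.df}) = {lrt.chi2:.2f}, "
            f"p = {lrt.p_value:.4g}"
        )
    acc = block["accuracy"]["coefficients"]
    block["compensation_pct"] = {
        "same": compensation_percentage(acc["motion_profile[same]"], "same"),
        "opposite": compensation_percentage(
            acc["motion_profile[opposite]"], "opposite"
        ),
    }
    print(
        f"{condition}: compensation same {block['compensation_pct']['same']:.0f}%, "
        f"opposite {block['compensation_pct']['opposite']:.0f}%"
    )
    payload[condition] = block

(args.dir / "inference.json").write_text(json.dumps(payload, indent=2))
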