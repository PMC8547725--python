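"""Maximum-likelihood cumulative-Gaussian psychometric fits.

Each cell (participant x condition x motion profile x standard speed) is
fitted with a two-parameter cumulative Gaussian by direct likelihood
minimization:

    P("comparison faster" | comparison speed v) = NormalCDF((v - pse) / sd)

The mean (PSE) is the accuracy measure, the standard deviation the
precision proxy (proportional to the JND).  No guess/lapse parameters are
fitted.  Optimization is derivative-free Nelder-Mead from five data-driven
starting points with deterministic tie-breaking (lowest SD among
likelihood-equivalent optima); SD is constrained to [0.01, 10] m/s and
boundary solutions are flagged non-converged, as are perfectly separated
response sets for which the likelihood has no interior maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

__all__ = ["PsychometricFit", "fit_psychometric", "fit_all_cells"]

SD_BOUNDS = (0.01, 10.0)
MIN_TRIALS = 20


@dataclass(frozen=True)
class PsychometricFit:
    pse: float
    sd: float
    log_likelihood: float
    n_trials: int
    converged: bool


def _negloglik(params: np.ndarray, levels: np.ndarray, responses: np.ndarray) -> float:
    pse, sd = params
    z = (levels - pse) / sd
    # log P(y=1) = log Phi(z); log P(y=0) = log Phi(-z), both computed stably
    ll = np.where(responses == 1, log_ndtr(z), log_ndtr(-z))
    return -float(np.sum(ll))


def _is_separated(levels: np.ndarray, responses: np.ndarray) -> bool:
    """True when a threshold splits the responses perfectly (or they are
    constant); the MLE then pushes sd to the lower bound."""
    ones = levels[responses == 1]
    zeros = levels[responses == 0]
    if len(ones) == 0 or len(zeros) == 0:
        return True
    return ones.min() > zeros.max()


def fit_psychometric(
    levels,
    responses,
    min_trials: int = MIN_TRIALS,
    sd_bounds: tuple[float, float] = SD_BOUNDS,
) -> PsychometricFit:
    """Fit one cell's cumulative Gaussian by maximum likelihood.

    Parameters
    ----------
    levels, responses : array-like
        Comparison speeds (m/s) and binary responses (1 = "comparison
        faster").

    Raises
    ------
    ValueError
        On fewer than ``min_trials`` trials or fewer than two distinct
        comparison speeds.
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=int)
    n = len(levels)
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")
    if len(np.unique(levels)) < 2:
        raise ValueError("need at least 2 distinct comparison speeds")

    if _is_separated(levels, responses):
        ones = levels[responses == 1]
        zeros = levels[responses == 0]
        if len(ones) and len(zeros):
            pse = 0.5 * (ones.min() + zeros.max())
        else:
            pse = float(np.median(levels))
        sd = sd_bounds[0]
        return PsychometricFit(
            pse=float(pse),
            sd=sd,
            log_likelihood=-_negloglik(np.array([pse, sd]), levels, responses),
            n_trials=n,
            converged=False,
        )

    spread = max(float(np.std(levels)), 5 * sd_bounds[0])
    centre = float(np.mean(levels))
    starts = [
        (centre, spread),
        (float(np.median(levels)), spread / 2),
        (centre, spread * 2),
        (float(np.mean(levels[responses == 0])) * 0.5
         + float(np.mean(levels[responses == 1])) * 0.5, spread),
        (centre, max(spread / 4, 2 * sd_bounds[0])),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            _negloglik,
            x0=np.array(x0),
            args=(levels, responses),
            method="Nelder-Mead",
            bounds=[(None, None), sd_bounds],
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        # deterministic tie-break: better likelihood, then lower sd
        key = (round(res.fun, 9), round(res.x[1], 9))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    pse, sd = float(res.x[0]), float(res.x[1])
    at_bound = sd <= sd_bounds[0] * (1 + 1e-6) or sd >= sd_bounds[1] * (1 - 1e-6)
    return PsychometricFit(
        pse=pse,
        sd=sd,
        log_likelihood=-float(res.fun),
        n_trials=n,
        converged=bool(res.success) and not at_bound,
    )


CELL_KEYS = ["subject_id", "condition", "motion_profile", "standard_speed_mps"]


def fit_all_cells(trials: pd.DataFrame, min_trials: int = MIN_TRIALS) -> pd.DataFrame:
    """One psychometric fit per non-empty cell of the trial table.

    Cells failing the fit preconditions are kept with NaN estimates and
    ``converged = False`` so downstream modules can report them explicitly.
    """
    rows = []
    for key, grp in trials.groupby(CELL_KEYS, sort=True):
        try:
            fit = fit_psychometric(
                grp["comparison_speed_mps"].to_numpy(),
                grp["response"].to_numpy(),
                min_trials=min_trials,
            )
            rows.append(
                (*key, fit.pse, fit.sd, fit.log_likelihood, fit.n_trials, fit.converged)
            )
        except ValueError:
            rows.append((*key, np.nan, np.nan, np.nan, len(grp), False))
    return pd.DataFrame(
        rows,
        columns=CELL_KEYS + ["pse", "sd", "log_likelihood", "n_trials", "converged"],
    )
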