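"""Accuracy and precision decomposition models over per-cell psychometric fits.

Two two-parameter models are fitted per participant:

* accuracy:  PSE = PSE_static + E_selfmotion * C_selfmotion
                              + E_induced   * C_induced
* precision: SD  = SD_static  + E_selfmotion_sd * C_selfmotion_sd
                              + E_retinal       * RetinalVelocity

The condition codings separate what each backdrop manipulates: visually
simulated self-motion shifts perceived speed down (same direction, coded -1)
or up (opposite, +1); motion induced by the backdrop biases the target in
the opposite direction of the background motion (+1 when it should augment
perceived speed, -1 when it should reduce it); the precision model's
self-motion indicator is 1 whenever self-motion is visually simulated and 0
otherwise (including all moving-wall cells, where only the wall moves).
Baselines are fixed at the participant's observed static-cell fits per
backdrop (textured for main and moving-wall rows, blank for blank-wall
rows) and per standard speed; the two free effects are found by RMSE
minimization from zero initial values (the design is linear, so the
closed-form least-squares solution exists and is used as a cross-check in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

__all__ = [
    "ConditionCoding",
    "EffectEstimates",
    "RETINAL_SPEED_TABLE",
    "code_condition",
    "coding_table",
    "predict_pse",
    "predict_sd",
    "fit_effects",
    "fit_all_participants",
    "effect_correlation",
]

#: Mean retinal angular speed of the target (deg/s) by (motion profile,
#: standard speed).  Static values apply to every cell without visually
#: simulated self-motion, including the moving-wall condition.
RETINAL_SPEED_TABLE = {
    ("same", 6.6): 27.6,
    ("same", 8.0): 32.5,
    ("opposite", 6.6): 73.3,
    ("opposite", 8.0): 82.2,
    ("static", 6.6): 46.6,
    ("static", 8.0): 56.2,
}

CONDITIONS = ("main", "blank_wall", "moving_wall")
PROFILES = ("static", "same", "opposite")


@dataclass(frozen=True)
class ConditionCoding:
    condition: str
    motion_profile: str
    cond_selfmotion: int
    cond_induced: int
    cond_selfmotion_precision: int

    def retinal_velocity(self, standard_speed: float) -> float:
        profile = (
            self.motion_profile if self.cond_selfmotion_precision else "static"
        )
        return RETINAL_SPEED_TABLE[(profile, float(standard_speed))]


def code_condition(condition: str, motion_profile: str) -> ConditionCoding:
    """Condition coding of one (backdrop condition, motion profile) cell.

    In the moving-wall condition the ``motion_profile`` labels the *wall's*
    motion relative to the target; the observer is static, so the
    self-motion codings are 0 and only the induced-motion coding is active
    (wall moving with the target induces opposing motion: -1; wall moving
    against the target: +1).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if motion_profile not in PROFILES:
        raise ValueError(f"unknown motion profile {motion_profile!r}")

    if condition == "moving_wall" or motion_profile == "static":
        c_self = 0
        c_self_prec = 0
    else:
        c_self = -1 if motion_profile == "same" else 1
        c_self_prec = 1

    if motion_profile == "static" or condition == "blank_wall":
        c_induced = 0
    elif condition == "main":
        # self-motion with the target => backdrop streams against it
        c_induced = 1 if motion_profile == "same" else -1
    else:  # moving_wall
        c_induced = -1 if motion_profile == "same" else 1

    return ConditionCoding(
        condition=condition,
        motion_profile=motion_profile,
        cond_selfmotion=c_self,
        cond_induced=c_induced,
        cond_selfmotion_precision=c_self_prec,
    )


def coding_table() -> pd.DataFrame:
    """All 3 x 3 condition/profile codings as a table."""
    rows = [
        code_condition(c, p).__dict__ for c in CONDITIONS for p in PROFILES
    ]
    return pd.DataFrame(rows)


def _baseline_backdrop(condition: str) -> str:
    """Which static baseline a row uses: blank-wall rows use the blank
    static cell, everything else the textured static cell."""
    return "blank_wall" if condition == "blank_wall" else "main"


def predict_pse(
    baselines: dict, effects: tuple[float, float], coding: ConditionCoding,
    standard_speed: float,
) -> float:
    """Accuracy-model prediction for one cell.

    ``baselines`` maps (backdrop, standard speed) -> static PSE.
    ``effects = (effect_selfmotion, effect_induced)`` in m/s.
    """
    key = (_baseline_backdrop(coding.condition), float(standard_speed))
    if key not in baselines:
        raise KeyError(f"missing static baseline for {key}")
    e_self, e_induced = effects
    return (
        baselines[key]
        + e_self * coding.cond_selfmotion
        + e_induced * coding.cond_induced
    )


def predict_sd(
    baselines: dict, effects: tuple[float, float], coding: ConditionCoding,
    standard_speed: float,
) -> float:
    """Precision-model prediction for one cell.

    ``baselines`` maps (backdrop, standard speed) -> static SD.
    ``effects = (effect_selfmotion_sd, effect_retinal)``; the retinal term
    is ``effect_retinal * retinal velocity`` with the velocity in deg/s.
    """
    key = (_baseline_backdrop(coding.condition), float(standard_speed))
    if key not in baselines:
        raise KeyError(f"missing static baseline for {key}")
    e_self, e_retinal = effects
    return (
        baselines[key]
        + e_self * coding.cond_selfmotion_precision
        + e_retinal * coding.retinal_velocity(standard_speed)
    )


@dataclass(frozen=True)
class EffectEstimates:
    participant_id: str
    effect_selfmotion: float
    effect_induced: float
    effect_selfmotion_sd: float
    effect_retinal: float
    rmse_accuracy: float
    rmse_precision: float
    baselines_pse: dict
    baselines_sd: dict


def _rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _fit_two_parameter(observed, predict_row) -> tuple[np.ndarray, float]:
    """Minimize RMSE over the two effect parameters from (0, 0)."""
    obs = np.asarray(observed, dtype=float)

    def loss(effects):
        pred = np.array([predict_row(tuple(effects), i) for i in range(len(obs))])
        return _rmse(pred, obs)

    res = minimize(
        loss, x0=np.zeros(2), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
    )
    return res.x, float(res.fun)


def fit_effects(fit_table: pd.DataFrame, participant_id: str) -> EffectEstimates:
    """Fit accuracy and precision models to one participant's cell fits.

    ``fit_table`` must hold this participant's psychometric fits with
    columns condition, motion_profile, standard_speed_mps, pse, sd, covering
    the static cells of each backdrop (for the baselines) and the moving
    cells the models predict.  Missing cells raise with their names.
    """
    sub = fit_table[fit_table["subject_id"] == participant_id]
    cells = {
        (r.condition, r.motion_profile, float(r.standard_speed_mps)): (r.pse, r.sd)
        for r in sub.itertuples()
    }
    speeds = sorted({k[2] for k in cells})
    missing = [
        (backdrop, "static", s)
        for backdrop in ("main", "blank_wall")
        for s in speeds
        if (backdrop, "static", s) not in cells
    ]
    if missing:
        raise ValueError(f"missing static baseline cells: {missing}")

    baselines_pse = {
        (b, s): cells[(b, "static", s)][0] for b in ("main", "blank_wall") for s in speeds
    }
    baselines_sd = {
        (b, s): cells[(b, "static", s)][1] for b in ("main", "blank_wall") for s in speeds
    }

    # The static cells are the baselines (fixed inputs), not targets: the
    # residuals run over the cells the effects actually predict.
    rows = []
    for (condition, profile, speed), (pse, sd) in sorted(cells.items()):
        if np.isnan(pse) or np.isnan(sd):
            raise ValueError(
                f"cell ({condition}, {profile}, {speed}) has no usable fit"
            )
        if profile == "static":
            continue
        rows.append((code_condition(condition, profile), speed, pse, sd))

    pse_obs = [r[2] for r in rows]
    sd_obs = [r[3] for r in rows]

    acc, rmse_acc = _fit_two_parameter(
        pse_obs,
        lambda eff, i: predict_pse(baselines_pse, eff, rows[i][0], rows[i][1]),
    )
    prec, rmse_prec = _fit_two_parameter(
        sd_obs,
        lambda eff, i: predict_sd(baselines_sd, eff, rows[i][0], rows[i][1]),
    )
    return EffectEstimates(
        participant_id=participant_id,
        effect_selfmotion=float(acc[0]),
        effect_induced=float(acc[1]),
        effect_selfmotion_sd=float(prec[0]),
        effect_retinal=float(prec[1]),
        rmse_accuracy=rmse_acc,
        rmse_precision=rmse_prec,
        baselines_pse=baselines_pse,
        baselines_sd=baselines_sd,
    )


def fit_all_participants(fit_table: pd.DataFrame, subjects=None) -> pd.DataFrame:
    """Effect estimates for every (eligible) participant as a table."""
    if subjects is None:
        subjects = sorted(fit_table["subject_id"].unique())
    rows = []
    for pid in subjects:
        est = fit_effects(fit_table, pid)
        rows.append(
            (
                pid,
                est.effect_selfmotion,
                est.effect_induced,
                est.effect_selfmotion_sd,
                est.effect_retinal,
                est.rmse_accuracy,
                est.rmse_precision,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "effect_selfmotion",
            "effect_induced",
            "effect_selfmotion_sd",
            "effect_retinal",
            "rmse_accuracy",
            "rmse_precision",
        ],
    )


def effect_correlation(estimates: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between the accuracy-model and precision-model
    self-motion effects across participants (two-sided p)."""
    if len(estimates) < 3:
        raise ValueError("need at least 3 participants")
    x = estimates["effect_selfmotion"].to_numpy(dtype=float)
    y = estimates["effect_selfmotion_sd"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in effect estimates; correlation undefined")
    r, p = pearsonr(x, y)
    return float(r), float(p)
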