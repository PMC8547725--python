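"""Synthetic cumulative-Gaussian observers and session generators.

The generative model mirrors the study's simulation-based power analysis:

* static-observer PSE = 2/3 of the standard speed (a consistent "comparison
  looks faster" bias seen in pilot data);
* visually simulated self-motion shifts the PSE by 1/8 of the 1 m/s mean
  self-motion speed (+0.125 m/s when observer and target move in opposite
  directions, -0.125 m/s for the same direction);
* SD = 10% of the PSE (a ~7% Weber fraction), inflated by 1.25 whenever
  self-motion is simulated;
* per-participant heterogeneity: one PSE multiplier and one SD multiplier,
  both N(1, 0.1), applied to every cell of that participant;
* stimulus strengths: 55 ratios per cell from Cauchy(1, 0.04) (emulating the
  concentration of staircase trials around the PSE), mapped to comparison
  speeds, answered by Bernoulli draws from the observer's cumulative
  Gaussian.

Two sampling modes are provided: ``simulate_power_dataset`` (Cauchy-sampled
trials, the power analysis's mode) and ``simulate_experiment_session``
(trials placed by live PEST staircases, emulating a full experimental
session including control-condition staircases).  ``simulate_ratings``
generates the post-experiment self-motion versus world-motion ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import staircase as sc

__all__ = [
    "PROFILES",
    "GenerativeConfig",
    "ObserverParams",
    "cell_psychometric_params",
    "sample_observer",
    "simulate_power_dataset",
    "simulate_experiment_session",
    "simulate_ratings",
]

PROFILES = ("static", "same", "opposite")
CONDITIONS = ("main", "blank_wall", "moving_wall")

#: Expected pole of the self-motion rating scale per condition: -1 = "I
#: moved", +1 = "the world/wall moved".
RATING_POLES = {"regular": -1.0, "blank_wall": -1.0, "moving_wall": 1.0}


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the generative observer model (speeds in m/s)."""

    pse_static_ratio: float = 2.0 / 3.0
    selfmotion_bias: float = 0.125
    sd_to_pse_ratio: float = 0.10
    sd_inflation_moving: float = 1.25
    participant_multiplier_sd: float = 0.10
    stimulus_ratio_location: float = 1.0
    stimulus_ratio_scale: float = 0.04
    stimulus_ratio_clip: tuple = (0.2, 3.0)
    trials_per_cell: int = 55
    standard_speeds: tuple = (6.6, 8.0)
    motion_profiles: tuple = PROFILES

    def __post_init__(self) -> None:
        for name in ("pse_static_ratio", "sd_to_pse_ratio", "sd_inflation_moving"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")


@dataclass(frozen=True)
class ObserverParams:
    """Per-participant psychometric parameters, keyed by (speed, profile)."""

    participant_id: str
    pse: dict
    sd: dict

    def cell(self, standard_speed: float, motion_profile: str) -> tuple[float, float]:
        key = (standard_speed, motion_profile)
        return self.pse[key], self.sd[key]


def cell_psychometric_params(
    config: GenerativeConfig, standard_speed: float, motion_profile: str
) -> tuple[float, float]:
    """Population-level (PSE, SD) of one standard-speed x profile cell."""
    if standard_speed <= 0:
        raise ValueError("standard_speed must be positive")
    if motion_profile not in PROFILES:
        raise ValueError(f"unknown motion profile {motion_profile!r}")
    pse = config.pse_static_ratio * standard_speed
    if motion_profile == "opposite":
        pse += config.selfmotion_bias
    elif motion_profile == "same":
        pse -= config.selfmotion_bias
    sd = config.sd_to_pse_ratio * pse
    if motion_profile != "static":
        sd *= config.sd_inflation_moving
    return pse, sd


def sample_observer(
    config: GenerativeConfig, participant_id: str, rng: np.random.Generator
) -> ObserverParams:
    """Draw one observer: population cells scaled by N(1, 0.1) multipliers.

    One multiplier for the PSE and one for the SD, each shared across all
    cells of the participant; resulting values are clamped positive.
    """
    m_pse = rng.normal(1.0, config.participant_multiplier_sd)
    m_sd = rng.normal(1.0, config.participant_multiplier_sd)
    pse, sd = {}, {}
    for speed in config.standard_speeds:
        for profile in config.motion_profiles:
            base_pse, base_sd = cell_psychometric_params(config, speed, profile)
            key = (speed, profile)
            pse[key] = max(base_pse * m_pse, 1e-6)
            sd[key] = max(base_sd * m_sd, 1e-6)
    return ObserverParams(participant_id=participant_id, pse=pse, sd=sd)


def _draw_ratios(config: GenerativeConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.stimulus_ratio_clip
    ratios = rng.standard_cauchy(n) * config.stimulus_ratio_scale
    ratios += config.stimulus_ratio_location
    return np.clip(ratios, lo, hi)


def simulate_power_dataset(
    config: GenerativeConfig, n_participants: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Trial table for the power analysis's generative model.

    For every participant x standard speed x motion profile cell,
    ``trials_per_cell`` comparison speeds are drawn as Cauchy ratios of the
    participant's cell PSE; responses are Bernoulli with
    ``P("comparison faster") = NormalCDF((comparison - pse) / sd)``.  The
    target's left/right direction is drawn per trial and recorded as the
    sign of the standard speed; inference collapses it (the psychometric
    parameters depend on the unsigned speed and the motion profile only).
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for i in range(n_participants):
        pid = f"s{i + 1:02d}"
        obs = sample_observer(config, pid, rng)
        for speed in config.standard_speeds:
            for profile in config.motion_profiles:
                pse, sd = obs.cell(speed, profile)
                comparison = _draw_ratios(config, config.trials_per_cell, rng) * pse
                p_faster = norm.cdf((comparison - pse) / sd)
                resp = (rng.random(config.trials_per_cell) < p_faster).astype(int)
                direction = rng.choice([-1.0, 1.0], size=config.trials_per_cell)
                for k in range(config.trials_per_cell):
                    rows.append(
                        (
                            pid,
                            "main",
                            profile,
                            direction[k] * speed,
                            comparison[k],
                            resp[k],
                            f"{pid}_main_{profile}_{speed:g}",
                            "high" if k % 2 == 0 else "low",
                            k + 1,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "motion_profile",
            "standard_speed_mps",
            "comparison_speed_mps",
            "response",
            "staircase_id",
            "thread",
            "trial_index",
        ],
    )


#: Default session layout: every condition x profile cell is run at both
#: standard speeds with a high and a low PEST thread.  (In the study the
#: static textured cells were shared between the main and moving-wall
#: conditions; here they are simulated independently per condition so each
#: backdrop carries its own baseline.)
def _session_cells(config: GenerativeConfig):
    for condition in CONDITIONS:
        for speed in config.standard_speeds:
            for profile in config.motion_profiles:
                yield condition, speed, profile


def simulate_experiment_session(
    config: GenerativeConfig,
    observer: ObserverParams,
    rng: np.random.Generator,
    conditions=CONDITIONS,
    staircase_config: sc.StaircaseConfig | None = None,
) -> pd.DataFrame:
    """Emulate one participant's session with live PEST staircases.

    Each cell runs two threads (start offsets +/-33% of the standard speed)
    against Bernoulli responses from the observer's cumulative Gaussian for
    that cell.  The observer's (PSE, SD) depend on the motion profile only,
    not on the backdrop, so the control conditions share the main condition's
    psychometric parameters.
    """
    rows = []
    for condition, speed, profile in _session_cells(config):
        if condition not in conditions:
            continue
        pse, sd = observer.cell(speed, profile)
        sc_id = f"{observer.participant_id}_{condition}_{profile}_{speed:g}"
        for thread, offset in (("high", 0.33), ("low", -0.33)):
            base = staircase_config or sc.StaircaseConfig(standard_speed=speed)
            cfg = replace(base, standard_speed=speed, start_offset_fraction=offset)

            def respond(level: float) -> int:
                if sd <= 1e-9:
                    return int(level > pse)
                return int(rng.random() < norm.cdf((level - pse) / sd))

            state = sc.run_staircase(cfg, respond)
            for k, (level, resp) in enumerate(
                zip(state.level_history, state.responses)
            ):
                rows.append(
                    (
                        observer.participant_id,
                        condition,
                        profile,
                        speed,
                        level,
                        resp,
                        sc_id,
                        thread,
                        k + 1,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "motion_profile",
            "standard_speed_mps",
            "comparison_speed_mps",
            "response",
            "staircase_id",
            "thread",
            "trial_index",
        ],
    )


def simulate_ratings(
    participant_id: str,
    rng: np.random.Generator,
    truthfulness: float = 1.0,
    spread: float = 0.15,
    repetitions: int = 4,
) -> pd.DataFrame:
    """Synthetic self-motion ratings: 4 repetitions x 3 conditions x 2
    directions = 24 records per participant, each in [-1, 1].

    ``truthfulness`` interpolates between the condition's expected pole (1.0,
    a participant who perceives the stimulus as intended) and 0 (a
    participant who cannot tell); Gaussian jitter with SD ``spread`` is
    added and the result clipped to the scale bounds.
    """
    rows = []
    for condition, pole in RATING_POLES.items():
        centre = truthfulness * pole
        for _direction in ("left", "right"):
            for _ in range(repetitions):
                r = centre + (rng.normal(0.0, spread) if spread > 0 else 0.0)
                rows.append((participant_id, condition, float(np.clip(r, -1.0, 1.0))))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "rating"])
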