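"""Deterministic trial geometry.

A trial shows a target travelling laterally at ``v_x`` m/s for ``t`` seconds
at a fixed simulated depth, while the observer is either static or displaced
laterally along a Gaussian speed profile (position follows a cumulative
Gaussian in time).  The module provides

* the observer displacement profile ``observer_position``,
* the symmetric initial target placement ``initial_target_position``
  (``x_initial = 0.5 * (D_observer - v_x * t)``), and
* the mean retinal angular speed of the target over a trial.

Angles use planar geometry: the target direction is ``atan(lateral offset /
depth)``; the small vertical eye-target offset is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "MotionProfileParams",
    "TrialGeometry",
    "observer_position",
    "initial_target_position",
    "mean_retinal_speed",
]


@dataclass(frozen=True)
class MotionProfileParams:
    """Gaussian self-motion speed profile.

    The observer's lateral position in time is
    ``total_displacement * NormalCDF(t; profile_mean, profile_sd)``, i.e. the
    observer accelerates to peak speed at ``profile_mean`` and decelerates to
    a halt.  Defaults give a 0.5 m displacement over a 0.5 s trial, a mean
    self-motion speed of 1 m/s.

    Parameters
    ----------
    profile_mean : float
        Time of peak speed, seconds.
    profile_sd : float
        Temporal spread of the speed profile, seconds.
    total_displacement : float
        Signed lateral displacement over the trial, metres (negative for
        leftward motion).
    trial_duration : float
        Trial length, seconds.
    """

    profile_mean: float = 0.25
    profile_sd: float = 0.08
    total_displacement: float = 0.5
    trial_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.profile_sd <= 0:
            raise ValueError("profile_sd must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")


@dataclass(frozen=True)
class TrialGeometry:
    """Geometry of one trial: target speed/depth and observer displacement.

    ``observer_displacement`` is the signed lateral distance the observer is
    simulated to move over the trial (0 for a static observer).
    """

    target_speed: float
    observer_displacement: float = 0.0
    target_depth: float = 8.0
    trial_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")


def observer_position(t_query, params: MotionProfileParams = MotionProfileParams()):
    """Signed lateral observer displacement at time ``t_query``.

    Position follows a cumulative Gaussian in time scaled to the total
    displacement.  Monotone in ``t_query``; the displacement accumulated over
    the full trial is the nominal ``total_displacement`` up to the (tiny)
    CDF tail mass outside ``[0, trial_duration]``.

    Raises
    ------
    ValueError
        If ``t_query`` lies outside ``[0, trial_duration]``.
    """
    t = np.asarray(t_query, dtype=float)
    if np.any(t < 0) or np.any(t > params.trial_duration):
        raise ValueError(
            f"t_query must lie within [0, {params.trial_duration}] s"
        )
    pos = params.total_displacement * norm.cdf(
        t, loc=params.profile_mean, scale=params.profile_sd
    )
    return pos if pos.ndim else float(pos)


def initial_target_position(geom: TrialGeometry) -> float:
    """Initial lateral target position relative to the observer's start.

    Chosen so that observer and target motion are symmetric: the
    observer-target lateral offset at the end of the trial mirrors the offset
    at the start (equal magnitude, opposite sign)::

        x_initial = 0.5 * (D_observer - v_x * t)
    """
    return 0.5 * (
        geom.observer_displacement - geom.target_speed * geom.trial_duration
    )


def _relative_offset(times: np.ndarray, geom: TrialGeometry, params: MotionProfileParams) -> np.ndarray:
    """Target-minus-observer lateral offset at ``times``."""
    x0 = initial_target_position(geom)
    target = x0 + geom.target_speed * times
    observer = params.total_displacement * norm.cdf(
        times, loc=params.profile_mean, scale=params.profile_sd
    )
    # params.total_displacement and geom.observer_displacement must agree;
    # the geometry value is authoritative for the trajectory endpoints.
    observer *= (
        geom.observer_displacement / params.total_displacement
        if params.total_displacement != 0
        else 0.0
    )
    return target - observer


def mean_retinal_speed(
    geom: TrialGeometry,
    params: MotionProfileParams | None = None,
    dt: float = 1e-3,
) -> float:
    """Mean retinal angular speed of the target over the trial, deg/s.

    The total visual angle swept by the observer-relative target direction
    (planar geometry: ``atan(lateral offset / depth)``) divided by the trial
    duration.  For a static observer this equals the closed form
    ``2 * atan(|v_x| * t / 2 / depth) / t``.  For a moving observer the sweep
    is integrated numerically at ``dt`` resolution (the direction can reverse
    mid-trial, so the unsigned angular increments are accumulated).
    """
    if params is None:
        params = MotionProfileParams(
            total_displacement=(
                geom.observer_displacement if geom.observer_displacement != 0 else 0.5
            ),
            trial_duration=geom.trial_duration,
        )
    if geom.observer_displacement == 0.0:
        half = abs(geom.target_speed) * geom.trial_duration / 2.0 / geom.target_depth
        swept = 2.0 * np.arctan(half)
    else:
        n = max(int(round(geom.trial_duration / dt)), 2)
        times = np.linspace(0.0, geom.trial_duration, n + 1)
        angle = np.arctan(_relative_offset(times, geom, params) / geom.target_depth)
        swept = float(np.sum(np.abs(np.diff(angle))))
    return float(np.degrees(swept) / geom.trial_duration)
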