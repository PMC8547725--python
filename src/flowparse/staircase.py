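"""PEST adaptive staircase as a deterministic state machine.

One PEST thread controls the comparison speed of a 2IFC speed-discrimination
trial.  A response of 1 means "comparison judged faster" and moves the level
down; 0 moves it up.  Step sizes follow Taylor-Creelman rules:

* trials 1-5: step fixed at the initial value;
* from trial 6 onward, runs of same answers govern the step (second same
  answer: maintained; third: doubled unless a doubling preceded the last
  reversal; fourth and later: always doubled);
* from trial 11 onward a reversal additionally halves the step.

A thread converges once at least 20 trials were judged and the last five
steps were all below 0.1 m/s; otherwise it terminates at 27 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "init_staircase",
    "update",
    "check_finished",
    "training_screen",
    "run_staircase",
]

RUNNING = "running"
CONVERGED = "converged"
TERMINATED = "terminated"


@dataclass(frozen=True)
class StaircaseConfig:
    """Rule parameters of one PEST thread (speeds in m/s)."""

    standard_speed: float
    start_offset_fraction: float = 0.33
    initial_step: float = 1.2
    convergence_step_threshold: float = 0.1
    convergence_run_length: int = 5
    min_trials_for_convergence: int = 20
    max_trials: int = 27
    fixed_step_trials: int = 5
    reversal_rule_start_trial: int = 11
    level_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.standard_speed <= 0:
            raise ValueError("standard_speed must be positive")


@dataclass(frozen=True)
class StaircaseState:
    """Full PEST bookkeeping after ``trial_index`` judged trials.

    ``level`` is the comparison speed the *next* trial would present;
    ``step`` the step size that produced it.  ``step_history[i]`` records the
    step size in force after trial ``i + 1`` (the quantity the convergence
    rule inspects); ``level_history[i]`` the level presented on trial
    ``i + 1``.
    """

    config: StaircaseConfig
    level: float
    step: float
    trial_index: int = 0
    status: str = RUNNING
    responses: tuple = ()
    level_history: tuple = ()
    step_history: tuple = ()
    same_answer_run: int = 0
    doubled_since_reversal: bool = False
    doubled_before_last_reversal: bool = False


def init_staircase(config: StaircaseConfig) -> StaircaseState:
    """Fresh thread at ``standard * (1 + start_offset_fraction)``."""
    level = config.standard_speed * (1.0 + config.start_offset_fraction)
    return StaircaseState(config=config, level=level, step=config.initial_step)


def _next_step(state: StaircaseState, reversal: bool, run: int) -> tuple[float, bool, bool]:
    """Step size after the current response, with doubling-flag bookkeeping.

    Returns (step, doubled_since_reversal, doubled_before_last_reversal).
    """
    cfg = state.config
    trial = state.trial_index + 1
    step = state.step
    doubled_since = state.doubled_since_reversal
    doubled_before = state.doubled_before_last_reversal

    if trial <= cfg.fixed_step_trials:
        if reversal:
            doubled_before, doubled_since = doubled_since, False
        return step, doubled_since, doubled_before

    if reversal:
        doubled_before, doubled_since = doubled_since, False
        if trial >= cfg.reversal_rule_start_trial:
            step = step / 2.0
    elif run == 2:
        pass  # second same answer: step maintained
    elif run == 3:
        if not doubled_before:
            step = step * 2.0
            doubled_since = True
    elif run >= 4:
        step = step * 2.0
        doubled_since = True
    return step, doubled_since, doubled_before


def update(state: StaircaseState, response: int) -> StaircaseState:
    """Advance the thread by one judged trial.

    ``response`` = 1 ("comparison faster") moves the level down by the
    updated step, 0 moves it up; the level is clamped at the positive floor.
    Raises if the thread already finished.
    """
    if state.status != RUNNING:
        raise RuntimeError(f"cannot update a staircase with status {state.status!r}")
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")

    presented_level = state.level
    reversal = bool(state.responses) and response != state.responses[-1]
    run = 1 if (not state.responses or reversal) else state.same_answer_run + 1
    step, doubled_since, doubled_before = _next_step(state, reversal, run)

    direction = -1.0 if response == 1 else 1.0
    level = max(state.level + direction * step, state.config.level_floor)

    new = replace(
        state,
        level=level,
        step=step,
        trial_index=state.trial_index + 1,
        responses=state.responses + (response,),
        level_history=state.level_history + (presented_level,),
        step_history=state.step_history + (step,),
        same_answer_run=run,
        doubled_since_reversal=doubled_since,
        doubled_before_last_reversal=doubled_before,
    )
    return check_finished(new)


def check_finished(state: StaircaseState) -> StaircaseState:
    """Apply the convergence/termination rules, returning the updated state.

    Converged: the last ``convergence_run_length`` trials all had steps
    strictly below the threshold AND at least ``min_trials_for_convergence``
    trials were judged.  Terminated: ``max_trials`` reached without
    convergence.  Status transitions are irreversible.
    """
    if state.status != RUNNING:
        return state
    cfg = state.config
    k = cfg.convergence_run_length
    if (
        state.trial_index >= cfg.min_trials_for_convergence
        and len(state.step_history) >= k
        and all(s < cfg.convergence_step_threshold for s in state.step_history[-k:])
    ):
        return replace(state, status=CONVERGED)
    if state.trial_index >= cfg.max_trials:
        return replace(state, status=TERMINATED)
    return state


def training_screen(final_steps, threshold: float = 0.3) -> bool:
    """Training pass/fail: fail iff any of the last five steps exceeds 0.3 m/s.

    "Above" is strict — a step of exactly 0.3 passes.  Requires exactly five
    step values.
    """
    steps = list(final_steps)
    if len(steps) != 5:
        raise ValueError(f"expected exactly 5 step values, got {len(steps)}")
    return all(s <= threshold for s in steps)


def run_staircase(config: StaircaseConfig, respond) -> StaircaseState:
    """Drive a thread to completion with ``respond(level) -> {0, 1}``."""
    state = init_staircase(config)
    while state.status == RUNNING:
        state = update(state, respond(state.level))
    return state
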