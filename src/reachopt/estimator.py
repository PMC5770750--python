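"""Delayed-feedback state estimation with an internal forward model.

Sensory feedback about the true arm state arrives with a delay of ``delay``
time steps, so the controller cannot observe the current state directly.
The estimator maintains two terms and blends them:

* an *open-loop* term: the previous open-loop estimate propagated through
  the (noise-free) forward model with the efference copy of the last
  command.  It drifts from the true trajectory because the applied command
  included motor noise the efference copy does not.
* a *closed-loop* term: the delayed true state rolled forward through the
  forward model with the buffered efference copies, which re-anchors the
  estimate to ground truth.

The combined estimate is the weighted mean
``x~ = (k1 x~1 + k2 x~2) / (k1 + k2)``.  Sensory noise is neglected; with a
noise-free plant both terms are exact and the estimate equals the true
state at every step.  Efference copies are the commanded (pre-noise)
activations.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .arm import ArmParams, PlantState, step

__all__ = [
    "EstimatorConfig",
    "StateEstimator",
    "open_loop_update",
    "closed_loop_update",
    "combine",
]


@dataclass
class EstimatorConfig:
    """Weights and delay of the two-term state estimator."""

    delay_steps: int = 10  #: sensory delay Delta, in integration steps
    k1: float = 0.2  #: open-loop term weight
    k2: float = 1.0  #: closed-loop term weight

    def __post_init__(self) -> None:
        if self.delay_steps < 0:
            raise ValueError("EstimatorConfig.delay_steps must be >= 0")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("EstimatorConfig weights must be >= 0")
        if self.k1 + self.k2 <= 0:
            raise ValueError("EstimatorConfig.k1 + k2 must be > 0")


def open_loop_update(
    prev_estimate: PlantState, u_prev: np.ndarray, params: ArmParams
) -> PlantState:
    """One noise-free forward-model step of the open-loop estimate."""
    new_state, _ = step(prev_estimate, u_prev, params, rng=None)
    return new_state


def closed_loop_update(
    delayed_state: PlantState,
    command_buffer,
    params: ArmParams,
    expected_len: int | None = None,
) -> PlantState:
    """Roll the delayed true state forward through the buffered commands.

    ``command_buffer`` holds the efference copies issued since the delayed
    observation, oldest first.  If ``expected_len`` is given the buffer
    length is checked against it.
    """
    commands = list(command_buffer)
    if expected_len is not None and len(commands) != expected_len:
        raise ValueError(
            f"command buffer holds {len(commands)} commands, expected {expected_len}"
        )
    est = delayed_state.copy()
    for u in commands:
        est, _ = step(est, u, params, rng=None)
    return est


def combine(x1: PlantState, x2: PlantState, config: EstimatorConfig) -> PlantState:
    """Weighted mean of the open- and closed-loop estimates."""
    w = config.k1 + config.k2
    if w <= 0:
        raise ValueError("estimator weights sum to zero")
    q = (config.k1 * x1.q + config.k2 * x2.q) / w
    q_dot = (config.k1 * x1.q_dot + config.k2 * x2.q_dot) / w
    return PlantState(q, q_dot)


class StateEstimator:
    """Stateful wrapper running the estimator in closed loop.

    Call :meth:`reset` with the (exactly known) initial state, then at each
    control step call :meth:`estimate` with the most recent delayed true
    state available, and :meth:`record_command` with the efference copy of
    the command issued.  During the first ``delay_steps`` steps no delayed
    observation exists yet; the closed-loop term then rolls the initial
    state forward through all commands issued so far.
    """

    def __init__(self, config: EstimatorConfig, params: ArmParams):
        self.config = config
        self.params = params
        self._open: PlantState | None = None
        self._buffer: deque[np.ndarray] = deque()
        self._t = 0

    def reset(self, x0: PlantState) -> None:
        self._open = x0.copy()
        self._anchor = x0.copy()  # state at time t - delay (initially t=0)
        self._buffer.clear()
        self._t = 0

    def record_command(self, u: np.ndarray, new_delayed_state: PlantState | None) -> None:
        """Register the efference copy for the step just taken.

        ``new_delayed_state`` is the true state that becomes observable at
        the *next* step (i.e. the state from ``delay_steps`` ago), or None
        while still inside the warm-up window.
        """
        if self._open is None:
            raise RuntimeError("estimator not reset")
        u = np.asarray(u, dtype=float).reshape(6).copy()
        self._buffer.append(u)
        self._open = open_loop_update(self._open, u, self.params)
        self._t += 1
        if len(self._buffer) > self.config.delay_steps:
            self._buffer.popleft()
            if new_delayed_state is None:
                raise ValueError("delayed state required once past the warm-up window")
            self._anchor = new_delayed_state.copy()

    def estimate(self) -> PlantState:
        """Combined estimate of the current state."""
        if self._open is None:
            raise RuntimeError("estimator not reset")
        closed = closed_loop_update(self._anchor, self._buffer, self.params)
        return combine(self._open, closed, self.config)
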