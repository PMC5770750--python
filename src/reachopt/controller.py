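"""Feed-forward neural policies mapping estimated state to muscle activations.

Each starting point gets its own small network: 4 inputs (normalized joint
angles and velocities), one hidden layer of ``n_hidden`` tanh units, and 6
logistic outputs so that activations always lie in [0,1]^6 without
clipping.  Policies are pure functions of their parameter vector — there is
no recurrence or internal state — which makes them directly searchable by a
black-box optimizer over the flat parameter vector.

Input scaling is fixed so that parameter vectors are transferable between
runs: joint angles are mapped affinely onto [-1, 1] using the joint limits,
and joint velocities are divided by ``VELOCITY_SCALE`` (20 rad/s), keeping
the units in the sensitive range of their activation functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import ArmParams, PlantState

__all__ = ["Policy", "policy_forward", "init_policy", "normalize_state", "VELOCITY_SCALE"]

#: Fixed joint-velocity normalization scale (rad/s).
VELOCITY_SCALE = 20.0

N_INPUT = 4
N_OUTPUT = 6


def n_params(n_hidden: int) -> int:
    """Parameter count of a 4 -> n_hidden -> 6 network (weights + biases)."""
    return N_INPUT * n_hidden + n_hidden + n_hidden * N_OUTPUT + N_OUTPUT


@dataclass
class Policy:
    """Flat-parameter feed-forward controller for one starting point.

    ``theta`` packs, in order: hidden weights (n_hidden x 4, row-major),
    hidden biases (n_hidden), output weights (6 x n_hidden, row-major),
    output biases (6).
    """

    n_hidden: int
    theta: np.ndarray

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("Policy.n_hidden must be >= 1")
        self.theta = np.asarray(self.theta, dtype=float).reshape(-1)
        expected = n_params(self.n_hidden)
        if self.theta.size != expected:
            raise ValueError(
                f"Policy.theta has {self.theta.size} parameters, "
                f"expected {expected} for n_hidden={self.n_hidden}"
            )

    def unpack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(W1, b1, W2, b2) views of the flat parameter vector."""
        nh = self.n_hidden
        i = 0
        w1 = self.theta[i : i + N_INPUT * nh].reshape(nh, N_INPUT)
        i += N_INPUT * nh
        b1 = self.theta[i : i + nh]
        i += nh
        w2 = self.theta[i : i + nh * N_OUTPUT].reshape(N_OUTPUT, nh)
        i += nh * N_OUTPUT
        b2 = self.theta[i : i + N_OUTPUT]
        return w1, b1, w2, b2


def normalize_state(state: PlantState, params: ArmParams) -> np.ndarray:
    """Map a plant state to the network's 4-dimensional input vector."""
    qn = 2.0 * (state.q - params.q_min) / (params.q_max - params.q_min) - 1.0
    return np.concatenate([qn, state.q_dot / VELOCITY_SCALE])


def policy_forward(policy: Policy, estimate: PlantState, params: ArmParams) -> np.ndarray:
    """Evaluate the policy on an estimated state; returns u in [0,1]^6."""
    if not np.all(np.isfinite(policy.theta)):
        raise ValueError("policy parameters must be finite")
    w1, b1, w2, b2 = policy.unpack()
    h = np.tanh(w1 @ normalize_state(estimate, params) + b1)
    z = w2 @ h + b2
    return 1.0 / (1.0 + np.exp(-z))


def init_policy(rng: np.random.Generator, n_hidden: int = 10) -> Policy:
    """Random initial policy with all weights and biases uniform on [0, 0.1]."""
    theta = rng.uniform(0.0, 0.1, size=n_params(n_hidden))
    return Policy(n_hidden=n_hidden, theta=theta)
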