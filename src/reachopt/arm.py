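"""Two-link planar arm driven by six muscles with signal-dependent noise.

The plant is a standard horizontal-plane, two degrees-of-freedom rigid-body
arm (shoulder + elbow) actuated by six muscles (mono- and bi-articular
flexor/extensor pairs) through a constant moment-arm matrix.  Muscle
activations are corrupted by multiplicative Gaussian noise before being
converted to joint torques, which is the source of the signal-dependent
variability that shapes the speed-accuracy trade-off.

Joint dynamics follow

    q'' = M(q)^-1 (tau - C(q, q') - B q')

with inertia matrix M, Coriolis vector C and a damping matrix B collecting
unmodelled dissipative effects.  Gravity is absent because the arm moves in
the horizontal plane.  Integration uses a semi-implicit Euler scheme
(velocity first, then position with the new velocity) at a fixed step ``dt``.

Angle convention: ``q1`` is the shoulder angle measured from the +x axis,
``q2`` the relative elbow flexion; the shoulder sits at the origin, so a
fully extended arm at ``q = (pi/2, 0)`` points straight up the +y axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmParams",
    "PlantState",
    "MuscleCommand",
    "compute_inertia",
    "coriolis",
    "muscle_torque",
    "step",
    "forward_kinematics",
    "inverse_kinematics",
]

#: Moment-arm matrix A (m), one row per muscle, one column per joint.
#: Muscles: shoulder flexor/extensor, elbow flexor/extensor, bi-articular
#: flexor/extensor.
DEFAULT_MOMENT_ARMS = np.array(
    [
        [0.040, 0.000],
        [-0.040, 0.000],
        [0.000, 0.025],
        [0.000, -0.025],
        [0.028, 0.028],
        [-0.035, -0.035],
    ]
)

#: Maximum muscle tensions f_max (N).
DEFAULT_FMAX = np.array([700.0, 382.0, 572.0, 445.0, 159.0, 318.0])

#: Damping matrix B (N m s).
DEFAULT_DAMPING = np.array([[0.05, 0.025], [0.025, 0.05]])

#: Joint limits representing the reachable space of a human arm (rad).
DEFAULT_Q_MIN = np.array([-0.6, -0.2])
DEFAULT_Q_MAX = np.array([2.6, 3.0])


@dataclass
class ArmParams:
    """Physical parameters of the planar arm.

    Defaults are anthropometric values for an adult human arm; the moment-arm
    matrix is constant (state-dependent moment arms are deliberately not
    modelled).
    """

    m1: float = 1.4  #: upper-arm mass (kg)
    m2: float = 1.1  #: forearm mass (kg)
    l1: float = 0.3  #: upper-arm length (m)
    l2: float = 0.35  #: forearm length (m)
    I1: float = 0.025  #: upper-arm inertia (kg m^2)
    I2: float = 0.045  #: forearm inertia (kg m^2)
    s1: float = 0.11  #: shoulder -> upper-arm COM distance (m)
    s2: float = 0.16  #: elbow -> forearm COM distance (m)
    B: np.ndarray = field(default_factory=lambda: DEFAULT_DAMPING.copy())
    A: np.ndarray = field(default_factory=lambda: DEFAULT_MOMENT_ARMS.copy())
    f_max: np.ndarray = field(default_factory=lambda: DEFAULT_FMAX.copy())
    kappa: float = 0.3  #: multiplicative motor-noise scale (dimensionless)
    dt: float = 0.002  #: integration step (s)
    q_min: np.ndarray = field(default_factory=lambda: DEFAULT_Q_MIN.copy())
    q_max: np.ndarray = field(default_factory=lambda: DEFAULT_Q_MAX.copy())

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.f_max = np.asarray(self.f_max, dtype=float)
        self.q_min = np.asarray(self.q_min, dtype=float)
        self.q_max = np.asarray(self.q_max, dtype=float)
        for name in ("m1", "m2", "l1", "l2", "I1", "I2", "s1", "s2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ArmParams.{name} must be strictly positive")
        if self.A.shape != (6, 2):
            raise ValueError("ArmParams.A must be a 6x2 moment-arm matrix")
        if self.f_max.shape != (6,) or np.any(self.f_max <= 0):
            raise ValueError("ArmParams.f_max must be 6 strictly positive tensions")
        if self.B.shape != (2, 2) or not np.allclose(self.B, self.B.T):
            raise ValueError("ArmParams.B must be a symmetric 2x2 matrix")
        if np.any(np.diag(self.B) < 0):
            raise ValueError("ArmParams.B must have non-negative diagonal")
        if self.dt <= 0:
            raise ValueError("ArmParams.dt must be > 0")
        if self.kappa < 0:
            raise ValueError("ArmParams.kappa must be >= 0")
        if np.any(self.q_min >= self.q_max):
            raise ValueError("ArmParams joint bounds must satisfy q_min < q_max")

    @property
    def arm_length(self) -> float:
        """Total arm length l1 + l2 (m)."""
        return self.l1 + self.l2

    # derived inertia constants
    @property
    def k1(self) -> float:
        return self.I1 + self.I2 + self.m2 * self.l1**2

    @property
    def k2(self) -> float:
        return self.m2 * self.l1 * self.s2

    @property
    def k3(self) -> float:
        return self.I2


@dataclass
class PlantState:
    """Joint-space state: angles ``q`` (rad) and velocities ``q_dot`` (rad/s)."""

    q: np.ndarray
    q_dot: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).reshape(2)
        self.q_dot = np.asarray(self.q_dot, dtype=float).reshape(2)

    def as_vector(self) -> np.ndarray:
        """Flat 4-vector (q1, q2, q1', q2')."""
        return np.concatenate([self.q, self.q_dot])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "PlantState":
        x = np.asarray(x, dtype=float).reshape(4)
        return cls(q=x[:2], q_dot=x[2:])

    def copy(self) -> "PlantState":
        return PlantState(self.q.copy(), self.q_dot.copy())


@dataclass
class MuscleCommand:
    """Raw and noise-corrupted muscle activations, both confined to [0,1]^6."""

    u: np.ndarray
    u_noisy: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).reshape(6)
        self.u_noisy = np.asarray(self.u_noisy, dtype=float).reshape(6)
        for name, vec in (("u", self.u), ("u_noisy", self.u_noisy)):
            if np.any(vec < 0) or np.any(vec > 1):
                raise ValueError(f"MuscleCommand.{name} must lie in [0, 1]^6")


def compute_inertia(q2: float, params: ArmParams) -> np.ndarray:
    """Configuration-dependent inertia matrix M(q).

    M depends only on the elbow angle:

        M = [[k1 + 2 k2 cos(q2),  k3 + k2 cos(q2)],
             [k3 + k2 cos(q2),    k3             ]]

    with k1 = I1 + I2 + m2 l1^2, k2 = m2 l1 s2, k3 = I2.  Symmetric positive
    definite for all q2 within the joint range.
    """
    c = np.cos(q2)
    k1, k2, k3 = params.k1, params.k2, params.k3
    return np.array([[k1 + 2 * k2 * c, k3 + k2 * c], [k3 + k2 * c, k3]])


def coriolis(q: np.ndarray, q_dot: np.ndarray, params: ArmParams) -> np.ndarray:
    """Coriolis/centripetal force vector C(q, q')."""
    qd1, qd2 = q_dot
    s = params.k2 * np.sin(q[1])
    return np.array([-qd2 * (2 * qd1 + qd2) * s, qd1**2 * s])


def muscle_torque(
    u: np.ndarray,
    rng_draw: np.ndarray | None,
    params: ArmParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint torque from muscle activations with signal-dependent noise.

    The commanded activation is corrupted multiplicatively,
    ``u~ = u * (1 + kappa N(0, I))``, clamped back to the admissible box
    [0,1]^6, and converted to torque via ``tau = A^T (f_max * u~)``.

    Parameters
    ----------
    u
        Raw activation vector in [0,1]^6.
    rng_draw
        6-vector of standard-normal draws, or None for the noise-free map.

    Returns
    -------
    (torque, u_noisy)
        Joint torque (N m, 2-vector) and the clamped noisy activation.
    """
    u = np.asarray(u, dtype=float).reshape(6)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("muscle activations must lie in [0, 1]^6")
    if rng_draw is None:
        u_noisy = u.copy()
    else:
        draw = np.asarray(rng_draw, dtype=float).reshape(6)
        u_noisy = np.clip(u * (1.0 + params.kappa * draw), 0.0, 1.0)
    torque = params.A.T @ (params.f_max * u_noisy)
    return torque, u_noisy


def _clamp_bounds(q: np.ndarray, q_dot: np.ndarray, params: ArmParams) -> None:
    """Clamp joints to their range in place, zeroing velocity on contact."""
    for i in range(2):
        if q[i] < params.q_min[i]:
            q[i] = params.q_min[i]
            q_dot[i] = 0.0
        elif q[i] > params.q_max[i]:
            q[i] = params.q_max[i]
            q_dot[i] = 0.0


def step(
    state: PlantState,
    u: np.ndarray,
    params: ArmParams,
    rng: np.random.Generator | np.ndarray | None = None,
) -> tuple[PlantState, np.ndarray]:
    """Advance the plant by one time step under activation ``u``.

    ``rng`` may be a numpy Generator (a fresh 6-vector of standard normals is
    drawn), an explicit 6-vector of draws, or None for noise-free dynamics.
    Returns the new state and the noisy activation actually applied.
    Semi-implicit Euler: velocity is updated first, then position with the
    updated velocity; joint limits are enforced by clamping with the
    violating joint's velocity zeroed.
    """
    x = state.as_vector()
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite plant state")
    if isinstance(rng, np.random.Generator):
        draw = rng.standard_normal(6)
    else:
        draw = rng  # explicit draws or None
    torque, u_noisy = muscle_torque(u, draw, params)
    M = compute_inertia(state.q[1], params)
    rhs = torque - coriolis(state.q, state.q_dot, params) - params.B @ state.q_dot
    q_ddot = np.linalg.solve(M, rhs)
    q_dot = state.q_dot + q_ddot * params.dt
    q = state.q + q_dot * params.dt
    _clamp_bounds(q, q_dot, params)
    return PlantState(q, q_dot), u_noisy


def forward_kinematics(
    q: np.ndarray, params: ArmParams
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint position and Jacobian of the two-link chain.

    Returns ``(p, J)`` where ``p = (x, y)`` is the hand position and ``J`` is
    the 2x2 Jacobian mapping joint velocities to Cartesian hand velocity.
    """
    q = np.asarray(q, dtype=float).reshape(2)
    q1, q12 = q[0], q[0] + q[1]
    c1, s1 = np.cos(q1), np.sin(q1)
    c12, s12 = np.cos(q12), np.sin(q12)
    p = np.array([params.l1 * c1 + params.l2 * c12, params.l1 * s1 + params.l2 * s12])
    J = np.array(
        [
            [-params.l1 * s1 - params.l2 * s12, -params.l2 * s12],
            [params.l1 * c1 + params.l2 * c12, params.l2 * c12],
        ]
    )
    return p, J


def inverse_kinematics(p: np.ndarray, params: ArmParams) -> np.ndarray:
    """Joint angles reaching hand position ``p``, elbow-positive branch.

    Raises ``ValueError`` (naming the requested radius) if ``p`` lies outside
    the annulus ``|l1 - l2| <= |p| <= l1 + l2``.
    """
    p = np.asarray(p, dtype=float).reshape(2)
    r = float(np.hypot(p[0], p[1]))
    r_max = params.l1 + params.l2
    r_min = abs(params.l1 - params.l2)
    if r > r_max + 1e-12 or r < r_min - 1e-12:
        raise ValueError(
            f"point at radius {r:.6f} m is unreachable "
            f"(reachable annulus: [{r_min:.3f}, {r_max:.3f}] m)"
        )
    cos_q2 = (r**2 - params.l1**2 - params.l2**2) / (2 * params.l1 * params.l2)
    cos_q2 = float(np.clip(cos_q2, -1.0, 1.0))
    q2 = float(np.arccos(cos_q2))  # elbow-positive solution
    q1 = float(
        np.arctan2(p[1], p[0])
        - np.arctan2(params.l2 * np.sin(q2), params.l1 + params.l2 * np.cos(q2))
    )
    return np.array([q1, q2])


def kinetic_energy(state: PlantState, params: ArmParams) -> float:
    """Total kinetic energy 1/2 q'^T M(q) q' (J)."""
    M = compute_inertia(state.q[1], params)
    return 0.5 * float(state.q_dot @ M @ state.q_dot)
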