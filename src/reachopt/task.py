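"""Reaching task: geometry, closed-loop rollouts and the expected-utility objective.

The task mirrors a horizontal-plane reaching study: from one of 15 start
points the hand must cross a "wall" line (y = 0.6175 m, i.e. 95% of arm
length straight ahead of the shoulder) inside a target interval of width W
centered at x = 0.  Start points sit on three arcs centered on the target
at 15%, 37.5% and 60% of arm length, holding 3, 5 and 7 points spread over
+-45 degrees about the target-to-shoulder axis.

A rollout runs the loop {estimate state -> policy -> noisy plant step}
until the endpoint path crosses the wall line (the crossing point is found
by linear interpolation within the crossing step) or a timeout elapses.

The objective of a trajectory is the utility

    J = [hit] * rho * exp(-MT / gamma)  -  upsilon * sum_t ||u_t||^2 dt
        -  w_perp * (x-velocity at crossing)^2

i.e. a temporally discounted reward collected only when the target interval
is hit, minus the accumulated squared-activation effort, minus a
perpendicularity penalty on the endpoint-velocity component parallel to the
wall.  The *expected* utility of a policy is the Monte-Carlo mean of J over
independently seeded noisy rollouts; it is the quantity the policy search
maximizes, and its shape as a function of movement time is what couples the
speed-accuracy and cost-benefit trade-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .arm import ArmParams, PlantState, forward_kinematics, inverse_kinematics
from .controller import VELOCITY_SCALE, Policy
from .estimator import EstimatorConfig

__all__ = [
    "TaskLayout",
    "CostConfig",
    "Trajectory",
    "build_layout",
    "rollout",
    "utility",
    "expected_utility",
]

WALL_Y = 0.6175  #: y-coordinate of the wall line (m)
ARC_FRACTIONS = (0.15, 0.375, 0.60)  #: arc radii as fractions of arm length
POINTS_PER_ARC = (3, 5, 7)
ANGULAR_SPAN_DEG = 45.0  #: half-span of each arc about the target axis


@dataclass
class TaskLayout:
    """Target interval and start-point geometry of the reaching task."""

    wall_y: float
    target_center_x: float
    target_width: float
    start_points: np.ndarray  #: (n_start, 2) Cartesian positions (m)
    start_distance: np.ndarray  #: (n_start,) distance to the target center (m)
    start_arc: np.ndarray  #: (n_start,) arc index (0 = nearest)
    arc_fractions: tuple = ARC_FRACTIONS
    points_per_arc: tuple = POINTS_PER_ARC

    @property
    def n_starts(self) -> int:
        return len(self.start_points)

    def contains_hit(self, x: float) -> bool:
        """Whether a wall crossing at ``x`` lands inside the target interval."""
        return abs(x - self.target_center_x) <= self.target_width / 2


@dataclass
class CostConfig:
    """Weights of the expected-utility objective."""

    gamma: float = 0.6  #: reward discount time constant (s)
    rho: float = 3000.0  #: immediate reward weight
    upsilon: float = 1.0  #: effort weight
    w_perp: float = 1.0  #: perpendicularity (tangential endpoint speed) weight
    timeout: float = 4.0  #: maximum simulated movement duration (s)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("CostConfig.gamma must be > 0")
        if self.rho < 0 or self.upsilon < 0 or self.w_perp < 0:
            raise ValueError("CostConfig weights must be >= 0")
        if self.timeout <= 0:
            raise ValueError("CostConfig.timeout must be > 0")


@dataclass
class Trajectory:
    """Full record of one simulated reaching movement."""

    times: np.ndarray  #: (n+1,) time stamps (s)
    states: np.ndarray  #: (n+1, 4) joint states
    commands: np.ndarray  #: (n, 6) raw activations u_t
    noisy_commands: np.ndarray  #: (n, 6) applied activations u~_t
    path: np.ndarray  #: (n+1, 2) endpoint positions
    outcome: str  #: 'hit' | 'miss' | 'timeout'
    hit_x: float  #: wall-crossing x (m); nan on timeout
    movement_time: float  #: time of wall crossing (s); nan on timeout
    effort: float  #: sum ||u_t||^2 dt
    end_velocity: np.ndarray | None  #: endpoint (vx, vy) at crossing; None on timeout

    @property
    def hit(self) -> bool:
        return self.outcome == "hit"

    @property
    def crossed(self) -> bool:
        return self.outcome != "timeout"


def build_layout(
    arm_length: float,
    target_width: float,
    wall_y: float = WALL_Y,
    target_center_x: float = 0.0,
    arc_fractions: tuple = ARC_FRACTIONS,
    points_per_arc: tuple = POINTS_PER_ARC,
    angular_span_deg: float = ANGULAR_SPAN_DEG,
    params: ArmParams | None = None,
) -> TaskLayout:
    """Construct the start-point arcs around the target.

    Arc radii are ``fraction * arm_length`` measured from the target center;
    each arc's points are evenly spaced over +-``angular_span_deg`` about
    the target-to-shoulder axis.  Raises if a start point falls outside the
    reachable workspace of ``params`` (defaults are used when omitted).
    """
    if target_width <= 0:
        raise ValueError("target_width must be > 0")
    if params is None:
        params = ArmParams()
    target = np.array([target_center_x, wall_y])
    span = np.deg2rad(angular_span_deg)
    points, dists, arcs = [], [], []
    for arc_idx, (frac, n_pts) in enumerate(zip(arc_fractions, points_per_arc)):
        r = frac * arm_length
        angles = np.linspace(-span, span, n_pts)
        for th in angles:
            # theta = 0 points from the target straight back toward the shoulder
            p = target + r * np.array([np.sin(th), -np.cos(th)])
            radius = float(np.hypot(*p))
            if radius > params.l1 + params.l2 or radius < abs(params.l1 - params.l2):
                raise ValueError(
                    f"start point {p} (radius {radius:.3f} m) outside the workspace"
                )
            points.append(p)
            dists.append(r)
            arcs.append(arc_idx)
    return TaskLayout(
        wall_y=wall_y,
        target_center_x=target_center_x,
        target_width=target_width,
        start_points=np.array(points),
        start_distance=np.array(dists),
        start_arc=np.array(arcs, dtype=int),
        arc_fractions=tuple(arc_fractions),
        points_per_arc=tuple(points_per_arc),
    )


def rollout(
    policy: Policy,
    start: np.ndarray,
    layout: TaskLayout,
    cost_cfg: CostConfig,
    estimator_cfg: EstimatorConfig,
    params: ArmParams,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one noisy reaching movement from ``start`` (Cartesian, m)."""
    q0 = inverse_kinematics(np.asarray(start, dtype=float), params)
    x0 = np.concatenate([q0, np.zeros(2)])
    max_steps = int(round(cost_cfg.timeout / params.dt))
    noise = rng.standard_normal((max_steps, 6))
    w1, b1, w2, b2 = (np.ascontiguousarray(a) for a in policy.unpack())
    par = _kernel.pack_params(params, estimator_cfg, layout.wall_y, VELOCITY_SCALE)
    (n, states, us, uns, xy, crossed, hit_x, mt, evx, evy, effort) = _kernel.simulate(
        x0,
        w1,
        b1,
        w2,
        b2,
        np.ascontiguousarray(params.A.T),
        params.f_max,
        par,
        estimator_cfg.delay_steps,
        max_steps,
        noise,
    )
    if not np.all(np.isfinite(states[: n + 1])):
        bad = int(np.argmax(~np.isfinite(states[: n + 1]).all(axis=1)))
        raise FloatingPointError(f"non-finite dynamics at step {bad}")
    if crossed:
        outcome = "hit" if layout.contains_hit(hit_x) else "miss"
        end_velocity = np.array([evx, evy])
    else:
        outcome = "timeout"
        end_velocity = None
    return Trajectory(
        times=np.arange(n + 1) * params.dt,
        states=states[: n + 1].copy(),
        commands=us[:n].copy(),
        noisy_commands=uns[:n].copy(),
        path=xy[: n + 1].copy(),
        outcome=outcome,
        hit_x=float(hit_x),
        movement_time=float(mt),
        effort=float(effort),
        end_velocity=end_velocity,
    )


def utility(traj: Trajectory, cost_cfg: CostConfig) -> float:
    """Utility J of one trajectory (see module docstring)."""
    j = -cost_cfg.upsilon * traj.effort
    if traj.crossed:
        j -= cost_cfg.w_perp * float(traj.end_velocity[0]) ** 2
        if traj.hit:
            j += cost_cfg.rho * np.exp(-traj.movement_time / cost_cfg.gamma)
    return float(j)


def expected_utility(
    policy: Policy,
    start: np.ndarray,
    layout: TaskLayout,
    cost_cfg: CostConfig,
    estimator_cfg: EstimatorConfig,
    params: ArmParams,
    n_rollouts: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Monte-Carlo estimate of the expected utility of a policy.

    Returns ``(mean_J, hit_rate, mean_MT)``; ``mean_MT`` averages over
    wall-crossing rollouts only and is nan if none crossed.
    """
    if n_rollouts < 1:
        raise ValueError("n_rollouts must be >= 1")
    js, hits, mts = [], 0, []
    for _ in range(n_rollouts):
        traj = rollout(policy, start, layout, cost_cfg, estimator_cfg, params, rng)
        js.append(utility(traj, cost_cfg))
        hits += traj.hit
        if traj.crossed:
            mts.append(traj.movement_time)
    mean_mt = float(np.mean(mts)) if mts else float("nan")
    return float(np.mean(js)), hits / n_rollouts, mean_mt
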