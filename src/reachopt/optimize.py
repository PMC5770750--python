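"""Black-box policy search with CMA-ES over the noisy expected utility.

One independent optimization is run per (target width, start point): the
controller's flat parameter vector is searched by a
(mu/mu_w, lambda)-CMA-ES (covariance matrix adaptation evolution strategy,
Hansen's standard formulation: weighted recombination, cumulative step-size
adaptation, rank-one + rank-mu covariance updates).  Each candidate is
scored by the mean utility over ``repet`` independently seeded rollouts;
CMA-ES ranks candidates by that noisy estimate and no re-averaging across
iterations is performed.  The returned policy is the best *evaluated*
candidate, which makes the best-so-far objective non-decreasing by
construction.

Seeding is hierarchical and counter-based: the master seed fans out to
per-(iteration, candidate) rollout streams, so results are reproducible and
a candidate's rollout stream does not depend on the population size.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arm import ArmParams
from .controller import Policy, init_policy
from .estimator import EstimatorConfig
from .task import CostConfig, TaskLayout, build_layout, expected_utility, rollout, utility

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "CMAES",
    "optimize_policy",
    "evaluate_policy",
    "optimize_campaign",
    "CampaignResult",
    "save_policy",
    "load_policy",
]


@dataclass
class OptimizerConfig:
    """CMA-ES meta-parameters."""

    sigma0: float = 0.01  #: initial global step size (covariance factor)
    popsize: int = 30  #: population size lambda
    max_iter: int = 5000  #: iteration budget (sole stopping criterion)
    repet: int = 50  #: rollouts per candidate evaluation

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("OptimizerConfig.sigma0 must be > 0")
        if self.popsize < 2:
            raise ValueError("OptimizerConfig.popsize must be >= 2")
        if self.max_iter < 1:
            raise ValueError("OptimizerConfig.max_iter must be >= 1")
        if self.repet < 1:
            raise ValueError("OptimizerConfig.repet must be >= 1")


@dataclass
class OptimizationTrace:
    """Per-iteration progress record of one policy search."""

    iteration: list = field(default_factory=list)
    best_J: list = field(default_factory=list)  #: best candidate of the iteration
    mean_J: list = field(default_factory=list)  #: population mean
    best_so_far_J: list = field(default_factory=list)
    hit_rate: list = field(default_factory=list)  #: of the iteration's best candidate
    mean_mt: list = field(default_factory=list)

    def append(self, it, best, mean, best_so_far, hit_rate, mean_mt) -> None:
        self.iteration.append(it)
        self.best_J.append(best)
        self.mean_J.append(mean)
        self.best_so_far_J.append(best_so_far)
        self.hit_rate.append(hit_rate)
        self.mean_mt.append(mean_mt)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "best_J": self.best_J,
                "mean_J": self.mean_J,
                "best_so_far_J": self.best_so_far_J,
                "hit_rate": self.hit_rate,
                "mean_mt": self.mean_mt,
            }
        )


class CMAES:
    """Minimalist (mu/mu_w, lambda)-CMA-ES minimizer.

    Implements weighted recombination of the best half of the population,
    cumulative step-size adaptation (CSA) and the rank-one plus rank-mu
    covariance update with standard default learning rates.
    """

    def __init__(
        self,
        x0: np.ndarray,
        sigma0: float,
        popsize: int,
        rng: np.random.Generator,
    ):
        self.n = len(x0)
        n = self.n
        self.rng = rng
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.lam = int(popsize)
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)
        self.c_sigma = (self.mueff + 2) / (n + self.mueff + 5)
        self.d_sigma = (
            1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.c_sigma
        )
        self.c_c = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.c_1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.c_mu = min(
            1 - self.c_1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))
        self.p_sigma = np.zeros(n)
        self.p_c = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.count_iter = 0

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2
        d2, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d2, 1e-20))

    def ask(self) -> np.ndarray:
        """Sample a new population, shape (popsize, n)."""
        z = self.rng.standard_normal((self.lam, self.n))
        self._last_z = z
        y = z @ (self.B * self.D).T  # y ~ N(0, C)
        self._last_y = y
        return self.mean + self.sigma * y

    def tell(self, solutions: np.ndarray, fvals: np.ndarray) -> None:
        """Update the distribution from objective values (minimization)."""
        fvals = np.asarray(fvals, dtype=float)
        if not np.any(np.isfinite(fvals)):
            raise RuntimeError("CMA-ES: all candidate objectives are non-finite")
        order = np.argsort(fvals)
        sel = order[: self.mu]
        y_sel = (solutions[sel] - self.mean) / self.sigma
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w

        # CSA step-size path (C^-1/2 applied through the eigenbasis)
        c_inv_half_yw = self.B @ ((self.B.T @ y_w) / self.D)
        self.p_sigma = (1 - self.c_sigma) * self.p_sigma + np.sqrt(
            self.c_sigma * (2 - self.c_sigma) * self.mueff
        ) * c_inv_half_yw
        self.count_iter += 1
        h_sig = float(
            np.linalg.norm(self.p_sigma)
            / np.sqrt(1 - (1 - self.c_sigma) ** (2 * self.count_iter))
            < (1.4 + 2 / (self.n + 1)) * self.chi_n
        )
        self.p_c = (1 - self.c_c) * self.p_c + h_sig * np.sqrt(
            self.c_c * (2 - self.c_c) * self.mueff
        ) * y_w

        rank_mu = (y_sel * self.weights[:, None]).T @ y_sel
        self.C = (
            (1 - self.c_1 - self.c_mu) * self.C
            + self.c_1
            * (
                np.outer(self.p_c, self.p_c)
                + (1 - h_sig) * self.c_c * (2 - self.c_c) * self.C
            )
            + self.c_mu * rank_mu
        )
        self.sigma *= np.exp(
            (self.c_sigma / self.d_sigma)
            * (np.linalg.norm(self.p_sigma) / self.chi_n - 1)
        )
        self._decompose()


def _child_seed(*entropy) -> np.random.Generator:
    """Deterministic child generator from a tuple of small integers."""
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def optimize_policy(
    start: np.ndarray,
    layout: TaskLayout,
    cost_cfg: CostConfig,
    estimator_cfg: EstimatorConfig,
    params: ArmParams,
    opt_cfg: OptimizerConfig,
    seed: int,
    n_hidden: int = 10,
    progress: bool = False,
) -> tuple[Policy, OptimizationTrace]:
    """CMA-ES search for the policy maximizing expected utility at one start.

    Fully reproducible from ``(configs, seed)``.  Each candidate in each
    iteration is scored with ``repet`` rollouts drawn from its own RNG
    stream keyed by (seed, iteration, candidate index).
    """
    policy0 = init_policy(_child_seed(seed, 0), n_hidden)
    es = CMAES(policy0.theta, opt_cfg.sigma0, opt_cfg.popsize, _child_seed(seed, 1))

    def score(theta: np.ndarray, it: int, ci: int):
        rng = _child_seed(seed, 2, it, ci)
        return expected_utility(
            Policy(n_hidden, theta), start, layout, cost_cfg, estimator_cfg,
            params, opt_cfg.repet, rng,
        )

    # baseline: the random initial policy, scored like any candidate
    j0, hr0, mt0 = score(policy0.theta, 0, 0)
    best_theta = policy0.theta.copy()
    best_j = j0
    trace = OptimizationTrace()
    trace.append(0, j0, j0, best_j, hr0, mt0)

    t_start = time.time()
    for it in range(1, opt_cfg.max_iter + 1):
        X = es.ask()
        js = np.empty(opt_cfg.popsize)
        hrs = np.empty(opt_cfg.popsize)
        mts = np.empty(opt_cfg.popsize)
        for ci in range(opt_cfg.popsize):
            js[ci], hrs[ci], mts[ci] = score(X[ci], it, ci)
        es.tell(X, -js)
        i_best = int(np.argmax(js))
        if js[i_best] > best_j:
            best_j = float(js[i_best])
            best_theta = X[i_best].copy()
        trace.append(
            it, float(js[i_best]), float(np.mean(js)), best_j,
            float(hrs[i_best]), float(mts[i_best]),
        )
        if progress and (it % 10 == 0 or it == opt_cfg.max_iter):
            print(
                f"iter {it:4d}  best J {js[i_best]:9.2f}  best-so-far {best_j:9.2f}"
                f"  hit rate {hrs[i_best]:.2f}  mean MT {mts[i_best]:.3f}"
                f"  [{time.time() - t_start:.1f}s]"
            )
    return Policy(n_hidden, best_theta), trace


def evaluate_policy(
    policy: Policy,
    start: np.ndarray,
    layout: TaskLayout,
    cost_cfg: CostConfig,
    estimator_cfg: EstimatorConfig,
    params: ArmParams,
    n_rollouts: int,
    rng: np.random.Generator,
    keep_trajectories: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list]:
    """Roll out a policy repeatedly and tabulate per-trial statistics.

    Returns a DataFrame with one row per rollout (outcome, hit position,
    movement time, effort, utility and velocity-profile summaries); with
    ``keep_trajectories`` the Trajectory objects are returned as well.
    """
    from .analysis import velocity_profile  # analysis sits above task in the stack

    rows, trajs = [], []
    for k in range(n_rollouts):
        traj = rollout(policy, start, layout, cost_cfg, estimator_cfg, params, rng)
        row = {
            "rollout": k,
            "outcome": traj.outcome,
            "hit": traj.hit,
            "hit_x": traj.hit_x,
            "mt": traj.movement_time,
            "effort": traj.effort,
            "J": utility(traj, cost_cfg),
        }
        if traj.crossed:
            vp = velocity_profile(traj)
            row.update(
                peak_speed=vp.peak_speed,
                t_peak=vp.time_of_peak,
                end_speed=vp.endpoint_speed,
                asymmetry=vp.asymmetry,
                end_vx=float(traj.end_velocity[0]),
            )
        else:
            row.update(
                peak_speed=np.nan, t_peak=np.nan, end_speed=np.nan,
                asymmetry=np.nan, end_vx=np.nan,
            )
        rows.append(row)
        if keep_trajectories:
            trajs.append(traj)
    df = pd.DataFrame(rows)
    return (df, trajs) if keep_trajectories else df


def save_policy(path, policy: Policy, metadata: dict | None = None) -> None:
    """Serialize a policy (flat parameters + metadata) as JSON."""
    payload = {"n_hidden": policy.n_hidden, "theta": policy.theta.tolist()}
    payload.update(metadata or {})
    Path(path).write_text(json.dumps(payload))


def load_policy(path) -> tuple[Policy, dict]:
    """Load a policy saved by :func:`save_policy`; returns (policy, metadata)."""
    payload = json.loads(Path(path).read_text())
    policy = Policy(payload.pop("n_hidden"), np.array(payload.pop("theta")))
    return policy, payload


@dataclass
class CampaignResult:
    """Outcome of a multi-(width, start) optimization campaign."""

    policies: dict  #: (width, start_id) -> Policy
    trials: pd.DataFrame  #: evaluation rollouts, one row per trajectory
    traces: dict  #: (width, start_id) -> OptimizationTrace or trace DataFrame


def optimize_campaign(
    target_widths,
    cost_cfg: CostConfig,
    estimator_cfg: EstimatorConfig,
    params: ArmParams,
    opt_cfg: OptimizerConfig,
    seed: int,
    start_ids=None,
    n_hidden: int = 10,
    eval_rollouts: int = 100,
    out_dir=None,
    progress: bool = False,
) -> CampaignResult:
    """Independent policy optimizations for every (target width, start point).

    With all 15 starts and ``eval_rollouts=100``, the evaluation set holds
    1,500 trajectories per target width.  When ``out_dir`` is given the
    campaign is resumable: each finished optimization saves its policy and
    trace, and existing policy files are loaded instead of re-optimized.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "policies").mkdir(parents=True, exist_ok=True)
        (out_path / "traces").mkdir(parents=True, exist_ok=True)

    policies, traces = {}, {}
    all_trials = []
    for wi, width in enumerate(target_widths):
        layout = build_layout(params.arm_length, width, params=params)
        ids = range(layout.n_starts) if start_ids is None else start_ids
        for si in ids:
            start = layout.start_points[si]
            tag = f"w{width:g}_s{si}"
            pol_file = out_path / "policies" / f"{tag}.json" if out_path else None
            run_seed = int(
                np.random.SeedSequence([seed, wi, si]).generate_state(1)[0] % 2**31
            )
            if pol_file is not None and pol_file.exists():
                policy, _ = load_policy(pol_file)
                trace = None
            else:
                if progress:
                    print(f"optimizing W={width} start={si} (seed {run_seed})")
                policy, trace = optimize_policy(
                    start, layout, cost_cfg, estimator_cfg, params, opt_cfg,
                    run_seed, n_hidden, progress=progress,
                )
                if pol_file is not None:
                    save_policy(
                        pol_file, policy,
                        {"target_width": width, "start_id": int(si), "seed": run_seed},
                    )
                    trace.to_dataframe().to_csv(
                        out_path / "traces" / f"{tag}.csv", index=False
                    )
            policies[(width, si)] = policy
            traces[(width, si)] = trace

            eval_rng = _child_seed(seed, 1000, wi, si)
            df = evaluate_policy(
                policy, start, layout, cost_cfg, estimator_cfg, params,
                eval_rollouts, eval_rng,
            )
            df.insert(0, "width", width)
            df.insert(1, "start_id", si)
            df.insert(2, "distance", layout.start_distance[si])
            df.insert(3, "arc", layout.start_arc[si])
            all_trials.append(df)

    trials = pd.concat(all_trials, ignore_index=True)
    if out_path is not None:
        trials.to_csv(out_path / "trials.csv", index=False)
    return CampaignResult(policies=policies, trials=trials, traces=traces)
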