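"""Behavioral statistics: Fitts regression, dispersion, KL, velocity profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from reachopt import (
    Trajectory,
    dispersion_summary,
    fitts_fit,
    kl_divergence,
    normalized_tables,
    velocity_profile,
)

DISTANCES = (0.0975, 0.24375, 0.39)
WIDTHS = (0.005, 0.01, 0.02, 0.04)


def _cell_trials(mt_fn, peak_fn=None, n=5):
    rows = []
    for d in DISTANCES:
        for w in WIDTHS:
            for _ in range(n):
                rows.append({
                    "distance": d, "width": w, "outcome": "hit", "hit": True,
                    "mt": mt_fn(d, w),
                    "peak_speed": peak_fn(d, w) if peak_fn else 1.0,
                })
    return pd.DataFrame(rows)


class TestFitts:
    def test_recovers_exact_linear_law(self):
        trials = _cell_trials(lambda d, w: 0.1 * np.log2(d / w) + 0.05)
        fit = fitts_fit(trials)
        assert fit.a == pytest.approx(0.1, abs=1e-12)
        assert fit.b == pytest.approx(0.05, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert len(fit.points) == 12

    def test_index_of_difficulty_value(self):
        trials = _cell_trials(lambda d, w: 0.1)
        fit = fitts_fit(trials)
        hardest = fit.points.loc[
            (fit.points["distance"] == 0.39) & (fit.points["width"] == 0.005), "ID"
        ].item()
        assert hardest == pytest.approx(np.log2(78), abs=1e-12)
        assert hardest == pytest.approx(6.285, abs=1e-3)

    def test_matches_normal_equations_oracle(self, rng):
        trials = _cell_trials(lambda d, w: 0.0)
        trials["mt"] = rng.uniform(0.1, 1.0, len(trials))
        fit = fitts_fit(trials)
        cells = trials.groupby(["distance", "width"])["mt"].mean().reset_index()
        x = np.log2(cells["distance"] / cells["width"])
        X = np.column_stack([x, np.ones(len(x))])
        beta = np.linalg.solve(X.T @ X, X.T @ cells["mt"])
        assert fit.a == pytest.approx(beta[0], abs=1e-10)
        assert fit.b == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_design_rejected(self):
        one_cell = pd.DataFrame({
            "distance": [0.39] * 5, "width": [0.01] * 5, "hit": True,
            "outcome": "hit", "mt": np.linspace(0.1, 0.2, 5),
        })
        with pytest.raises(ValueError, match="ID"):
            fitts_fit(one_cell)


class TestDispersion:
    def test_all_hits_at_center(self):
        summ = dispersion_summary(np.zeros(50), width=0.01)
        assert summ.gauss_mu == pytest.approx(0.0, abs=1e-9)
        assert summ.peak_offset_pct == pytest.approx(0.0, abs=1e-6)
        assert summ.hit_rate == 1.0
        assert summ.counts.sum() == 50

    @pytest.mark.parametrize("method", ["histogram", "ml"])
    def test_recovers_known_gaussian(self, method, rng):
        mu, sigma = 0.001, 0.003
        hits = rng.normal(mu, sigma, 10_000)
        summ = dispersion_summary(hits, width=0.01, method=method)
        assert summ.gauss_mu == pytest.approx(mu, rel=0.05)
        assert summ.gauss_sigma == pytest.approx(sigma, rel=0.05)

    def test_recovery_is_stable_across_seeds(self):
        # parameter recovery within 5% over many independent replications
        for seed in range(100):
            rng = np.random.default_rng(seed)
            hits = rng.normal(0.001, 0.003, 5_000)
            summ = dispersion_summary(hits, width=0.01)
            assert summ.gauss_sigma == pytest.approx(0.003, rel=0.05)

    def test_hit_rate_counts_target_interval(self):
        hits = np.array([-0.006, -0.001, 0.0, 0.002, 0.03])
        summ = dispersion_summary(hits, width=0.01)
        assert summ.hit_rate == pytest.approx(3 / 5)

    def test_zero_crossings_rejected(self):
        with pytest.raises(ValueError):
            dispersion_summary(np.array([]), width=0.01)


class TestKL:
    def test_identical_gaussians(self):
        assert kl_divergence(0.3, 1.2, 0.3, 1.2) == pytest.approx(0.0, abs=1e-15)

    def test_unit_shift_closed_form(self):
        assert kl_divergence(0.0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_asymmetric(self):
        assert kl_divergence(0, 1, 0, 2) != pytest.approx(kl_divergence(0, 2, 0, 1))

    def test_matches_numerical_quadrature(self, rng):
        for _ in range(10):
            pm, qm = rng.normal(0, 1, 2)
            ps, qs = rng.uniform(0.5, 2.0, 2)
            p = stats.norm(pm, ps)
            q = stats.norm(qm, qs)
            integrand = lambda x: p.pdf(x) * (p.logpdf(x) - q.logpdf(x))
            num, _ = integrate.quad(integrand, -30, 30, limit=200)
            assert kl_divergence(pm, ps, qm, qs) == pytest.approx(num, abs=1e-6)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            kl_divergence(0, 0.0, 0, 1.0)


def _straight_traj(speed=0.5, n=100, dt=0.002):
    # pure shoulder rotation: endpoint speed is constant |l1+l2| * qd1
    from reachopt import ArmParams

    p = ArmParams()
    qd1 = speed / p.arm_length
    times = np.arange(n + 1) * dt
    states = np.column_stack([
        np.pi / 4 + qd1 * times, np.zeros(n + 1),
        np.full(n + 1, qd1), np.zeros(n + 1),
    ])
    from reachopt.arm import forward_kinematics

    path = np.array([forward_kinematics(s[:2], p)[0] for s in states])
    vx, vy = forward_kinematics(states[-1, :2], p)[1] @ states[-1, 2:]
    return Trajectory(
        times=times, states=states, commands=np.zeros((n, 6)),
        noisy_commands=np.zeros((n, 6)), path=path, outcome="hit",
        hit_x=path[-1, 0], movement_time=times[-1], effort=0.0,
        end_velocity=np.array([vx, vy]),
    )


class TestVelocityProfile:
    def test_constant_speed_profile_conventions(self):
        vp = velocity_profile(_straight_traj())
        assert vp.peak_speed == pytest.approx(0.5, rel=1e-9)
        assert vp.endpoint_speed == pytest.approx(0.5, rel=1e-9)
        assert vp.asymmetry == 0.5  # flat profile convention

    def test_timeout_rejected(self):
        traj = _straight_traj()
        traj.outcome = "timeout"
        with pytest.raises(ValueError, match="timed-out"):
            velocity_profile(traj)


class TestNormalizedTables:
    def test_reference_cell_is_one(self):
        trials = _cell_trials(
            mt_fn=lambda d, w: 0.1 * np.log2(d / w) + 0.05,
            peak_fn=lambda d, w: d * (1 + w),
        )
        peak_tab, mt_tab = normalized_tables(trials)
        assert peak_tab.iloc[0, 0] == pytest.approx(1.0)
        assert mt_tab.iloc[0, 0] == pytest.approx(1.0)
        assert peak_tab.shape == (3, 4) and mt_tab.shape == (3, 4)

    def test_expected_monotonicity_directions(self):
        trials = _cell_trials(
            mt_fn=lambda d, w: 0.1 * np.log2(d / w) + 0.05,
            peak_fn=lambda d, w: 2 * d + 5 * w,
        )
        peak_tab, mt_tab = normalized_tables(trials)
        # MT decreases across widths (rows), peak speed grows with distance
        assert np.all(np.diff(mt_tab.to_numpy(), axis=1) < 0)
        assert np.all(np.diff(peak_tab.to_numpy(), axis=0) > 0)

    def test_empty_cell_named_in_error(self):
        trials = _cell_trials(lambda d, w: 0.1)
        trials = trials[~((trials.distance == 0.39) & (trials.width == 0.02))]
        with pytest.raises(ValueError, match="0.39"):
            normalized_tables(trials)
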