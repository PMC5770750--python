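"""Behavioral statistics of reaching: Fitts' law, velocity profiles, hit dispersion.

All operations are pure functions of a trial table (one row per trajectory,
as produced by :func:`reachopt.optimize.evaluate_policy`) or of individual
:class:`~reachopt.task.Trajectory` objects, so re-running the analysis never
touches the simulator RNG.  The same statistics can be applied to any
externally recorded trial table with the same columns
(``width``, ``distance``, ``mt``, ``hit_x``, ``outcome``/``hit`` ...).

* Fitts' law: mean movement time per (distance, width) cell regressed on
  the index of difficulty ID = log2(D / W) by ordinary least squares.
* Hit dispersion: wall-crossing positions binned at 0.5 mm around the
  target center; a Gaussian is fitted to the bin counts by least squares
  (maximum likelihood on the raw hits is available as an option), and the
  fitted peak location is expressed as a percentage of target width.
* Velocity profiles: endpoint Cartesian speed over time; peak speed, time
  of peak, terminal speed and the asymmetry ratio time-of-peak / MT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats

from .arm import ArmParams, forward_kinematics
from .task import Trajectory

__all__ = [
    "FittsFit",
    "DispersionSummary",
    "VelocityProfile",
    "fitts_fit",
    "dispersion_summary",
    "kl_divergence",
    "velocity_profile",
    "normalized_tables",
]

HIST_BIN_WIDTH = 0.0005  #: dispersion histogram bin width (m)


@dataclass
class FittsFit:
    """OLS fit of mean movement time against the index of difficulty."""

    points: pd.DataFrame  #: one row per (distance, width): ID, mean_mt, n
    a: float  #: slope (s/bit)
    b: float  #: intercept (s)
    r_squared: float


@dataclass
class DispersionSummary:
    """Histogram and Gaussian summary of wall-crossing positions."""

    bin_edges: np.ndarray  #: (n_bins+1,) edges (m), centered on the target
    counts: np.ndarray  #: (n_bins,) crossings per bin
    gauss_mu: float  #: fitted Gaussian mean (m)
    gauss_sigma: float  #: fitted Gaussian SD (m)
    hit_rate: float  #: fraction of crossings inside the target interval
    peak_offset_pct: float  #: 100 * (gauss_mu - center) / width


@dataclass
class VelocityProfile:
    """Endpoint-speed summary of one completed movement."""

    times: np.ndarray
    speed: np.ndarray  #: endpoint Cartesian speed (m/s)
    peak_speed: float
    time_of_peak: float
    endpoint_speed: float  #: speed at the wall crossing
    asymmetry: float  #: time_of_peak / movement time


def fitts_fit(trials: pd.DataFrame, include_misses: bool = True) -> FittsFit:
    """Fit MT = a * log2(D / W) + b over (distance, width) cell means.

    Uses completed (wall-crossing) movements; by default both hits and
    misses enter the cell means, ``include_misses=False`` restricts to hits.
    Raises on a degenerate design with fewer than two distinct ID values.
    """
    df = trials
    if "outcome" in df.columns:
        df = df[df["outcome"] != "timeout"]
    if not include_misses:
        df = df[df["hit"]]
    cells = (
        df.groupby(["distance", "width"], as_index=False)
        .agg(mean_mt=("mt", "mean"), n=("mt", "size"))
    )
    cells["ID"] = np.log2(cells["distance"] / cells["width"])
    if cells["ID"].nunique() < 2:
        raise ValueError("Fitts regression needs >= 2 distinct ID values")
    res = sp_stats.linregress(cells["ID"], cells["mean_mt"])
    return FittsFit(
        points=cells,
        a=float(res.slope),
        b=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def dispersion_summary(
    hits: np.ndarray,
    width: float,
    center: float = 0.0,
    bin_width: float = HIST_BIN_WIDTH,
    method: str = "histogram",
) -> DispersionSummary:
    """Summarize wall-crossing positions around the target.

    ``hits`` are crossing x-coordinates (m).  Binning is fixed at
    ``bin_width`` with a bin edge placed symmetrically about ``center``.
    ``method='histogram'`` fits a Gaussian to the bin counts by least
    squares (falling back to sample moments when the fit is degenerate);
    ``method='ml'`` uses sample mean/SD of the raw crossings directly.
    """
    hits = np.asarray(hits, dtype=float)
    if hits.size == 0:
        raise ValueError("no wall crossings to summarize")
    half_span = max(np.max(np.abs(hits - center)), width) + bin_width
    n_half = int(np.ceil(half_span / bin_width))
    edges = center + bin_width * np.arange(-n_half, n_half + 1)
    counts, _ = np.histogram(hits, bins=edges)
    mu_ml = float(np.mean(hits))
    sigma_ml = float(np.std(hits))
    sigma_floor = bin_width / np.sqrt(12.0)  # resolution limit of the binning
    if method == "ml":
        mu, sigma = mu_ml, max(sigma_ml, sigma_floor)
    elif method == "histogram":
        centers = (edges[:-1] + edges[1:]) / 2
        try:
            popt, _ = sp_optimize.curve_fit(
                _gaussian,
                centers,
                counts,
                p0=[max(counts.max(), 1.0), mu_ml, max(sigma_ml, sigma_floor)],
                maxfev=10000,
            )
            mu, sigma = float(popt[1]), abs(float(popt[2]))
            if not np.isfinite(mu) or not np.isfinite(sigma) or sigma <= 0:
                raise RuntimeError
        except RuntimeError:
            mu, sigma = mu_ml, max(sigma_ml, sigma_floor)
        sigma = max(sigma, sigma_floor)
    else:
        raise ValueError(f"unknown dispersion fit method: {method!r}")
    hit_rate = float(np.mean(np.abs(hits - center) <= width / 2))
    return DispersionSummary(
        bin_edges=edges,
        counts=counts,
        gauss_mu=mu,
        gauss_sigma=sigma,
        hit_rate=hit_rate,
        peak_offset_pct=100.0 * (mu - center) / width,
    )


def kl_divergence(p_mu: float, p_sigma: float, q_mu: float, q_sigma: float) -> float:
    """Closed-form KL divergence KL(N(p_mu, p_sigma^2) || N(q_mu, q_sigma^2))."""
    if p_sigma <= 0 or q_sigma <= 0:
        raise ValueError("Gaussian standard deviations must be > 0")
    return float(
        np.log(q_sigma / p_sigma)
        + (p_sigma**2 + (p_mu - q_mu) ** 2) / (2 * q_sigma**2)
        - 0.5
    )


def velocity_profile(traj: Trajectory, params: ArmParams | None = None) -> VelocityProfile:
    """Endpoint-speed time series and summary of a completed movement.

    The speed at each stored state is the norm of the Jacobian-mapped joint
    velocity.  A flat (constant-speed) profile has no meaningful peak time;
    its asymmetry is reported as 0.5 by convention.  Raises on timeouts.
    """
    if not traj.crossed:
        raise ValueError("velocity profile undefined for a timed-out trajectory")
    if params is None:
        params = ArmParams()
    n = len(traj.times)
    speed = np.empty(n)
    for i in range(n):
        _, jac = forward_kinematics(traj.states[i, :2], params)
        speed[i] = np.linalg.norm(jac @ traj.states[i, 2:])
    i_peak = int(np.argmax(speed))
    peak = float(speed[i_peak])
    flat = peak - speed.min() < 1e-12
    mt = traj.movement_time
    t_peak = mt / 2 if flat else float(traj.times[i_peak])
    end_speed = float(np.linalg.norm(traj.end_velocity))
    asym = 0.5 if flat else (t_peak / mt if mt > 0 else 0.5)
    return VelocityProfile(
        times=traj.times,
        speed=speed,
        peak_speed=peak,
        time_of_peak=t_peak,
        endpoint_speed=end_speed,
        asymmetry=float(asym),
    )


def normalized_tables(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance x width tables of peak speed and MT, normalized to one cell.

    Rows are the distinct distances (ascending: short, medium, long),
    columns the distinct widths (ascending).  Each cell is the mean over
    completed movements, divided by the (shortest distance, smallest width)
    reference cell, which is therefore 1.00 by construction.  Raises,
    naming the cell, if any (distance, width) combination has no data.
    """
    df = trials
    if "outcome" in df.columns:
        df = df[df["outcome"] != "timeout"]
    distances = np.sort(df["distance"].unique())
    widths = np.sort(df["width"].unique())
    tables = {}
    for col in ("peak_speed", "mt"):
        tab = pd.DataFrame(index=distances, columns=widths, dtype=float)
        for d in distances:
            for w in widths:
                cell = df[(df["distance"] == d) & (df["width"] == w)][col].dropna()
                if cell.empty:
                    raise ValueError(f"empty cell: distance={d}, width={w}")
                tab.loc[d, w] = cell.mean()
        tables[col] = tab / tab.iloc[0, 0]
    return tables["peak_speed"], tables["mt"]


# ---------------------------------------------------------------------------
# plotting (report figures; lazy matplotlib import keeps headless use light)


def plot_fitts(fit: FittsFit, ax=None):
    """Mean MT against ID with the fitted regression line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(fit.points["ID"], fit.points["mean_mt"], color="k")
    grid = np.linspace(fit.points["ID"].min(), fit.points["ID"].max(), 50)
    ax.plot(grid, fit.a * grid + fit.b, "r-",
            label=f"MT = {fit.a:.3f} ID + {fit.b:.3f} (r$^2$={fit.r_squared:.2f})")
    ax.set_xlabel("index of difficulty (bits)")
    ax.set_ylabel("movement time (s)")
    ax.legend()
    return ax


def plot_dispersion(summary: DispersionSummary, width: float, ax=None):
    """Hit histogram with the fitted Gaussian and target boundaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = (summary.bin_edges[:-1] + summary.bin_edges[1:]) / 2
    ax.bar(centers * 1000, summary.counts, width=0.5, color="navy")
    grid = np.linspace(summary.bin_edges[0], summary.bin_edges[-1], 400)
    amp = summary.counts.max()
    ax.plot(grid * 1000, _gaussian(grid, amp, summary.gauss_mu, summary.gauss_sigma),
            color="skyblue", lw=2)
    for b in (-width / 2, width / 2):
        ax.axvline(b * 1000, color="r")
    ax.set_xlabel("hit position (mm)")
    ax.set_ylabel("count")
    return ax


def plot_velocity_profiles(trajectories, params: ArmParams | None = None, ax=None):
    """Overlay endpoint-speed profiles of completed movements."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for traj in trajectories:
        if not traj.crossed:
            continue
        vp = velocity_profile(traj, params)
        ax.plot(vp.times, vp.speed, alpha=0.3, color="tab:blue")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("endpoint speed (m/s)")
    return ax
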