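"""Nanoparticle-tracking-analysis physics on simulated Brownian trajectories.

Dark-field nanoparticle tracking determines particle size from the mean
squared displacement (MSD) of camera-plane Brownian trajectories via the
Stokes–Einstein relation, and zeta potential from electrophoretic mobility
via the Smoluchowski approximation with the chamber's electro-osmotic flow
removed by multi-depth velocity profiling.  This module implements that
chain on simulated 2-D tracks:

* Brownian simulation: Gaussian increments of variance 2*D*dt per axis at a
  fixed frame interval (default 1/33 s, the camera frame rate), plus
  optional drift and depth-dependent flow.
* MSD over all overlapping lag pairs; in 2-D, MSD(tau) = 4*D*tau, so D is a
  quarter of the fitted slope (free intercept absorbs localisation noise).
* Sizing: d = k_B*T / (3*pi*eta*D).
* Electro-osmotic correction: the apparent velocity across normalised depth
  z in [0, 1] is fitted with a quadratic; in a closed cell the net flow is
  zero, so the depth average of the fitted profile is the particle's true
  electrophoretic velocity.
* Zeta: mu = v_ep / E, zeta = mu*eta / (eps_r*eps_0), sign preserved.
* Submicron ("ultrafine", ISO/TC281) classification: diameter < 1 um strict.

Positions are in microns and lag times in seconds throughout; sizing and
zeta formulas work in SI internally with explicit unit helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "MediumParams",
    "Trajectory",
    "ParticleEstimate",
    "simulate_brownian",
    "msd",
    "ensemble_msd",
    "diffusion_from_msd",
    "stokes_einstein_diameter",
    "electroosmotic_correction",
    "smoluchowski_zeta",
    "mobility_to_zeta",
    "einstein_consistency_check",
    "classify_submicron",
    "estimate_particles",
    "read_trajectories",
    "write_trajectories",
    "DEFAULT_DT_S",
]

K_B = constants.Boltzmann
EPS_0 = constants.epsilon_0
DEFAULT_DT_S = 1.0 / 33.0  # camera frame interval at 33 fps

UM2_S_TO_M2_S = 1e-12
M_TO_NM = 1e9
V_TO_MV = 1e3


@dataclass(frozen=True)
class MediumParams:
    """Suspending-medium parameters for sizing and zeta conversion.

    Defaults: 298.15 K (room temperature), water-like viscosity
    8.9e-4 Pa·s, relative permittivity 78.5.  Viscosity is not adjusted for
    temperature automatically; pass the value appropriate for T.
    """

    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4
    relative_permittivity: float = 78.5

    def __post_init__(self) -> None:
        if min(self.temperature_K, self.viscosity_Pa_s,
               self.relative_permittivity) <= 0:
            raise ValueError("all medium parameters must be positive")


@dataclass
class Trajectory:
    """2-D particle track: positions (um) at a fixed frame interval (s)."""

    particle_id: int
    positions_um: np.ndarray  # (n, 2)
    dt_s: float = DEFAULT_DT_S
    depth: float | None = None  # normalised chamber depth in [0, 1]

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.ndim != 2 or self.positions_um.shape[1] != 2:
            raise ValueError("positions_um must be an (n, 2) array")
        if len(self.positions_um) < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not np.all(np.isfinite(self.positions_um)):
            raise ValueError("positions must be finite")

    @property
    def duration_s(self) -> float:
        return (len(self.positions_um) - 1) * self.dt_s


@dataclass(frozen=True)
class ParticleEstimate:
    """Per-particle results: D, hydrodynamic diameter, mobility, zeta."""

    particle_id: int
    D_um2_s: float
    diameter_nm: float | None
    mobility_m2_Vs: float | None = None
    zeta_mV: float | None = None

    @property
    def is_submicron(self) -> bool | None:
        if self.diameter_nm is None:
            return None
        return classify_submicron(self.diameter_nm)


def simulate_brownian(
    n_particles: int,
    d_um2_s: float,
    *,
    dt_s: float = DEFAULT_DT_S,
    n_steps: int = 300,
    drift_um_s: tuple[float, float] = (0.0, 0.0),
    depth_profile: Callable[[float], float] | None = None,
    seed: int | None = None,
) -> list[Trajectory]:
    """Simulate 2-D Brownian tracks with optional drift and depth-dependent flow.

    Each step adds Gaussian increments of variance ``2*d_um2_s*dt_s`` per
    axis plus ``drift_um_s * dt_s``.  With ``depth_profile`` each particle is
    assigned a uniform random depth z in [0, 1] and ``depth_profile(z)`` is
    added to the x-velocity — the geometry of electro-osmotic flow along the
    field axis of a closed measurement cell.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if d_um2_s < 0:
        raise ValueError("d_um2_s must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * d_um2_s * dt_s)
    out = []
    for pid in range(n_particles):
        z = float(rng.uniform(0.0, 1.0)) if depth_profile is not None else None
        v = np.array(drift_um_s, dtype=float)
        if depth_profile is not None:
            v = v + np.array([depth_profile(z), 0.0])
        steps = rng.normal(0.0, sigma, size=(n_steps, 2)) + v * dt_s
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        out.append(Trajectory(pid, pos, dt_s, depth=z))
    return out


def msd(trajectory: Trajectory, max_lag: int) -> np.ndarray:
    """MSD(tau) for lags 1..max_lag over all overlapping displacement pairs."""
    n = len(trajectory.positions_um)
    if not 1 <= max_lag < n:
        raise ValueError(f"max_lag must be in [1, {n - 1}]")
    pos = trajectory.positions_um
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = pos[lag:] - pos[:-lag]
        out[lag - 1] = np.mean(np.sum(disp**2, axis=1))
    return out


def ensemble_msd(trajectories: Sequence[Trajectory], max_lag: int) -> np.ndarray:
    """Mean of per-trajectory MSD curves (equal trajectory weighting)."""
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    return np.mean([msd(t, max_lag) for t in trajectories], axis=0)


def diffusion_from_msd(
    msd_um2: np.ndarray,
    dt_s: float = DEFAULT_DT_S,
    n_fit_lags: int | None = None,
) -> float:
    """D (um²/s) from the slope of a line fitted through the first MSD lags.

    The intercept is free, so a constant localisation-noise offset does not
    bias D.  ``n_fit_lags`` defaults to the first 25% of lags (minimum 2) to
    limit the correlation bias of overlapping displacements.  A negative
    fitted slope is clamped to D = 0 with a warning.
    """
    msd_um2 = np.asarray(msd_um2, dtype=float)
    if len(msd_um2) < 2:
        raise ValueError("need at least 2 MSD lags to fit a slope")
    if n_fit_lags is None:
        n_fit_lags = max(2, len(msd_um2) // 4)
    n_fit_lags = min(n_fit_lags, len(msd_um2))
    if n_fit_lags < 2:
        raise ValueError("n_fit_lags must be >= 2")
    tau = dt_s * np.arange(1, n_fit_lags + 1)
    slope, _ = np.polyfit(tau, msd_um2[:n_fit_lags], 1)
    if slope < 0:
        warnings.warn("negative MSD slope; clamping D to 0", stacklevel=2)
        return 0.0
    return float(slope / 4.0)  # 2-D: MSD = 4 D tau


def stokes_einstein_diameter(d_m2_s: float, medium: MediumParams) -> float:
    """Hydrodynamic diameter (m) from D (m²/s): d = k_B T / (3 pi eta D)."""
    if d_m2_s <= 0:
        raise ValueError("diffusion coefficient must be positive to define a diameter")
    return K_B * medium.temperature_K / (3.0 * np.pi * medium.viscosity_Pa_s * d_m2_s)


def electroosmotic_correction(
    observed_velocity_by_depth: Sequence[tuple[float, float]],
) -> float:
    """Particle electrophoretic velocity from a multi-depth velocity profile.

    Fits ``v(z) = a z² + b z + c`` to (depth, apparent velocity) samples,
    depths normalised to [0, 1].  In a closed cell the electro-osmotic
    return flow has zero depth average, so the fitted profile's integral over
    [0, 1] — ``a/3 + b/2 + c`` — is the particle's own velocity.
    """
    pts = np.asarray(observed_velocity_by_depth, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected a sequence of (depth, velocity) pairs")
    z, v = pts[:, 0], pts[:, 1]
    if len(np.unique(z)) < 3:
        raise ValueError("at least 3 distinct depths are required for a quadratic fit")
    a, b, c = np.polyfit(z, v, 2)
    return float(a / 3.0 + b / 2.0 + c)


def smoluchowski_zeta(
    v_ep_m_s: float, field_V_m: float, medium: MediumParams
) -> float:
    """Zeta potential (V) from electrophoretic velocity and applied field.

    mu = v/E; zeta = mu * eta / (eps_r * eps_0).  Sign is preserved.
    """
    if field_V_m == 0:
        raise ValueError("applied field must be non-zero")
    return mobility_to_zeta(v_ep_m_s / field_V_m, medium)


def mobility_to_zeta(mobility_m2_Vs: float, medium: MediumParams) -> float:
    """Smoluchowski conversion: zeta (V) = mu * eta / (eps_r * eps_0)."""
    return mobility_m2_Vs * medium.viscosity_Pa_s / (
        medium.relative_permittivity * EPS_0
    )


def einstein_consistency_check(
    trajectory: Trajectory,
    assumed_diameter_nm: float,
    medium: MediumParams,
    window_s: float = 10.0,
    band: tuple[float, float] = (0.5, 2.0),
) -> tuple[float, bool]:
    """Ratio of observed to Stokes–Einstein-predicted MSD slope over a window.

    Fits D over lags up to ``window_s`` and compares with the diffusion
    coefficient implied by the assumed diameter.  Returns ``(ratio,
    consistent)`` where consistency means the ratio falls inside ``band``.
    """
    if assumed_diameter_nm <= 0:
        raise ValueError("assumed diameter must be positive")
    if window_s > trajectory.duration_s:
        raise ValueError("window_s exceeds the trajectory duration")
    max_lag = max(2, int(window_s / trajectory.dt_s))
    max_lag = min(max_lag, len(trajectory.positions_um) - 1)
    curve = msd(trajectory, max_lag)
    d_obs = diffusion_from_msd(curve, trajectory.dt_s)
    d_pred_m2_s = K_B * medium.temperature_K / (
        3.0 * np.pi * medium.viscosity_Pa_s * assumed_diameter_nm / M_TO_NM
    )
    d_pred = d_pred_m2_s / UM2_S_TO_M2_S
    ratio = d_obs / d_pred
    return float(ratio), bool(band[0] <= ratio <= band[1])


def classify_submicron(diameter_nm: float) -> bool:
    """Ultrafine-particle criterion: diameter strictly below 1 um (1000 nm)."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    return diameter_nm < 1000.0


def estimate_particles(
    trajectories: Sequence[Trajectory],
    medium: MediumParams,
    *,
    n_fit_lags: int | None = None,
    max_lag: int | None = None,
) -> list[ParticleEstimate]:
    """Per-trajectory D and Stokes–Einstein diameter estimates."""
    out = []
    for traj in trajectories:
        lags = max_lag or (len(traj.positions_um) - 1) // 2
        curve = msd(traj, max(2, lags))
        d = diffusion_from_msd(curve, traj.dt_s, n_fit_lags)
        if d > 0:
            diam_nm = stokes_einstein_diameter(d * UM2_S_TO_M2_S, medium) * M_TO_NM
        else:
            diam_nm = None
        out.append(ParticleEstimate(traj.particle_id, d, diam_nm))
    return out


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Write tracks as delimited text: particle_id, frame, x_um, y_um[, z]."""
    rows = []
    has_depth = any(t.depth is not None for t in trajectories)
    for t in trajectories:
        for frame, (x, y) in enumerate(t.positions_um):
            row = [t.particle_id, frame, x, y]
            if has_depth:
                row.append(t.depth if t.depth is not None else np.nan)
            rows.append(row)
    cols = ["particle_id", "frame", "x_um", "y_um"] + (["z"] if has_depth else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_trajectories(
    path: str | Path, dt_s: float = DEFAULT_DT_S
) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"particle_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("frame")
        depth = None
        if "z" in grp.columns and grp["z"].notna().any():
            depth = float(grp["z"].iloc[0])
        out.append(Trajectory(int(pid), grp[["x_um", "y_um"]].to_numpy(),
                              dt_s, depth=depth))
    return out
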