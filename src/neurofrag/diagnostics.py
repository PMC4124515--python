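"""Decay functionals and long-time regime classification.

Relaxation of the population density to its stationary profile ``A`` is
quantified through the cumulative difference

    M(s, t) = int_0^s [ n(x, t) - A(x) ] dx

and its time derivative ``J = dM/dt``: both vanish at ``s = 0`` and
``s = infinity`` and satisfy a closed transport equation, which is why
the theory certifies exponential decay for the weighted norms
``int P |M|`` and ``int P |J|`` rather than for ``n - A`` directly.
This module computes those functionals on simulator output, fits
empirical exponential rates, and classifies trajectories into the
desynchronized (converged activity) versus synchronized (periodic
activity) regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulator import DensityState, Trajectory

__all__ = [
    "DecayReport",
    "OscillationReport",
    "cumulative_difference",
    "time_derivative_J",
    "estimate_decay_rate",
    "oscillation_analysis",
]

FLOOR = 1e-13  # below this the functional is double-precision noise

FUNCTIONALS = ("L1_m", "weighted_L1_M", "weighted_L1_J", "activity_gap")


@dataclass
class DecayReport:
    """Fitted exponential rate of a decay functional."""

    nu_hat: float
    functional: str
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int
    window_shrunk: bool = False


@dataclass
class OscillationReport:
    """Late-time classification of the activity series ``N(t)``."""

    regime: str  # converged | periodic | irregular
    amplitude: float
    period: Optional[float] = None
    plateau: Optional[float] = None
    n_peaks: int = 0


def cumulative_difference(state: DensityState, A_values: np.ndarray) -> np.ndarray:
    """``M(s) = int_0^s [n - A]`` as a running discrete integral.

    Since both densities carry unit mass, the last entry is zero up to
    conservation error.
    """
    A_values = np.asarray(A_values, dtype=float)
    if A_values.shape != state.values.shape:
        raise ValueError("density and stationary profile live on different grids")
    return np.cumsum(state.values - A_values) * state.grid.ds


def time_derivative_J(
    snapshots: Sequence[DensityState], A_values: np.ndarray
) -> list[np.ndarray]:
    """``J = dM/dt`` by centered (interior) / one-sided (ends) differences."""
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots to differentiate in time")
    times = np.array([snap.time for snap in snapshots])
    M = np.stack([cumulative_difference(snap, A_values) for snap in snapshots])
    J = np.gradient(M, times, axis=0)
    return [J[i] for i in range(len(snapshots))]


def _functional_series(
    traj: Trajectory,
    A_values: Optional[np.ndarray],
    P_values: Optional[np.ndarray],
    functional: str,
    A_star: Optional[float],
) -> tuple[np.ndarray, np.ndarray]:
    if functional == "activity_gap":
        if A_star is None:
            raise ValueError("activity_gap needs the stationary activity A_star")
        return traj.times, np.abs(traj.N_values - A_star)
    if not traj.snapshots:
        raise ValueError(f"functional {functional!r} needs stored snapshots")
    if A_values is None:
        raise ValueError("density functionals need the stationary profile")
    ds = traj.grid.ds
    times = np.array([snap.time for snap in traj.snapshots])
    if functional == "L1_m":
        vals = np.array(
            [ds * np.abs(s.values - A_values).sum() for s in traj.snapshots]
        )
    elif functional == "weighted_L1_M":
        if P_values is None:
            raise ValueError("weighted functionals need the dual weight P")
        vals = np.array(
            [
                ds * np.sum(P_values * np.abs(cumulative_difference(s, A_values)))
                for s in traj.snapshots
            ]
        )
    elif functional == "weighted_L1_J":
        if P_values is None:
            raise ValueError("weighted functionals need the dual weight P")
        Js = time_derivative_J(traj.snapshots, A_values)
        vals = np.array([ds * np.sum(P_values * np.abs(J)) for J in Js])
    else:
        raise ValueError(f"unknown functional {functional!r}; pick from {FUNCTIONALS}")
    return times, vals


def estimate_decay_rate(
    traj: Trajectory,
    A_values: Optional[np.ndarray] = None,
    P_values: Optional[np.ndarray] = None,
    functional: str = "weighted_L1_M",
    window: Optional[tuple[float, float]] = None,
    A_star: Optional[float] = None,
) -> DecayReport:
    """Least-squares exponential rate of a decay functional.

    Fits ``log(functional)`` against time over ``window`` (whole series
    by default) and reports ``nu_hat = -slope``.  Times where the
    functional is at the double-precision floor are dropped; if that
    shrinks the requested window the report says so.
    """
    times, vals = _functional_series(traj, A_values, P_values, functional, A_star)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        times, vals = times[sel], vals[sel]
    keep = vals > FLOOR
    shrunk = bool(np.any(~keep))
    times, vals = times[keep], vals[keep]
    if len(times) < 2:
        raise ValueError("fewer than two usable points above the precision floor")
    slope, intercept = np.polyfit(times, np.log(vals), 1)
    pred = slope * times + intercept
    log_vals = np.log(vals)
    ss_res = float(np.sum((log_vals - pred) ** 2))
    ss_tot = float(np.sum((log_vals - log_vals.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayReport(
        nu_hat=float(-slope),
        functional=functional,
        fit_window=(float(times[0]), float(times[-1])),
        r_squared=r2,
        n_points=len(times),
        window_shrunk=shrunk,
    )


def oscillation_analysis(
    traj: Trajectory,
    late_fraction: float = 0.5,
    convergence_tol: float = 1e-3,
    min_span: float = 20.0,
) -> OscillationReport:
    """Classify the late-time activity as converged, periodic, or irregular.

    Looks at the last ``late_fraction`` of ``N(t)``.  The trajectory is
    *converged* when the late-window peak-to-peak amplitude is below
    ``convergence_tol`` relative to the late mean; *periodic* when at
    least three peaks (local maxima above the midpoint of late mean and
    late max) occur with spacing coefficient-of-variation under 5%;
    otherwise *irregular*.
    """
    span = float(traj.times[-1] - traj.times[0])
    if span < min_span:
        raise ValueError(
            f"trajectory spans {span:.1f} time units; need at least {min_span}"
        )
    k0 = int(len(traj.times) * (1.0 - late_fraction))
    N = traj.N_values[k0:]
    t = traj.times[k0:]
    mean = float(N.mean())
    amplitude = float(N.max() - N.min())

    if amplitude < convergence_tol * max(abs(mean), FLOOR):
        return OscillationReport(
            regime="converged", amplitude=amplitude, plateau=mean
        )

    height = mean + 0.5 * (float(N.max()) - mean)
    peaks, _ = find_peaks(N, height=height)
    n_peaks = len(peaks)
    if n_peaks >= 3:
        spacings = np.diff(t[peaks])
        cv = float(spacings.std() / spacings.mean())
        if cv < 0.05:
            return OscillationReport(
                regime="periodic",
                amplitude=amplitude,
                period=float(spacings.mean()),
                n_peaks=n_peaks,
            )
    return OscillationReport(regime="irregular", amplitude=amplitude, n_peaks=n_peaks)
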