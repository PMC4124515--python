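"""Model coefficients: firing rate ``p(s, N)`` and fragmentation kernel ``K(s, u)``.

The elapsed-time population model is driven by two ingredients:

* a discharge (hazard) rate ``p(s, N)`` — zero during the refractory
  period, saturating at a ceiling ``pM`` once the elapsed time ``s``
  exceeds a stimulation-dependent threshold ``sigma(N)``;
* a fragmentation kernel ``K(s, u)`` — the distribution of the
  post-discharge state ``s`` of a neuron that fired at elapsed time
  ``u``, supported on ``s <= u`` (a discharge can only rejuvenate).

This module evaluates and discretizes both, and computes the derived
smallness quantities (``theta``, ``B*``, the exponential-moment witness
``mu``, and the direct-decay rate ``nu``) that certify exponential
relaxation of the network in the weakly coupled regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import scipy.sparse as sp

from .grid import Grid

__all__ = [
    "ThresholdRule",
    "FiringRate",
    "FragmentationKernel",
    "KernelDiscretization",
    "ConditionReport",
    "KernelAdmissibilityError",
    "n_plus_minus",
    "sigma_of",
    "firing_rate_eval",
    "kernel_cdf",
    "kernel_theta",
    "discretize_kernel",
    "b_star_quadrature",
    "compute_B_star",
    "check_assumptions",
]


class KernelAdmissibilityError(ValueError):
    """Raised when a kernel violates the contraction requirement ``theta < 1``."""


def n_plus_minus(alpha: float) -> tuple[float, float]:
    """Activity levels bracketing the descending branch of the threshold map.

    For a threshold scale ``alpha > 0``::

        N_minus = 1 / (2 e^alpha - 1),   N_plus = e^alpha / (2 e^alpha - 1)

    and the ordering ``0 < N_minus < N_plus < 1`` always holds.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    d = 2.0 * math.exp(alpha) - 1.0
    return 1.0 / d, math.exp(alpha) / d


@dataclass(frozen=True)
class ThresholdRule:
    """Piecewise-logarithmic refractory threshold ``sigma(N)``.

    The threshold is ``2*alpha`` for weak stimulation, decreases
    logarithmically between the two pivot activities ``N_minus`` and
    ``N_plus``, and saturates at ``alpha`` for strong stimulation.  It is
    continuous, non-increasing, and ranges over ``[alpha, 2*alpha]``.
    """

    alpha: float
    N_minus: float = field(init=False)
    N_plus: float = field(init=False)
    sigma_minus: float = field(init=False)
    sigma_plus: float = field(init=False)

    def __post_init__(self) -> None:
        nm, np_ = n_plus_minus(self.alpha)
        object.__setattr__(self, "N_minus", nm)
        object.__setattr__(self, "N_plus", np_)
        object.__setattr__(self, "sigma_minus", self.alpha)
        object.__setattr__(self, "sigma_plus", 2.0 * self.alpha)

    def __call__(self, x):
        return sigma_of(x, self)


def sigma_of(x, rule: ThresholdRule):
    """Evaluate the threshold map ``sigma`` at activity ``x >= 0``.

    Piecewise: ``2*alpha`` on ``[0, N_minus]``,
    ``2*alpha - ln(x) + ln(N_minus)`` on ``[N_minus, N_plus]``,
    ``alpha`` on ``[N_plus, inf)``.  Vectorized in ``x``.
    """
    a = rule.alpha
    x_arr = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mid = 2.0 * a - np.log(x_arr) + math.log(rule.N_minus)
    out = np.where(
        x_arr <= rule.N_minus, 2.0 * a, np.where(x_arr >= rule.N_plus, a, mid)
    )
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


Threshold = Union[ThresholdRule, float]


@dataclass(frozen=True)
class FiringRate:
    """Discharge rate family ``p(s, N)``.

    ``family="step"`` is the sharp indicator ``pM * 1{s >= sigma(N)}``
    (closed at the boundary: ``p(sigma, N) = pM``); ``family="regularized"``
    replaces the jump by a linear ramp of width ``smoothing_width`` ending
    at ``sigma(N)``, so the rate is Lipschitz in ``s``.  The threshold is
    either a :class:`ThresholdRule` (nonlinear coupling through the total
    activity ``N``) or a constant (uncoupled / linear dynamics).

    ``eta`` declares a bound on ``|dp/dN|``; when omitted it is derived
    for ramp rates (``pM * |sigma'|_max / smoothing_width``) and is
    ``inf`` for coupled step rates, whose ``N``-derivative is a singular
    measure — such rates sit outside the weak-coupling hypotheses and are
    flagged, not rejected.
    """

    family: str
    threshold: Threshold
    pM: float = 1.0
    smoothing_width: float = 0.0
    eta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("step", "regularized"):
            raise ValueError(f"unknown rate family {self.family!r}")
        if self.pM <= 0:
            raise ValueError("pM must be positive")
        if self.smoothing_width < 0:
            raise ValueError("smoothing_width must be nonnegative")
        if self.family == "step" and self.smoothing_width != 0:
            raise ValueError("step family requires smoothing_width == 0")

    # -- threshold ---------------------------------------------------------
    @property
    def depends_on_N(self) -> bool:
        return isinstance(self.threshold, ThresholdRule)

    def sigma(self, N):
        if isinstance(self.threshold, ThresholdRule):
            return sigma_of(N, self.threshold)
        return float(self.threshold) if np.ndim(N) == 0 else np.full(np.shape(N), float(self.threshold))

    @property
    def sigma_max(self) -> float:
        if isinstance(self.threshold, ThresholdRule):
            return self.threshold.sigma_plus
        return float(self.threshold)

    # -- evaluation --------------------------------------------------------
    def __call__(self, s, N):
        return firing_rate_eval(s, N, self)

    def eta_bound(self) -> float:
        """Effective bound on ``|dp/dN|`` (0 for constant thresholds)."""
        if self.eta is not None:
            return self.eta
        if not self.depends_on_N:
            return 0.0
        if self.smoothing_width == 0:
            return math.inf
        # |sigma'| peaks at 1/N_minus on the logarithmic branch
        rule = self.threshold
        return self.pM / self.smoothing_width / rule.N_minus


def firing_rate_eval(s, N, rate: FiringRate):
    """Evaluate ``p(s, N)``; vectorized in ``s`` (scalar ``N``)."""
    sig = rate.sigma(N)
    s_arr = np.asarray(s, dtype=float)
    delta = rate.smoothing_width
    if delta == 0.0:
        out = np.where(s_arr >= sig, rate.pM, 0.0)
    else:
        ramp = rate.pM * np.clip((s_arr - (sig - delta)) / delta, 0.0, 1.0)
        # the ceiling must hold exactly at and beyond the threshold
        out = np.where(s_arr >= sig, rate.pM, ramp)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(out)
    return out


PointMap = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class FragmentationKernel:
    """Redistribution law ``K(s, u)`` for the post-discharge state.

    ``family="point_map"``: a deterministic reset ``K(s, u) = delta(s - psi(u))``
    with ``psi`` monotone and ``psi(u) <= u``; ``psi identically 0`` is the
    classical full reset of age-structured models.  ``family="density"``: an
    absolutely continuous kernel given by a callable ``density_values(s, u)``
    supported on ``s <= u``.

    ``theta`` declares the contraction bound ``sup_u d/du int s K(s,u) ds``
    (for point maps, ``sup psi'``); when omitted it is estimated on a probe
    grid by :func:`kernel_theta`.
    """

    family: str
    psi: Optional[PointMap] = None
    psi_prime: Optional[PointMap] = None
    density_values: Optional[Callable[[np.ndarray, float], np.ndarray]] = None
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family == "point_map":
            if self.psi is None:
                raise ValueError("point_map kernel requires psi")
            probe = np.linspace(0.0, 50.0, 257)
            vals = np.asarray(self.psi(probe), dtype=float)
            if np.any(vals < -1e-12) or np.any(vals > probe + 1e-9):
                raise ValueError("psi must satisfy 0 <= psi(u) <= u")
            if np.any(np.diff(vals) < -1e-9):
                raise ValueError("psi must be non-decreasing")
        elif self.family == "density":
            if self.density_values is None:
                raise ValueError("density kernel requires density_values")
        else:
            raise ValueError(f"unknown kernel family {self.family!r}")

    @classmethod
    def point_map_linear(cls, slope: float) -> "FragmentationKernel":
        """Proportional reset ``psi(u) = slope * u`` (slope in [0, 1))."""
        if not 0.0 <= slope < 1.0:
            raise KernelAdmissibilityError(
                f"linear point map needs slope in [0, 1), got {slope}"
            )
        return cls(
            family="point_map",
            psi=lambda u, c=slope: c * np.asarray(u, dtype=float),
            psi_prime=lambda u, c=slope: np.full(np.shape(u) or (), c),
            theta=slope,
        )

    @classmethod
    def full_reset(cls) -> "FragmentationKernel":
        """Classical age-structured reset ``K = delta_{s=0}``."""
        return cls.point_map_linear(0.0)


def kernel_cdf(kern: FragmentationKernel, s: float, u: float) -> float:
    """Cumulative kernel ``f(s, u) = int_0^s K(x, u) dx``.

    Always in ``[0, 1]``, non-decreasing in ``s``, and equal to 1 for
    ``s >= u`` (no mass escapes past the discharge state).
    """
    if s >= u:
        return 1.0
    if kern.family == "point_map":
        return 1.0 if s >= float(np.asarray(kern.psi(np.asarray(u, dtype=float)))) else 0.0
    x = np.linspace(0.0, max(s, 0.0), 513)
    val = float(np.trapezoid(np.asarray(kern.density_values(x, u), dtype=float), x))
    return float(np.clip(val, 0.0, 1.0))


def kernel_theta(
    kern: FragmentationKernel,
    u_max: float = 50.0,
    n_probe: int = 512,
    strict: bool = True,
) -> float:
    """Estimate the contraction bound ``theta``.

    For point maps this is ``sup psi'`` over a probe grid; for density
    kernels the first moment ``int s K(s, u) ds`` is computed by
    quadrature and differentiated in ``u``.  A declared ``theta`` on the
    kernel takes precedence for density kernels.  With ``strict=True`` an
    estimate ``>= 1`` raises :class:`KernelAdmissibilityError`.
    """
    u = np.linspace(0.0, u_max, n_probe)
    if kern.family == "point_map":
        if kern.psi_prime is not None:
            est = float(np.max(np.asarray(kern.psi_prime(u), dtype=float)))
        else:
            vals = np.asarray(kern.psi(u), dtype=float)
            est = float(np.max(np.diff(vals) / np.diff(u)))
    else:
        if kern.theta is not None:
            est = float(kern.theta)
        else:
            moments = np.empty_like(u)
            for i, ui in enumerate(u):
                if ui == 0.0:
                    moments[i] = 0.0
                    continue
                x = np.linspace(0.0, ui, 513)
                moments[i] = np.trapezoid(
                    x * np.asarray(kern.density_values(x, ui), dtype=float), x
                )
            est = float(np.max(np.diff(moments) / np.diff(u)))
    if strict and est >= 1.0:
        raise KernelAdmissibilityError(
            f"contraction bound estimate {est:.4f} >= 1; kernel inadmissible"
        )
    return est


@dataclass(frozen=True)
class KernelDiscretization:
    """Column-stochastic redistribution matrix on a grid.

    Column ``j`` carries the arrival distribution of mass discharged from
    cell ``j``; every column sums to 1 exactly and the matrix is lower
    triangular (a neuron never lands past its discharge state).
    """

    grid: Grid
    redistribution_matrix: sp.csr_matrix

    def apply(self, mass: np.ndarray) -> np.ndarray:
        """Route a per-cell vector of discharged mass to its arrival cells."""
        return self.redistribution_matrix @ mass


def discretize_kernel(kern: FragmentationKernel, grid: Grid) -> KernelDiscretization:
    """Build the discrete redistribution matrix for ``kern`` on ``grid``.

    Point maps deposit the mass of discharge node ``u_j`` onto the two
    nodes bracketing ``psi(u_j)``, weighted to preserve the first moment
    exactly; density kernels are node-sampled and renormalized.  Columns
    are normalized to 1 exactly in either case.
    """
    n = grid.n_cells
    nodes = grid.nodes
    rows, cols, data = [], [], []
    if kern.family == "point_map":
        targets = np.minimum(np.asarray(kern.psi(nodes), dtype=float), nodes)
        targets = np.maximum(targets, 0.0)
        for j in range(n):
            t = targets[j]
            k = int(np.floor(t / grid.ds))
            k = min(k, j)
            w_hi = t / grid.ds - k
            if w_hi <= 1e-14 or k + 1 > j:
                rows.append(k)
                cols.append(j)
                data.append(1.0)
            else:
                if k + 1 > j:  # pragma: no cover - excluded by construction
                    raise ValueError("arrival index above discharge index")
                rows.extend([k, k + 1])
                cols.extend([j, j])
                data.extend([1.0 - w_hi, w_hi])
    else:
        for j in range(n):
            u_j = nodes[j]
            w = np.asarray(kern.density_values(nodes[: j + 1], u_j), dtype=float)
            w = np.clip(w, 0.0, None)
            tot = w.sum()
            if tot <= 0.0:
                w = np.zeros(j + 1)
                w[0] = 1.0
                tot = 1.0
            w = w / tot
            nz = np.nonzero(w)[0]
            rows.extend(nz.tolist())
            cols.extend([j] * len(nz))
            data.extend(w[nz].tolist())
    mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    # exact renormalization of every column
    colsum = np.asarray(mat.sum(axis=0)).ravel()
    mat = mat @ sp.diags(1.0 / colsum)
    return KernelDiscretization(grid=grid, redistribution_matrix=mat.tocsr())


# ---------------------------------------------------------------------------
# Smallness conditions
# ---------------------------------------------------------------------------


@dataclass
class ConditionReport:
    """Verdicts on the weak-coupling hypotheses at a stationary activity.

    ``B_star`` is the smallness quantity combining the refractory length
    ``sigma*``, the variation of the frozen rate ``p*`` and the kernel
    contraction ``theta``; ``B_star < 1`` (plus a companion inequality)
    opens the dual-weight decay machinery.  ``mu_star`` witnesses the
    exponential-moment condition used to control the refractory zone, and
    ``nu_B1`` is the direct decay rate available for point-map kernels
    with differentiable rates.
    """

    B_star: float
    condition_15_holds: bool
    mu_star: Optional[float]
    condition_16_holds: bool
    theta_estimate: float
    nu_B1: Optional[float]
    eta: float
    notes: str = ""


def _frozen_rate(rate: FiringRate, A_star: float):
    sigma_star = float(rate.sigma(A_star))
    return (lambda s: firing_rate_eval(s, A_star, rate)), sigma_star


def b_star_quadrature(
    p_star: Callable[[np.ndarray], np.ndarray],
    sigma_star: float,
    theta: float,
    n_quad: int = 4096,
) -> float:
    """Trapezoidal evaluation of the smallness quantity ``B*``::

        B* = exp(int_0^sigma* p*) * [ sigma* * TV(p*; [0, sigma*])
                                      + theta * int_0^sigma* p* ]

    ``TV`` is the total variation of the frozen rate on the closed
    refractory interval (``int |p*'|``, including the terminal jump of a
    step rate).
    """
    if sigma_star <= 0:
        return 0.0
    s = np.linspace(0.0, sigma_star, n_quad + 1)
    p_vals = np.asarray(p_star(s), dtype=float)
    int_p = float(np.trapezoid(p_vals, s))
    tv = float(np.sum(np.abs(np.diff(p_vals))))
    return math.exp(int_p) * (sigma_star * tv + theta * int_p)


def compute_B_star(
    rate: FiringRate,
    kern: FragmentationKernel,
    A_star: float,
    n_quad: int = 4096,
) -> float:
    """Smallness quantity ``B*`` with coefficients frozen at ``A_star``.

    Uses ``p*(s) = p(s, A*)``, ``sigma* = sigma(A*)`` and the kernel's
    contraction bound ``theta``; see :func:`b_star_quadrature` for the
    formula.
    """
    if A_star < 0:
        raise ValueError("A_star must be nonnegative")
    p_star, sigma_star = _frozen_rate(rate, A_star)
    theta = kern.theta if kern.theta is not None else kernel_theta(kern, strict=False)
    return b_star_quadrature(p_star, sigma_star, theta, n_quad=n_quad)


def _exp_moment_gap(
    p_vals: np.ndarray,
    u: np.ndarray,
    kern: FragmentationKernel,
    mu: float,
) -> float:
    """``sup_u p(u) [ int K(s,u) e^{mu(u-s)} ds - 1 ]`` over the probe grid."""
    if kern.family == "point_map":
        psi_u = np.asarray(kern.psi(u), dtype=float)
        inner = np.exp(mu * (u - psi_u)) - 1.0
    else:
        inner = np.empty_like(u)
        for i, ui in enumerate(u):
            if ui == 0.0:
                inner[i] = 0.0
                continue
            x = np.linspace(0.0, ui, 257)
            kv = np.asarray(kern.density_values(x, ui), dtype=float)
            inner[i] = np.trapezoid(kv * np.exp(mu * (ui - x)), x) - 1.0
    return float(np.max(p_vals * inner))


def check_assumptions(
    rate: FiringRate,
    kern: FragmentationKernel,
    A_star: float,
    n_probe: int = 1024,
) -> ConditionReport:
    """Evaluate every certifiable smallness condition; report, never raise.

    The exponential-moment condition is scanned over a logarithmic grid
    of 200 values ``mu in [1e-4, 10]`` and the first witness is recorded.
    ``nu_B1`` is reported only for point-map kernels with a rate that is
    differentiable in ``s`` (ramp or constant-in-``s``); step rates are
    flagged as outside the smallness hypotheses.
    """
    notes: list[str] = []
    p_star, sigma_star = _frozen_rate(rate, A_star)
    theta = kernel_theta(kern, strict=False)
    if theta >= 1.0:
        notes.append(f"theta estimate {theta:.3f} >= 1: kernel inadmissible")
    b_star = compute_B_star(rate, kern, A_star)

    # companion inequality of the B* condition (direct, stronger form)
    s = np.linspace(0.0, max(sigma_star, 1e-12), 2049)
    int_p = float(np.trapezoid(np.asarray(p_star(s), dtype=float), s))
    cond15 = bool(
        b_star < 1.0 and theta * math.exp(int_p) / (1.0 - b_star) < rate.pM
    )

    # exponential-moment condition on the refractory zone
    u = np.linspace(0.0, max(sigma_star, 1e-12), n_probe)
    p_u = np.asarray(p_star(u), dtype=float)
    mu_star = None
    for mu in np.logspace(-4, 1, 200):
        if _exp_moment_gap(p_u, u, kern, mu) < mu:
            mu_star = float(mu)
            break
    cond16 = mu_star is not None

    # direct-decay rate (point maps, differentiable rates only)
    nu_b1 = None
    if kern.family == "point_map" and (
        rate.smoothing_width > 0 or not rate.depends_on_N or sigma_star == 0.0
    ):
        u_max = rate.sigma_max + 10.0 / rate.pM
        ug = np.linspace(0.0, u_max, 4097)
        psi_u = np.asarray(kern.psi(ug), dtype=float)
        psi_bar = ug - psi_u
        psi_bar_prime = np.gradient(psi_bar, ug)
        p_vals = np.asarray(p_star(ug), dtype=float)
        p_prime = np.abs(np.gradient(p_vals, ug))
        if rate.smoothing_width == 0 and sigma_star > 0:
            nu_b1 = None  # singular |p'|: certificate not defined
        else:
            nu_b1 = float(np.min(p_vals * psi_bar_prime - p_prime * psi_bar))
    if rate.smoothing_width == 0 and sigma_star > 0:
        notes.append(
            "step rate: |dp/ds| and |dp/dN| are singular measures; "
            "outside smallness hypotheses (reported, not rejected)"
        )
    eta = rate.eta_bound()
    if not math.isfinite(eta):
        notes.append("eta unbounded (coupled step rate)")

    return ConditionReport(
        B_star=b_star,
        condition_15_holds=cond15,
        mu_star=mu_star,
        condition_16_holds=cond16,
        theta_estimate=theta,
        nu_B1=nu_b1,
        eta=eta,
        notes="; ".join(notes),
    )
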