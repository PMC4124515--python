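"""Dual eigenweight and exponential-decay certificates.

Exponential relaxation of the model is proved through a weighted L1
norm: one seeks a positive weight ``P`` with ``P(0) = 1`` and an
eigenvalue ``lambda < 0`` solving the adjoint-type equation

    -P'(s) + (lambda + p*(s)) P(s)
        = int_0^s [ |p*'(s)| f(u, s) + p*(s) Phi(u, s) ] P(u) du,

with the coefficients frozen at the stationary activity
(``p*(s) = p(s, A*)``).  The right side only involves ``P`` on
``[0, s]``, so the equation is of Volterra type and is integrated by a
forward march.  Under the smallness condition ``B* < 1`` the weight
stays positive, is sandwiched between ``1 - B*`` and ``exp(int p*)`` on
the refractory zone, and increases past ``sigma*`` — which is exactly
what makes the weighted norm of the cumulative difference ``M`` decay
like ``exp(lambda t)``.

For point-map kernels ``K = delta(s - psi(u))`` the memory integral is
evaluated exactly on the measure: ``Phi(u, s) = psi'(s) delta(u - psi(s))``
contributes ``p*(s) psi'(s) P(psi(s))`` with ``P`` linearly interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .coefficients import (
    FiringRate,
    FragmentationKernel,
    firing_rate_eval,
    kernel_theta,
)
from .grid import Grid

__all__ = ["DualEigenresult", "dual_P", "find_lambda", "prop_B1_rate"]

OVERFLOW_CAP = 1e12

RateStar = Union[np.ndarray, Callable[[np.ndarray], np.ndarray]]


@dataclass
class DualEigenresult:
    """Dual weight, certified eigenvalue, and the decay constants."""

    grid: Grid
    P_values: np.ndarray
    lam: float
    B_star: float
    B_ratio: float
    admissible: bool
    sigma_star: float
    reason: str = ""


def _p_star_values(rate_star: RateStar, grid: Grid) -> np.ndarray:
    if callable(rate_star):
        return np.asarray(rate_star(grid.nodes), dtype=float)
    vals = np.asarray(rate_star, dtype=float)
    if vals.shape != (grid.n_cells,):
        raise ValueError("p* values must match the grid")
    return vals


def dual_P(
    lam: float,
    rate_star: RateStar,
    kern: FragmentationKernel,
    grid: Grid,
    sigma_star: Optional[float] = None,
) -> np.ndarray:
    """Forward-march the dual weight equation; returns ``P`` on the nodes.

    ``rate_star`` is the frozen rate ``p*`` (array on the nodes or
    callable); ``sigma_star`` marks the jump location of a sharp step
    rate, whose ``|p*'|`` is a point mass there and contributes a
    downward jump ``-pM * int_{psi(sigma*)}^{sigma*} P`` to the march.
    No admissibility judgment is made here; the march is truncated (and
    the profile capped) if ``P`` exceeds ``1e12``.
    """
    if lam > 0:
        raise ValueError("the dual weight is defined for lambda <= 0")
    n = grid.n_cells
    ds = grid.ds
    s = grid.nodes
    p_vals = _p_star_values(rate_star, grid)

    is_step = sigma_star is not None and sigma_star > 0
    if is_step:
        abs_p_prime = np.zeros(n)
        pM_jump = float(np.max(p_vals))
    else:
        abs_p_prime = np.abs(np.gradient(p_vals, s)) if n > 1 else np.zeros(n)
        pM_jump = 0.0

    if kern.family == "point_map":
        psi_s = np.minimum(np.asarray(kern.psi(s), dtype=float), s)
        if kern.psi_prime is not None:
            psi_p = np.asarray(kern.psi_prime(s), dtype=float) * np.ones(n)
        else:
            psi_p = np.gradient(psi_s, s) if n > 1 else np.zeros(n)
    else:
        # dense cumulative-kernel tables: f[u_idx, s_idx], Phi = -d f / d s
        f_tab = np.empty((n, n))
        for j in range(n):
            kv = np.asarray(kern.density_values(s, s[j]), dtype=float)
            kv[s > s[j]] = 0.0
            cums = np.concatenate([[0.0], np.cumsum(0.5 * (kv[1:] + kv[:-1]) * ds)])
            f_tab[:, j] = np.clip(cums, 0.0, 1.0)
            f_tab[s >= s[j], j] = 1.0
        phi_tab = -np.gradient(f_tab, s, axis=1)
        np.clip(phi_tab, 0.0, None, out=phi_tab)

    P = np.empty(n)
    P[0] = 1.0
    cumP = np.zeros(n)  # cumP[k] = int_0^{s_k} P

    def interp_cumP(x: float, k: int) -> float:
        """int_0^x P, trapezoid memory, x <= s_k."""
        idx = min(int(x / ds), k - 1) if k > 0 else 0
        frac = x - idx * ds
        if idx >= k:
            return cumP[k]
        p_at_x = P[idx] + (P[idx + 1] - P[idx]) * frac / ds if idx + 1 <= k else P[idx]
        return cumP[idx] + 0.5 * (P[idx] + p_at_x) * frac

    def interp_P(x: float, k: int) -> float:
        idx = min(int(x / ds), k)
        frac = x / ds - idx
        if idx + 1 > k:
            return P[idx]
        return P[idx] * (1.0 - frac) + P[idx + 1] * frac

    capped_from = None
    for k in range(n - 1):
        cumP[k] = cumP[k - 1] + 0.5 * (P[k - 1] + P[k]) * ds if k > 0 else 0.0
        a_k = lam + p_vals[k]
        if kern.family == "point_map":
            mem_f = abs_p_prime[k] * (cumP[k] - interp_cumP(psi_s[k], k))
            mem_phi = p_vals[k] * psi_p[k] * interp_P(psi_s[k], k)
            r_k = mem_f + mem_phi
        else:
            w = abs_p_prime[k] * f_tab[: k + 1, k] + p_vals[k] * phi_tab[: k + 1, k]
            if k == 0:
                r_k = 0.0
            else:
                r_k = float(np.trapezoid(w * P[: k + 1], dx=ds))
        P[k + 1] = P[k] * math.exp(a_k * ds) - ds * r_k * math.exp(a_k * ds / 2.0)
        # point-mass contribution of |p*'| for sharp rates
        if is_step and s[k] < sigma_star <= s[k + 1] + 1e-15:
            P[k + 1] -= pM_jump * (
                interp_cumP(min(sigma_star, s[k]), k)
                - interp_cumP(min(float(psi_s[k]), sigma_star), k)
            )
        if abs(P[k + 1]) > OVERFLOW_CAP:
            capped_from = k + 1
            break
    if capped_from is not None:
        P[capped_from:] = P[capped_from]
    return P


def _b_ratio(P: np.ndarray) -> float:
    """Smallest ``B`` with ``1/B <= P(x)`` and ``P(x) <= B P(y)`` for ``x <= y``."""
    suffix_min = np.minimum.accumulate(P[::-1])[::-1]
    pair_ratio = float(np.max(P / suffix_min))
    return max(1.0 / float(P.min()), pair_ratio, 1.0)


def find_lambda(
    rate_star: RateStar,
    kern: FragmentationKernel,
    grid: Grid,
    B_star: float,
    sigma_star: float = 0.0,
    n_scan: int = 21,
    mono_tol: float = 1e-10,
) -> DualEigenresult:
    """Locate the most negative certified eigenvalue ``lambda < 0``.

    Candidates ``lambda_k = -pM/4 * 2^{-k}`` are tried from the closest
    to zero downward; a candidate is admissible when its weight stays
    positive everywhere and is nondecreasing beyond ``sigma*`` (within
    ``mono_tol`` per cell).  The scan stops at the first failure and the
    last admissible candidate wins.  With ``B_star >= 1`` the result is
    flagged inadmissible from the start (weight reported at
    ``lambda = 0``); an empty scan is distinguished from that case in
    ``reason``.
    """
    p_vals = _p_star_values(rate_star, grid)
    pM = float(np.max(p_vals))
    j_sigma = grid.index_of(sigma_star) if sigma_star > 0 else 0

    def admissible_profile(P: np.ndarray) -> bool:
        if not np.all(P > 0.0):
            return False
        if np.max(P) >= OVERFLOW_CAP:
            return False
        tail = P[j_sigma:]
        return bool(np.all(np.diff(tail) >= -mono_tol))

    if B_star >= 1.0:
        P0 = dual_P(0.0, p_vals, kern, grid, sigma_star=sigma_star or None)
        return DualEigenresult(
            grid=grid, P_values=P0, lam=0.0, B_star=B_star,
            B_ratio=_b_ratio(np.clip(P0, 1e-300, None)), admissible=False,
            sigma_star=sigma_star, reason="B_star >= 1: smallness condition fails",
        )

    best: Optional[tuple[float, np.ndarray]] = None
    for k in range(n_scan - 1, -1, -1):
        lam = -pM / 4.0 * 2.0 ** (-k)
        P = dual_P(lam, p_vals, kern, grid, sigma_star=sigma_star or None)
        if admissible_profile(P):
            best = (lam, P)
        else:
            break
    if best is None:
        P0 = dual_P(0.0, p_vals, kern, grid, sigma_star=sigma_star or None)
        return DualEigenresult(
            grid=grid, P_values=P0, lam=0.0, B_star=B_star,
            B_ratio=_b_ratio(np.clip(P0, 1e-300, None)), admissible=False,
            sigma_star=sigma_star, reason="scan exhausted: no admissible lambda < 0",
        )
    lam, P = best
    return DualEigenresult(
        grid=grid, P_values=P, lam=lam, B_star=B_star,
        B_ratio=_b_ratio(P), admissible=True, sigma_star=sigma_star,
    )


def prop_B1_rate(
    rate: FiringRate,
    kern: FragmentationKernel,
    grid: Grid,
    A_star: float = 0.0,
) -> float:
    """Direct decay rate ``nu`` for point-map kernels and smooth rates.

    With ``psi_bar(u) = u - psi(u)`` (the rejuvenation gap),

        nu = inf_u [ p(u) psi_bar'(u) - |p'(u)| psi_bar(u) ];

    a positive value certifies ``int |M(., t)| <= int |M(., 0)| e^{-nu t}``
    without any weight.  Sharp step rates have a singular ``|p'|`` and
    are rejected.
    """
    if kern.family != "point_map":
        raise ValueError("the direct certificate requires a point-map kernel")
    sigma_star = float(rate.sigma(A_star))
    if rate.smoothing_width == 0.0 and sigma_star > 0.0:
        raise ValueError(
            "step rates have a singular |p'|; the direct certificate "
            "requires a differentiable (regularized) rate"
        )
    u = grid.nodes
    psi_u = np.minimum(np.asarray(kern.psi(u), dtype=float), u)
    psi_bar = u - psi_u
    if kern.psi_prime is not None:
        psi_bar_prime = 1.0 - np.asarray(kern.psi_prime(u), dtype=float) * np.ones_like(u)
    else:
        psi_bar_prime = np.gradient(psi_bar, u)
    p_vals = np.asarray(firing_rate_eval(u, A_star, rate), dtype=float)
    p_prime = np.abs(np.gradient(p_vals, u)) if len(u) > 1 else np.zeros_like(u)
    return float(np.min(p_vals * psi_bar_prime - p_prime * psi_bar))
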