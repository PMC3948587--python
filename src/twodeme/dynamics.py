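"""Right-hand sides and numerical integration of the two-deme dynamics.

Three dynamical modes are provided:

* :func:`gamete_rhs` -- the selection/recombination/migration flow on the
  product of two simplices, one per deme:

      dx_i/dt = x_i (w_i - wbar) - eta_i * rho * D + m_k (x_i' - x_i)

  with ``eta = (1, -1, -1, 1)`` and ``D = x1*x4 - x2*x3``.

* :func:`allele_ld_rhs` -- the equivalent flow in ``(p, q, D)`` coordinates,

      dp_k/dt = alpha_k p_k (1 - p_k) + beta_k D_k + m_k (p_k' - p_k)
      dq_k/dt = beta_k q_k (1 - q_k) + alpha_k D_k + m_k (q_k' - q_k)
      dD_k/dt = [alpha_k (1 - 2 p_k) + beta_k (1 - 2 q_k) - rho] D_k
                + m_k [(D_k' - D_k) + (p_k' - p_k)(q_k' - q_k)]

* :func:`le_rhs` -- the linkage-equilibrium limit, in which the loci
  decouple into two independent one-locus two-deme systems on [0, 1]^2.

The same right-hand side describes a haploid population with allelic
fitnesses ``+-alpha_k``, ``+-beta_k``; genic selection without dominance
makes the diploid marginal dynamics identical.

:func:`integrate` runs an adaptive stiff-capable solver (LSODA) in
geometrically growing time chunks until the sup-norm of the right-hand
side falls below a convergence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ModelParameters
from .state import d_bounds

__all__ = [
    "gamete_rhs",
    "allele_ld_rhs",
    "le_rhs",
    "jacobian",
    "trigametic_rhs",
    "trigametic_jacobian",
    "IntegrationResult",
    "integrate",
    "integrate_le",
]

_ETA = np.array([1.0, -1.0, -1.0, 1.0])


def _unpack(params: ModelParameters):
    sel, mig = params.selection, params.migration
    return (
        np.array([sel.alpha1, sel.alpha2]),
        np.array([sel.beta1, sel.beta2]),
        np.array([mig.m1, mig.m2]),
    )


def gamete_rhs(x: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative of the (2, 4) gamete-frequency array."""
    if params.is_le:
        raise ValueError("gamete dynamics need a finite rho; use le_rhs for LE")
    alpha, beta, m = _unpack(params)
    rho = params.rho_value
    x = np.asarray(x)
    # additive contribution of each gamete's own alleles; marginal fitness
    # is this plus the mean contribution, and the mean cancels pairwise
    c = 0.5 * (
        alpha[:, None] * np.array([1.0, 1.0, -1.0, -1.0])
        + beta[:, None] * np.array([1.0, -1.0, 1.0, -1.0])
    )
    cbar = (x * c).sum(axis=1, keepdims=True)
    D = x[:, 0] * x[:, 3] - x[:, 1] * x[:, 2]
    dx = x * (c - cbar) - _ETA[None, :] * rho * D[:, None]
    dx += m[:, None] * (x[::-1] - x)
    return dx


def allele_ld_rhs(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative of ``(p1, p2, q1, q2, D1, D2)``."""
    if params.is_le:
        raise ValueError("allele/LD dynamics need a finite rho; use le_rhs for LE")
    alpha, beta, m = _unpack(params)
    rho = params.rho_value
    y = np.asarray(y)
    p, q, D = y[0:2], y[2:4], y[4:6]
    dp = alpha * p * (1.0 - p) + beta * D + m * (p[::-1] - p)
    dq = beta * q * (1.0 - q) + alpha * D + m * (q[::-1] - q)
    dD = (alpha * (1.0 - 2.0 * p) + beta * (1.0 - 2.0 * q) - rho) * D + m * (
        (D[::-1] - D) + (p[::-1] - p) * (q[::-1] - q)
    )
    return np.concatenate([dp, dq, dD])


def le_rhs(u: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Linkage-equilibrium dynamics of ``(p1, p2, q1, q2)``.

    The two loci evolve as independent one-locus migration-selection
    systems; locus A never references q and vice versa.
    """
    alpha, beta, m = _unpack(params)
    u = np.asarray(u)
    p, q = u[0:2], u[2:4]
    dp = alpha * p * (1.0 - p) + m * (p[::-1] - p)
    dq = beta * q * (1.0 - q) + m * (q[::-1] - q)
    return np.concatenate([dp, dq])


def jacobian(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Analytic 6x6 Jacobian of :func:`allele_ld_rhs`."""
    alpha, beta, m = _unpack(params)
    rho = params.rho_value
    y = np.asarray(y, dtype=float)
    p, q, D = y[0:2], y[2:4], y[4:6]
    J = np.zeros((6, 6))
    for k in (0, 1):
        o = 1 - k  # other deme
        # dp_k row
        J[k, k] = alpha[k] * (1.0 - 2.0 * p[k]) - m[k]
        J[k, o] = m[k]
        J[k, 4 + k] = beta[k]
        # dq_k row
        J[2 + k, 2 + k] = beta[k] * (1.0 - 2.0 * q[k]) - m[k]
        J[2 + k, 2 + o] = m[k]
        J[2 + k, 4 + k] = alpha[k]
        # dD_k row
        J[4 + k, k] = -2.0 * alpha[k] * D[k] - m[k] * (q[o] - q[k])
        J[4 + k, o] = m[k] * (q[o] - q[k])
        J[4 + k, 2 + k] = -2.0 * beta[k] * D[k] - m[k] * (p[o] - p[k])
        J[4 + k, 2 + o] = m[k] * (p[o] - p[k])
        J[4 + k, 4 + k] = (
            alpha[k] * (1.0 - 2.0 * p[k]) + beta[k] * (1.0 - 2.0 * q[k]) - rho - m[k]
        )
        J[4 + k, 4 + o] = m[k]
    return J


def trigametic_rhs(z: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Dynamics restricted to the rho = 0 subsystem without gamete A1B2.

    With complete linkage the four gametes behave as alleles of one locus;
    the repulsion gamete A1B2 is always lost, and the invariant subsystem
    spanned by {A1B1, A2B1, A2B2} carries the remaining dynamics.
    Coordinates: ``z = (x1_1, x3_1, x1_2, x3_2)`` with ``x4 = 1 - x1 - x3``.
    """
    z = np.asarray(z)
    x = np.zeros((2, 4), dtype=z.dtype)
    x[0, 0], x[0, 2] = z[0], z[1]
    x[1, 0], x[1, 2] = z[2], z[3]
    x[:, 3] = 1.0 - x[:, 0] - x[:, 2]
    dx = gamete_rhs(x, params)
    return np.array([dx[0, 0], dx[0, 2], dx[1, 0], dx[1, 2]])


def trigametic_jacobian(z: np.ndarray, params: ModelParameters) -> np.ndarray:
    """4x4 Jacobian of :func:`trigametic_rhs` by complex-step differentiation
    (the flow is polynomial, so this is exact to machine precision)."""
    z = np.asarray(z, dtype=float)
    n = z.size
    J = np.empty((n, n))
    h = 1e-200
    for j in range(n):
        zc = z.astype(complex)
        zc[j] += 1j * h
        J[:, j] = trigametic_rhs(zc, params).imag / h
    return J


@dataclass
class IntegrationResult:
    """Terminal state of a convergence run plus optional trajectory."""

    y: np.ndarray
    t: float
    converged: bool
    rhs_norm: float
    trajectory_t: np.ndarray | None = None
    trajectory_y: np.ndarray | None = None  # shape (n_points, dim)


def _clip_pqd(y: np.ndarray, tol: float) -> np.ndarray:
    """Project tiny constraint violations back onto the state space; raise
    if the violation exceeds ``tol`` (silent clipping would mask solver
    failure)."""
    y = np.array(y, dtype=float)
    worst = 0.0
    for idx in range(4):
        worst = max(worst, -y[idx], y[idx] - 1.0)
    y[:4] = np.clip(y[:4], 0.0, 1.0)
    for k in (0, 1):
        lo, hi = d_bounds(y[k], y[2 + k])
        worst = max(worst, lo - y[4 + k], y[4 + k] - hi)
        y[4 + k] = min(max(y[4 + k], lo), hi)
    if worst > tol:
        raise RuntimeError(
            f"state left the constraint set by {worst:.2e} (> {tol:.0e}); "
            "integration aborted"
        )
    return y


def integrate(
    y0: np.ndarray,
    params: ModelParameters,
    *,
    horizon: float = 1e6,
    rhs_tol: float = 1e-10,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    clip_tol: float = 1e-9,
    keep_trajectory: bool = False,
) -> IntegrationResult:
    """Integrate the dynamics until the rhs sup-norm drops below ``rhs_tol``.

    For the LE sentinel the decoupled system :func:`le_rhs` is integrated
    on ``(p1, p2, q1, q2)`` and the result is reported with ``D = 0``.
    Non-convergence within ``horizon`` is flagged, not raised.
    """
    if params.is_le:
        res = integrate_le(
            np.asarray(y0)[:4],
            params,
            horizon=horizon,
            rhs_tol=rhs_tol,
            rtol=rtol,
            atol=atol,
            keep_trajectory=keep_trajectory,
        )
        return res

    def f(_t, y):
        return allele_ld_rhs(y, params)

    def settled(_t, y):
        return float(np.abs(allele_ld_rhs(y, params)).max()) - rhs_tol

    settled.terminal = True
    settled.direction = -1.0

    y = _clip_pqd(np.asarray(y0, dtype=float), clip_tol)
    t = 0.0
    # chunk length set by the slowest rate in the problem; a terminal
    # event stops each chunk as soon as the flow has settled
    alpha, beta, m = _unpack(params)
    rates = [v for v in [*np.abs(alpha), *np.abs(beta), *m] if v > 0]
    slow = min(rates) if rates else 1e-3
    chunk = min(horizon, 50.0 / slow)
    ts, ys = [0.0], [y.copy()]
    converged = np.abs(f(t, y)).max() < rhs_tol
    while t < horizon and not converged:
        span = min(chunk, horizon - t)
        sol = solve_ivp(
            f, (t, t + span), y, method="LSODA", rtol=rtol, atol=atol,
            events=settled,
        )
        if not sol.success:
            break
        t = sol.t[-1]
        y = _clip_pqd(sol.y[:, -1], clip_tol)
        if keep_trajectory:
            ts.extend(sol.t[1:].tolist())
            ys.extend(_clip_pqd(c, clip_tol) for c in sol.y[:, 1:].T)
        if sol.status == 1 or np.abs(f(t, y)).max() < rhs_tol:
            converged = True
            break
        chunk *= 8.0
    norm = float(np.abs(f(t, y)).max())
    return IntegrationResult(
        y=y,
        t=t,
        converged=converged,
        rhs_norm=norm,
        trajectory_t=np.array(ts) if keep_trajectory else None,
        trajectory_y=np.array(ys) if keep_trajectory else None,
    )


def integrate_le(
    u0: np.ndarray,
    params: ModelParameters,
    *,
    horizon: float = 1e6,
    rhs_tol: float = 1e-10,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    keep_trajectory: bool = False,
) -> IntegrationResult:
    """Integrate the LE dynamics; the state is reported as a 6-vector with
    zero linkage disequilibrium."""

    def f(_t, u):
        return le_rhs(u, params)

    def settled(_t, u):
        return float(np.abs(le_rhs(u, params)).max()) - rhs_tol

    settled.terminal = True
    settled.direction = -1.0

    u = np.clip(np.asarray(u0, dtype=float), 0.0, 1.0)
    t = 0.0
    alpha, beta, m = _unpack(params)
    rates = [v for v in [*np.abs(alpha), *np.abs(beta), *m] if v > 0]
    slow = min(rates) if rates else 1e-3
    chunk = min(horizon, 50.0 / slow)
    ts, us = [0.0], [u.copy()]
    converged = np.abs(f(t, u)).max() < rhs_tol
    while t < horizon and not converged:
        span = min(chunk, horizon - t)
        sol = solve_ivp(
            f, (t, t + span), u, method="LSODA", rtol=rtol, atol=atol,
            events=settled,
        )
        if not sol.success:
            break
        t = sol.t[-1]
        u = np.clip(sol.y[:, -1], 0.0, 1.0)
        if keep_trajectory:
            ts.extend(sol.t[1:].tolist())
            us.extend(np.clip(c, 0.0, 1.0) for c in sol.y[:, 1:].T)
        if sol.status == 1 or np.abs(f(t, u)).max() < rhs_tol:
            converged = True
            break
        chunk *= 8.0
    norm = float(np.abs(f(t, u)).max())
    y = np.concatenate([u, [0.0, 0.0]])
    traj = None
    if keep_trajectory:
        traj = np.hstack([np.array(us), np.zeros((len(us), 2))])
    return IntegrationResult(
        y=y,
        t=t,
        converged=converged,
        rhs_norm=norm,
        trajectory_t=np.array(ts) if keep_trajectory else None,
        trajectory_y=traj,
    )
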