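"""Stability classification of equilibria.

Local stability is decided by the eigenvalues of the Jacobian of the
6-dimensional ``(p1, p2, q1, q2, D1, D2)`` flow (or of the 4-dimensional
tri-gametic subsystem when ``rho = 0``, where the repulsion gamete A1B2 is
always lost and is discarded first).  Closed-form conditions are
implemented for the monomorphic equilibria, for the complete-linkage
polymorphism ``F0`` and for the complete-linkage single-locus
polymorphisms; they are cross-checked against the numerical eigenvalues in
the test-suite.

Boundary cases (an eigenvalue real part within the marginality tolerance
of zero) are reported as ``marginal`` and never silently rounded to
stable/unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .critical_rates import compute_ratios, m_tilde
from .dynamics import (
    allele_ld_rhs,
    jacobian,
    le_rhs,
    trigametic_jacobian,
)
from .equilibria import EquilibriumRecord, f_zero
from .parameters import ModelParameters

__all__ = [
    "StabilityVerdict",
    "classify",
    "classify_le",
    "classify_rho0_subsystem",
    "monomorphic_stability",
    "f_zero_stability",
    "slp_stability_rho0",
]

MARGINAL_TOL = 1e-8


@dataclass
class StabilityVerdict:
    classification: str  # asymptotically_stable | unstable | marginal
    leading_real_part: float
    method: str  # closed_form | eigenvalue
    eigenvalues: np.ndarray | None = None

    @property
    def stable(self) -> bool:
        return self.classification == "asymptotically_stable"


def _verdict_from_leading(
    leading: float, tol: float, method: str, eigs: np.ndarray | None = None
) -> StabilityVerdict:
    if abs(leading) <= tol:
        cls = "marginal"
    elif leading < 0:
        cls = "asymptotically_stable"
    else:
        cls = "unstable"
    return StabilityVerdict(cls, float(leading), method, eigs)


def classify(
    equilibrium: EquilibriumRecord | np.ndarray,
    params: ModelParameters,
    tol: float = MARGINAL_TOL,
    residual_tol: float = 1e-8,
) -> StabilityVerdict:
    """Eigenvalue classification of an equilibrium of the finite-rho flow."""
    y = equilibrium.y if isinstance(equilibrium, EquilibriumRecord) else np.asarray(equilibrium)
    if params.is_le:
        return classify_le(y, params, tol)
    res = np.abs(allele_ld_rhs(y, params)).max()
    if res > residual_tol:
        raise ValueError(f"not an equilibrium: rhs residual {res:.2e}")
    eigs = np.linalg.eigvals(jacobian(y, params))
    leading = float(eigs.real.max())
    verdict = _verdict_from_leading(leading, tol, "eigenvalue", eigs)
    if isinstance(equilibrium, EquilibriumRecord):
        equilibrium.stability = verdict
    return verdict


def classify_le(
    y: np.ndarray, params: ModelParameters, tol: float = MARGINAL_TOL
) -> StabilityVerdict:
    """Eigenvalue classification within the 4-dimensional LE dynamics."""
    u = np.asarray(y)[:4].astype(float)
    n = 4
    J = np.empty((n, n))
    h = 1e-200
    for j in range(n):
        uc = u.astype(complex)
        uc[j] += 1j * h
        J[:, j] = le_rhs(uc, params).imag / h
    eigs = np.linalg.eigvals(J)
    return _verdict_from_leading(float(eigs.real.max()), tol, "eigenvalue", eigs)


def classify_rho0_subsystem(
    y: np.ndarray, params: ModelParameters, tol: float = MARGINAL_TOL
) -> StabilityVerdict:
    """Eigenvalue classification in the rho = 0 tri-gametic subsystem
    {A1B1, A2B1, A2B2} (gamete A1B2 is discarded; it is always lost)."""
    from .state import pqd_to_gametes

    x = pqd_to_gametes(np.asarray(y, dtype=float))
    z = np.array([x[0, 0], x[0, 2], x[1, 0], x[1, 2]])
    eigs = np.linalg.eigvals(trigametic_jacobian(z, params))
    return _verdict_from_leading(float(eigs.real.max()), tol, "eigenvalue", eigs)


def monomorphic_stability(
    params: ModelParameters, tol: float = MARGINAL_TOL
) -> dict[str, StabilityVerdict]:
    """Closed-form stability of M1..M4 (canonical parameters, theta > 0).

    M1 (M4) is stable iff both alleles' immigration pressure exceeds the
    protection bounds at both loci and, for tight linkage, the repulsion
    of the fully-polymorphic direction is also lost; M2 is always
    unstable; M3's stability is independent of the recombination rate.
    """
    sel, mig = params.selection, params.migration
    a1, a2, b1, b2 = sel.alpha1, sel.alpha2, sel.beta1, sel.beta2
    m1, m2 = mig.m1, mig.m2
    rho = math.inf if params.is_le else params.rho_value
    r = compute_ratios(params)
    ss, ts = r.sigma_sum, r.tau_sum

    def margin_pair(*conds: float) -> StabilityVerdict:
        # conds are margins that must all be > 0 for stability
        worst = min(conds)
        if abs(worst) <= tol:
            return StabilityVerdict("marginal", 0.0, "closed_form")
        cls = "asymptotically_stable" if worst > 0 else "unstable"
        return StabilityVerdict(cls, -worst, "closed_form")

    def ld_block_margins(d1: float, d2: float) -> list[float]:
        """Stability margins of the 2x2 LD-direction block
        [[d1, m1], [m2, d2]]: negative trace and positive determinant."""
        if math.isinf(rho):
            return []  # LE: the LD directions decay instantaneously
        return [-(d1 + d2), d1 * d2 - m1 * m2]

    # M1: protection of the immigrant alleles lost at both loci, plus decay
    # of the locally-adapted-haplotype (LD) direction
    conds1 = [-1.0 - ss, -1.0 - ts]
    conds1 += ld_block_margins(
        -(a1 + b1 + rho) - m1, -(a2 + b2 + rho) - m2
    )
    m1_verdict = margin_pair(*conds1)

    m2_verdict = StabilityVerdict("unstable", math.nan, "closed_form")

    m3_verdict = margin_pair(ss - 1.0, -1.0 - ts)

    conds4 = [ss - 1.0, ts - 1.0]
    conds4 += ld_block_margins(a1 + b1 - rho - m1, a2 + b2 - rho - m2)
    m4_verdict = margin_pair(*conds4)

    return {"M1": m1_verdict, "M2": m2_verdict, "M3": m3_verdict, "M4": m4_verdict}


def f_zero_stability(
    params: ModelParameters, tol: float = MARGINAL_TOL
) -> StabilityVerdict:
    """Closed-form stability of the complete-linkage polymorphism F0:
    stable iff ``m1*m2 < m~``; on the boundary a line of equilibria with
    three gametes appears (zero eigenvalue)."""
    if params.is_le or params.rho_value != 0.0:
        raise ValueError("F0 stability applies to rho = 0 only")
    rec = f_zero(params)
    if not rec.admissible:
        raise ValueError("F0 is not admissible for these parameters")
    mt = m_tilde(params.selection)
    margin = mt - params.migration.m1 * params.migration.m2
    if abs(margin) <= tol:
        return StabilityVerdict("marginal", 0.0, "closed_form")
    cls = "asymptotically_stable" if margin > 0 else "unstable"
    return StabilityVerdict(cls, -margin, "closed_form")


def slp_stability_rho0(
    params: ModelParameters, tol: float = MARGINAL_TOL
) -> dict[str, StabilityVerdict]:
    """Closed-form stability of PA1 and PB2 under complete linkage.

    In the tri-gametic subsystem these are the only SLPs that can be
    stable: PA1 iff ``tau1+tau2 < -1``, ``|sigma1+sigma2| < 1`` and
    ``m1*m2 > m~``; PB2 iff ``sigma1+sigma2 > 1``, ``|tau1+tau2| < 1`` and
    ``m1*m2 > m~``.  On ``m1*m2 = m~`` both have a zero eigenvalue.
    """
    if params.is_le or params.rho_value != 0.0:
        raise ValueError("this closed form applies to rho = 0 only")
    r = compute_ratios(params)
    mt = m_tilde(params.selection)
    prod = params.migration.m1 * params.migration.m2

    def verdict(*margins: float) -> StabilityVerdict:
        worst = min(margins)
        if abs(worst) <= tol:
            return StabilityVerdict("marginal", 0.0, "closed_form")
        cls = "asymptotically_stable" if worst > 0 else "unstable"
        return StabilityVerdict(cls, -worst, "closed_form")

    pa1 = verdict(-1.0 - r.tau_sum, 1.0 - abs(r.sigma_sum), prod - mt)
    pb2 = verdict(r.sigma_sum - 1.0, 1.0 - abs(r.tau_sum), prod - mt)
    return {"PA1": pa1, "PB2": pb2}
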