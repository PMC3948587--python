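"""Invasion of a locally beneficial mutant linked to a polymorphic locus.

Setting: locus B is maintained polymorphic by migration-selection balance
(the resident population sits at the boundary equilibrium ``PB2`` where
``A2`` is fixed), and a mutant ``A1`` that is beneficial in deme 1 and
deleterious in deme 2 appears at the linked locus A.  The mutant invades
iff ``PB2`` is externally unstable, i.e. iff the leading eigenvalue of
the Jacobian restricted to the directions transversal to the B-locus
marginal system is positive.

For an isolated locus A the condition is classical: invasion iff the
polymorphism would be protected, ``m < m^A``, equivalently
``phi^A < phi < phi_inv`` with ``phi_inv = ((m - alpha2)/m) * phi^A``;
``phi_inv > 1`` iff ``m < alpha1``, so a mutant always invades when the
total migration rate is below its local advantage.

Linkage enlarges the invasion region: for ``phi > phi_inv`` invasion is
possible only below a maximum recombination rate ``rho_max``, and at fixed
rho the minimal invading advantage ``alpha_min`` shrinks to zero as the
mutant arises closer to the selected background locus.

At the boundary equilibrium the (p1, p2, D1, D2) directions decouple
exactly from the (q1, q2) marginal directions at linear order, so the
transversal spectrum is obtained from a 4x4 block of the analytic
Jacobian; no quartic is solved symbolically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .critical_rates import compute_ratios, phi_thresholds
from .dynamics import jacobian
from .equilibria import slp_equilibria
from .parameters import ModelParameters, SelectionRegime

__all__ = [
    "InvasionResult",
    "one_locus_invasion",
    "external_stability_PB2",
    "rho_max_for_invasion",
    "alpha_min_for_invasion",
]


@dataclass
class InvasionResult:
    invades: bool
    leading_external_eigenvalue: float | None
    phi_inv: float
    m_A: float
    phi_A: float


def one_locus_invasion(
    alpha1: float, alpha2: float, m: float, phi: float
) -> InvasionResult:
    """Invasion condition for the isolated locus A (no linked background).

    Treats the regime ``phi > phi^A`` in which the deleterious influx into
    deme 1 protects ``A2``; the mirrored case follows by relabelling.
    """
    if not (alpha1 > 0 > alpha2):
        raise ValueError("need alpha1 > 0 > alpha2")
    phi_A = alpha1 / (alpha1 - alpha2)
    if phi <= phi_A:
        raise ValueError(
            "phi <= phi^A: relabel demes/alleles to study invasion of the "
            "allele under influx (the condition is symmetric)"
        )
    den = alpha1 - phi * (alpha1 - alpha2)
    m_A = alpha1 * alpha2 / den if den != 0 else math.inf
    phi_inv = (m - alpha2) / m * phi_A
    # the equivalent forms of the condition: m < m^A  <=>  phi < phi_inv
    return InvasionResult(bool(phi < phi_inv), None, phi_inv, m_A, phi_A)


def external_stability_PB2(params: ModelParameters) -> float:
    """Leading transversal eigenvalue (real part) at the SLP ``PB2``.

    Positive means the locally beneficial mutant A1 invades the B-locus
    migration-selection balance.  Raises if PB2 is inadmissible.
    """
    r = compute_ratios(params)
    if abs(r.tau_sum) >= 1.0:
        raise ValueError("PB2 inadmissible: |tau1 + tau2| >= 1")
    pb2 = next(rec for rec in slp_equilibria(params) if rec.label == "PB2")
    J = jacobian(pb2.y, params)
    idx = np.array([0, 1, 4, 5])  # (p1, p2, D1, D2): transversal block
    eigs = np.linalg.eigvals(J[np.ix_(idx, idx)])
    return float(eigs.real.max())


def _params_with(params: ModelParameters, *, alpha1=None, rho=None) -> ModelParameters:
    sel = params.selection
    return ModelParameters(
        SelectionRegime(
            sel.alpha1 if alpha1 is None else alpha1,
            sel.alpha2,
            sel.beta1,
            sel.beta2,
        ),
        params.migration,
        params.rho if rho is None else rho,
    )


def rho_max_for_invasion(
    params: ModelParameters, *, rel_tol: float = 1e-8, rho_hi: float | None = None
) -> float:
    """Maximum recombination rate below which A1 invades PB2.

    Infinite when ``phi <= phi_inv`` (invasion unconditional in rho);
    otherwise located by bisection of the leading external eigenvalue,
    which is positive under tight linkage and negative under loose
    linkage in this regime.
    """
    sel, mig = params.selection, params.migration
    phi_A = phi_thresholds(sel).phi_A
    phi_inv = (mig.m - sel.alpha2) / mig.m * phi_A
    if mig.phi <= phi_inv:
        return math.inf
    lo = 0.0
    if rho_hi is None:
        rho_hi = 10.0 * max(abs(sel.beta1), abs(sel.beta2), mig.m, 1.0)
    hi = rho_hi
    f_hi = external_stability_PB2(_params_with(params, rho=hi))
    while f_hi > 0:
        hi *= 4.0
        if hi > 1e12:
            return math.inf
        f_hi = external_stability_PB2(_params_with(params, rho=hi))
    while hi - lo > rel_tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if external_stability_PB2(_params_with(params, rho=mid)) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def alpha_min_for_invasion(
    params: ModelParameters, *, rel_tol: float = 1e-8
) -> float:
    """Minimal selective advantage ``alpha1`` allowing A1 to invade PB2 at
    the given recombination rate, migration patterns and background locus.

    Zero (up to tolerance) under tight linkage; approaches the one-locus
    threshold ``m1 / (1 - m2/alpha2)`` as rho grows."""
    lo = 0.0
    hi = max(abs(params.selection.beta1), params.migration.m, 1.0)
    f_hi = external_stability_PB2(_params_with(params, alpha1=hi))
    while f_hi < 0:
        hi *= 4.0
        if hi > 1e9:
            raise RuntimeError("no invading alpha1 found below 1e9")
        f_hi = external_stability_PB2(_params_with(params, alpha1=hi))
    while hi - lo > rel_tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if external_stability_PB2(_params_with(params, alpha1=mid)) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
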