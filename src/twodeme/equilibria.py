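"""Closed-form and numerical equilibria of the two-deme dynamics.

Three families of equilibria exist:

* four monomorphic equilibria (ME) ``M1..M4``, one per gamete, which exist
  always;
* up to four single-locus polymorphisms (SLPs) ``PA1, PA2, PB1, PB2`` with
  one locus polymorphic in both demes and the other fixed, in linkage
  equilibrium (``D = 0``), with explicit coordinates in terms of the
  ratios ``sigma_k`` and ``tau_k``;
* full polymorphisms (FPs).  Closed forms are available in limiting
  regimes: ``F_inf`` (linkage equilibrium, the Cartesian product of the
  two one-locus polymorphisms), ``F_0`` (complete linkage, only the
  locally adapted gametes present), a weak-migration expansion of the
  stable FP and a strong-recombination (QLE) expansion.  For general
  parameters :func:`find_internal` locates interior roots numerically.

Interior equilibria always carry linkage disequilibrium: an internal root
with ``D1 = D2 = 0`` would force equality of allele frequencies across
demes, which only happens on the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .critical_rates import compute_ratios
from .dynamics import allele_ld_rhs
from .parameters import ModelParameters
from .state import pqd_to_gametes

__all__ = [
    "EquilibriumRecord",
    "monomorphic_equilibria",
    "slp_equilibria",
    "f_infinity",
    "f_zero",
    "weak_migration_F",
    "qle_F",
    "find_internal",
]

MONOMORPHIC_COORDS = {
    "M1": np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0]),
    "M2": np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0]),
    "M3": np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0]),
    "M4": np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
}


@dataclass
class EquilibriumRecord:
    """An equilibrium candidate: coordinates, label and provenance.

    ``admissible`` records whether the coordinates lie in the state space;
    inadmissible closed-form equilibria are returned flagged rather than
    omitted so that bifurcation tracking can follow them outside the
    simplex.  ``stability`` is attached by the stability module.
    """

    label: str
    y: np.ndarray
    admissible: bool
    source: str  # closed_form | weak_migration_approx | qle_approx | numeric
    stability: Optional[object] = None
    near_bifurcation: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def gametes(self) -> np.ndarray:
        return pqd_to_gametes(self.y)

    def residual(self, params: ModelParameters) -> float:
        return float(np.abs(allele_ld_rhs(self.y, params)).max())


def monomorphic_equilibria() -> list[EquilibriumRecord]:
    """The four fixation states; they are equilibria for any parameters."""
    return [
        EquilibriumRecord(label, coords.copy(), True, "closed_form")
        for label, coords in MONOMORPHIC_COORDS.items()
    ]


def _one_locus_pair(r1: float, r2: float) -> tuple[float, float]:
    """Equilibrium frequencies of the protected one-locus polymorphism with
    migration/selection ratios (r1, r2); r = 0 gives full differentiation."""
    root = math.sqrt(max(1.0 - 4.0 * r1 * r2, 0.0))
    return 0.5 * (1.0 - 2.0 * r1 + root), 0.5 * (1.0 - 2.0 * r2 - root)


def slp_equilibria(params: ModelParameters) -> list[EquilibriumRecord]:
    """The four single-locus polymorphisms with admissibility flags.

    The A-locus pair ``PA1``/``PA2`` is admissible iff ``|sigma1+sigma2|<1``
    and the B-locus pair iff ``|tau1+tau2|<1``; when the bound is crossed
    each SLP leaves the state space through a neighbouring monomorphism
    (recorded in ``extras['exit_target']``).
    """
    r = compute_ratios(params)
    pA1, pA2 = _one_locus_pair(r.sigma1, r.sigma2)
    qB1, qB2 = _one_locus_pair(r.tau1, r.tau2)
    adm_A = abs(r.sigma_sum) < 1.0
    adm_B = abs(r.tau_sum) < 1.0
    exit_A = {"PA1": "M3", "PA2": "M4"} if r.sigma_sum >= 0 else {"PA1": "M1", "PA2": "M2"}
    exit_B = {"PB1": "M2", "PB2": "M4"} if r.tau_sum >= 0 else {"PB1": "M1", "PB2": "M3"}
    recs = [
        EquilibriumRecord(
            "PA1", np.array([pA1, pA2, 1.0, 1.0, 0.0, 0.0]), adm_A, "closed_form",
            extras={"exit_target": exit_A["PA1"]},
        ),
        EquilibriumRecord(
            "PA2", np.array([pA1, pA2, 0.0, 0.0, 0.0, 0.0]), adm_A, "closed_form",
            extras={"exit_target": exit_A["PA2"]},
        ),
        EquilibriumRecord(
            "PB1", np.array([1.0, 1.0, qB1, qB2, 0.0, 0.0]), adm_B, "closed_form",
            extras={"exit_target": exit_B["PB1"]},
        ),
        EquilibriumRecord(
            "PB2", np.array([0.0, 0.0, qB1, qB2, 0.0, 0.0]), adm_B, "closed_form",
            extras={"exit_target": exit_B["PB2"]},
        ),
    ]
    return recs


def f_infinity(params: ModelParameters) -> EquilibriumRecord:
    """The fully polymorphic equilibrium of the LE dynamics: the Cartesian
    product of the two one-locus polymorphisms.  Admissible iff all four
    SLPs are admissible."""
    r = compute_ratios(params)
    pA1, pA2 = _one_locus_pair(r.sigma1, r.sigma2)
    qB1, qB2 = _one_locus_pair(r.tau1, r.tau2)
    adm = abs(r.sigma_sum) < 1.0 and abs(r.tau_sum) < 1.0
    return EquilibriumRecord(
        "Finf", np.array([pA1, pA2, qB1, qB2, 0.0, 0.0]), adm, "closed_form"
    )


def f_zero(params: ModelParameters) -> EquilibriumRecord:
    """The complete-linkage full polymorphism, at which only the locally
    adapted gametes ``A1B1`` and ``A2B2`` segregate.

    With ``rho = 0`` the gametes behave as alleles of a single locus with
    effects ``(alpha_k + beta_k)/2``; the two-gamete subsystem has the
    one-locus polymorphism at ratios ``kappa_k``, admissible iff
    ``|kappa1 + kappa2| < 1``.  ``D_k = p_k (1 - p_k)`` there (maximal LD).
    """
    r = compute_ratios(params)
    p1, p2 = _one_locus_pair(r.kappa1, r.kappa2)
    adm = abs(r.kappa_sum) < 1.0
    y = np.array(
        [p1, p2, p1, p2, p1 * (1.0 - p1), p2 * (1.0 - p2)]
    )
    exit_target = "M4" if r.kappa_sum >= 0 else "M1"
    return EquilibriumRecord(
        "F0", y, adm, "closed_form", extras={"exit_target": exit_target}
    )


def weak_migration_F(params: ModelParameters) -> EquilibriumRecord:
    """Leading-order coordinates of the stable full polymorphism for weak
    migration; exact at ``m = 0`` and accurate to O(m^2).

    LD is positive in both demes: migration imports locally adapted
    haplotype blocks, and recombination erodes the excess only at rate
    ``rho`` relative to the haplotype selection differential.
    """
    sel, mig = params.selection, params.migration
    a1, a2, b1, b2 = sel.alpha1, sel.alpha2, sel.beta1, sel.beta2
    rho = params.rho_value
    m1, m2 = mig.m1, mig.m2
    p1 = 1.0 - (m1 / a1) * (a1 + rho) / (a1 + b1 + rho)
    q1 = 1.0 - (m1 / b1) * (b1 + rho) / (a1 + b1 + rho)
    D1 = m1 / (a1 + b1 + rho)
    p2 = (m2 / -a2) * (rho - a2) / (rho - a2 - b2)
    q2 = (m2 / -b2) * (rho - b2) / (rho - a2 - b2)
    D2 = m2 / (rho - a2 - b2)
    y = np.array([p1, p2, q1, q2, D1, D2])
    adm = bool(np.all(pqd_to_gametes(y) >= 0))
    return EquilibriumRecord("F", y, adm, "weak_migration_approx")


def _qle_deme1(params: ModelParameters, finf_y: np.ndarray) -> tuple[float, float, float]:
    sel, mig = params.selection, params.migration
    a1, a2, b1, b2 = sel.alpha1, sel.alpha2, sel.beta1, sel.beta2
    rho = params.rho_value
    r = compute_ratios(params)
    p1i, p2i, q1i, q2i = finf_y[:4]
    sq_s = math.sqrt(1.0 - 4.0 * r.sigma1 * r.sigma2)
    sq_t = math.sqrt(1.0 - 4.0 * r.tau1 * r.tau2)
    p1 = p1i + (r.sigma1 / rho) * (
        (r.sigma2 * (b1 - b2) + b1 * sq_s) / sq_s
    ) * (q1i - q2i)
    q1 = q1i + (r.tau1 / rho) * (
        (r.tau2 * (a1 - a2) + a1 * sq_t) / sq_t
    ) * (p1i - p2i)
    D1 = (mig.m1 / rho) * (p1i - p2i) * (q1i - q2i)
    return p1, q1, D1


def qle_F(params: ModelParameters) -> EquilibriumRecord:
    """Quasi-linkage-equilibrium approximation of the full polymorphism:
    the LE product equilibrium plus O(1/rho) corrections; LD is positive
    and O(1/rho) in both demes whenever the demes are differentiated.

    The deme-2 coordinates follow from the deme-1 formulas through the
    deme-exchange symmetry of the model.  Raises if the LE equilibrium is
    inadmissible.
    """
    finf = f_infinity(params)
    if not finf.admissible:
        raise ValueError("QLE approximation needs an admissible LE polymorphism")
    rho = params.rho_value
    if rho <= 0:
        raise ValueError("QLE approximation needs rho > 0")
    p1, q1, D1 = _qle_deme1(params, finf.y)
    # deme exchange: alpha~_k = -alpha_{k*}, m~_1 = m_2, p~_k = 1 - p_{k*}
    from .parameters import CanonicalTransform

    swap = CanonicalTransform(swap_demes=True)
    sel, mig = params.selection, params.migration
    from .parameters import MigrationRegime, SelectionRegime

    params_sw = ModelParameters(
        SelectionRegime(-sel.alpha2, -sel.alpha1, -sel.beta2, -sel.beta1),
        MigrationRegime(mig.m2, mig.m1),
        params.rho,
    )
    finf_sw = swap.apply_state(finf.y)
    p2s, q2s, D2 = _qle_deme1(params_sw, finf_sw)
    p2, q2 = 1.0 - p2s, 1.0 - q2s
    y = np.array([p1, p2, q1, q2, D1, D2])
    adm = bool(np.all(pqd_to_gametes(y) >= 0))
    return EquilibriumRecord("F", y, adm, "qle_approx")


def _interior_seeds(params: ModelParameters, n_grid: int = 3) -> list[np.ndarray]:
    seeds = []
    try:
        seeds.append(weak_migration_F(params).y)
    except Exception:
        pass
    try:
        if params.rho_value > 0:
            seeds.append(qle_F(params).y)
    except Exception:
        pass
    f0 = f_zero(params)
    if f0.admissible:
        # pull slightly off the two-gamete edge for positive rho
        y = f0.y.copy()
        y[4:6] *= 0.9
        seeds.append(y)
    vals = np.linspace(0.25, 0.75, n_grid)
    for p1 in vals:
        for q1 in vals:
            seeds.append(np.array([p1, 1.0 - p1, q1, 1.0 - q1, 0.02, 0.02]))
    return seeds


def find_internal(
    params: ModelParameters,
    *,
    extra_seeds: list[np.ndarray] | None = None,
    merge_tol: float = 1e-8,
    residual_tol: float = 1e-11,
    interior_tol: float = 1e-7,
    max_roots_warn: int = 2,
) -> list[EquilibriumRecord]:
    """Numerically locate interior equilibria at finite ``rho > 0``.

    Multi-start quasi-Newton root search on the 6-dimensional right-hand
    side, seeded from the analytic approximations (weak migration, QLE,
    complete-linkage) and a coarse interior grid, plus any caller-supplied
    continuation seeds.  Roots are merged within ``merge_tol`` and only
    points strictly inside the state space are returned (0, 1 or 2 roots
    generically; more are reported with a warning flag in ``extras``).
    """
    if params.is_le:
        raise ValueError("find_internal needs finite rho; use f_infinity for LE")
    if params.rho_value == 0.0:
        raise ValueError("find_internal needs rho > 0; use f_zero for rho = 0")

    seeds = list(extra_seeds or []) + _interior_seeds(params)
    roots: list[np.ndarray] = []
    for seed in seeds:
        sol = optimize.root(
            lambda y: allele_ld_rhs(y, params), np.asarray(seed, dtype=float),
            method="hybr", tol=1e-12,
        )
        if not sol.success:
            continue
        y = sol.x
        if np.abs(allele_ld_rhs(y, params)).max() > residual_tol:
            continue
        if pqd_to_gametes(y).min() <= interior_tol:
            continue
        if any(np.abs(y - r).max() < merge_tol for r in roots):
            continue
        roots.append(y)
    near = []
    for i, a in enumerate(roots):
        flag = any(
            merge_tol <= np.abs(a - b).max() < 1e-4
            for j, b in enumerate(roots)
            if j != i
        )
        near.append(flag)
    records = [
        EquilibriumRecord(
            "F" if i == 0 else "F_other",
            y,
            True,
            "numeric",
            near_bifurcation=near[i],
            extras={"excess_roots": len(roots) > max_roots_warn},
        )
        for i, y in enumerate(roots)
    ]
    return records
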