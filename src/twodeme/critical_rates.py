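"""Critical migration rates and threshold migration ratios.

For fixed selection coefficients and migration ratio ``phi = m1/m``, the
equilibrium structure changes at a small set of critical total migration
rates.  This module provides:

* the dimensionless migration/selection ratios
  ``sigma_k = m_k/alpha_k``, ``tau_k = m_k/beta_k``,
  ``kappa_k = m_k/(alpha_k + beta_k)``;
* the threshold ratios ``phi^A, phi^B, phi^F0, phi~^AB, phi^AB, phi^M1,
  phi~^M1, phi^M4, phi~^M4, phi^AF0, phi^BF0`` at which critical rates
  change sign, collide or diverge;
* the critical rates ``m^A, m^B, m^F0, m^M1, m^M4`` (signed, with explicit
  infinity sentinels at the phi thresholds), the repulsion-stability rate
  ``m*`` and the product threshold ``m~`` governing the complete-linkage
  polymorphism;
* maximum migration rates admitting a stable full polymorphism:
  closed forms for linkage equilibrium (``min{|m^A|, |m^B|}``) and for
  complete linkage (``min{|m^F0|, m*}``), a strong-recombination
  approximation, and a numerical continuation for general rho.

Infinity sentinels are explicit values (``math.inf``) rather than
exceptions so that downstream min/ordering logic is total.  Division by
zero at the defining phi thresholds is detected by exact comparison of the
denominator, not by an epsilon band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import LE, ModelParameters, SelectionRegime

__all__ = [
    "MigrationSelectionRatios",
    "PhiThresholds",
    "MThresholds",
    "CriticalRates",
    "compute_ratios",
    "phi_thresholds",
    "m_thresholds",
    "m_tilde",
    "critical_rates",
    "m_max_LE",
    "m_max_rho0",
    "m_max_qle",
    "MMaxNumericResult",
    "m_max_numeric",
]


@dataclass(frozen=True)
class MigrationSelectionRatios:
    sigma1: float
    sigma2: float
    tau1: float
    tau2: float
    kappa1: float
    kappa2: float

    @property
    def sigma_sum(self) -> float:
        return self.sigma1 + self.sigma2

    @property
    def tau_sum(self) -> float:
        return self.tau1 + self.tau2

    @property
    def kappa_sum(self) -> float:
        return self.kappa1 + self.kappa2


def compute_ratios(params: ModelParameters) -> MigrationSelectionRatios:
    """Dimensionless ratios of migration to selection per locus and deme."""
    sel, mig = params.selection, params.migration
    return MigrationSelectionRatios(
        sigma1=mig.m1 / sel.alpha1,
        sigma2=mig.m2 / sel.alpha2,
        tau1=mig.m1 / sel.beta1,
        tau2=mig.m2 / sel.beta2,
        kappa1=mig.m1 / (sel.alpha1 + sel.beta1),
        kappa2=mig.m2 / (sel.alpha2 + sel.beta2),
    )


def _ratio(num, den_minus):
    """num / (num - den_minus), the recurring threshold-ratio shape.

    Returns +inf when the denominator vanishes (the threshold plays no
    role then, e.g. the tilde-AB ratio outside the beta2 < alpha2 regime).
    """
    if num == den_minus:
        return math.inf
    return num / (num - den_minus)


@dataclass(frozen=True)
class PhiThresholds:
    """The eleven threshold migration ratios (those marked with a trailing
    underscore-free ``rho`` argument depend on the recombination rate)."""

    phi_A: float
    phi_B: float
    phi_F0: float
    phi_AB_tilde: float
    phi_AB: float
    phi_M1: float
    phi_M1_tilde: float
    phi_M4: float
    phi_M4_tilde: float
    phi_AF0: float
    phi_BF0: float


def phi_thresholds(selection: SelectionRegime, rho: float = 0.0) -> PhiThresholds:
    a1, a2, b1, b2 = (
        selection.alpha1,
        selection.alpha2,
        selection.beta1,
        selection.beta2,
    )
    return PhiThresholds(
        phi_A=_ratio(a1, a2),
        phi_B=_ratio(b1, b2),
        phi_F0=_ratio(a1 + b1, a2 + b2),
        phi_AB_tilde=_ratio(a1 * b1 * (a2 - b2), a2 * b2 * (a1 - b1)),
        phi_AB=_ratio(a1 * b1 * (a2 + b2), a2 * b2 * (a1 + b1)),
        phi_M1=_ratio(
            a1 * (b2 + rho) * (a1 + b1 + rho), a2 * (b1 + rho) * (a2 + b2 + rho)
        ),
        phi_M1_tilde=_ratio(
            b1 * (a2 + rho) * (a1 + b1 + rho), b2 * (a1 + rho) * (a2 + b2 + rho)
        ),
        phi_M4=_ratio(
            b1 * (a2 - rho) * (a1 + b1 - rho), b2 * (a1 - rho) * (a2 + b2 - rho)
        ),
        phi_M4_tilde=_ratio(
            a1 * (b2 - rho) * (a1 + b1 - rho), a2 * (b1 - rho) * (a2 + b2 - rho)
        ),
        phi_AF0=_ratio(
            a1 * (a1 + b1) * (2 * a2 + b2), a2 * (a2 + b2) * (2 * a1 + b1)
        ),
        phi_BF0=_ratio(
            b1 * (a1 + b1) * (a2 + 2 * b2), b2 * (a2 + b2) * (a1 + 2 * b1)
        ),
    )


def m_tilde(selection: SelectionRegime) -> float:
    """Threshold on the product ``m1*m2`` below which the complete-linkage
    polymorphism is stable; diverges as theta -> 0."""
    a1, a2, b1, b2 = (
        selection.alpha1,
        selection.alpha2,
        selection.beta1,
        selection.beta2,
    )
    theta = selection.theta
    if theta == 0:
        return math.inf
    return -a1 * a2 * b1 * b2 * (a1 + b1) * (a2 + b2) / theta**2


@dataclass(frozen=True)
class MThresholds:
    """Signed critical total migration rates at a fixed ratio ``phi``.

    ``m_A``/``m_B``/``m_F0`` bound the admissibility intervals of the
    single-locus polymorphisms and the complete-linkage polymorphism
    (positive: loss through the high-migration monomorphism; negative:
    loss at ``m = |.|`` through the locally-adapted monomorphism).
    ``m_M1``/``m_M4`` enter the monomorphism stability conditions at
    recombination rate ``rho``; ``m_star`` is the rate at which the
    complete-linkage polymorphism changes stability.
    """

    m_A: float
    m_B: float
    m_F0: float
    m_M1: float
    m_M4: float
    m_star: float


def _signed_threshold(num: float, den: float) -> float:
    if den == 0.0:
        return math.inf
    return num / den


def m_thresholds(
    selection: SelectionRegime, phi: float, rho: float = 0.0
) -> MThresholds:
    a1, a2, b1, b2 = (
        selection.alpha1,
        selection.alpha2,
        selection.beta1,
        selection.beta2,
    )
    theta = selection.theta
    m_A = _signed_threshold(a1 * a2, a1 - phi * (a1 - a2))
    m_B = _signed_threshold(b1 * b2, b1 - phi * (b1 - b2))
    s1, s2 = a1 + b1, a2 + b2
    m_F0 = _signed_threshold(s1 * s2, s1 - phi * (s1 - s2))
    m_M1 = _signed_threshold(
        -(s1 + rho) * (s2 + rho), s1 + rho - phi * (s1 - s2)
    )
    m_M4 = _signed_threshold((s1 - rho) * (s2 - rho), s1 - rho - phi * (s1 - s2))
    if theta == 0.0 or phi in (0.0, 1.0):
        m_star = math.inf
    else:
        m_star = math.sqrt(-a1 * a2 * b1 * b2 * s1 * s2 / (phi * (1.0 - phi))) / theta
    return MThresholds(m_A, m_B, m_F0, m_M1, m_M4, m_star)


@dataclass(frozen=True)
class CriticalRates:
    """Bundle of every analytic threshold quantity at one parameter point."""

    ratios: MigrationSelectionRatios
    phi: PhiThresholds
    m: MThresholds
    m_tilde: float

    def as_dict(self) -> dict:
        d = {
            "sigma1": self.ratios.sigma1,
            "sigma2": self.ratios.sigma2,
            "tau1": self.ratios.tau1,
            "tau2": self.ratios.tau2,
            "kappa1": self.ratios.kappa1,
            "kappa2": self.ratios.kappa2,
            "m_tilde": self.m_tilde,
        }
        d.update({k: getattr(self.phi, k) for k in self.phi.__dataclass_fields__})
        d.update({k: getattr(self.m, k) for k in self.m.__dataclass_fields__})
        return d


def critical_rates(params: ModelParameters) -> CriticalRates:
    """All critical quantities for a canonical parameter set."""
    rho = 0.0 if params.is_le else params.rho_value
    phi = params.migration.phi
    if math.isnan(phi):
        phi = 0.5  # m = 0: thresholds are phi-independent where they matter
    return CriticalRates(
        ratios=compute_ratios(params),
        phi=phi_thresholds(params.selection, rho),
        m=m_thresholds(params.selection, phi, rho),
        m_tilde=m_tilde(params.selection),
    )


def m_max_LE(selection: SelectionRegime, phi: float) -> float:
    """Maximum total migration rate admitting a stable two-locus
    polymorphism under linkage equilibrium: ``min{|m^A|, |m^B|}``."""
    th = m_thresholds(selection, phi)
    return min(abs(th.m_A), abs(th.m_B))


def m_max_rho0(selection: SelectionRegime, phi: float) -> float:
    """Maximum total migration rate admitting a stable two-locus
    polymorphism under complete linkage: ``min{|m^F0|, m*}``."""
    th = m_thresholds(selection, phi)
    return min(abs(th.m_F0), th.m_star)


def m_max_qle(selection: SelectionRegime, rho: float, phi: float) -> float:
    """Strong-recombination (quasi-linkage-equilibrium) approximation of
    the migration rate at which the full polymorphism collides with the
    boundary equilibrium where A2 is fixed and locus B stays polymorphic.

    Valid to O(rho^-2) for ``phi > phi^AB``; the returned value is
    non-positive below that threshold (no such collision).
    """
    a1, a2, b1, b2 = (
        selection.alpha1,
        selection.alpha2,
        selection.beta1,
        selection.beta2,
    )
    mA = m_thresholds(selection, phi).m_A
    if not math.isfinite(mA):
        return math.inf
    bracket1 = (b1 / a1) * phi - (b2 / a2) * (1.0 - phi)
    inner = mA**-2 - 4.0 * phi * (1.0 - phi) / (b1 * b2)
    bracket2 = phi / b1 - (1.0 - phi) / b2 - math.sqrt(inner)
    return mA - (mA**3 / rho) * bracket1 * bracket2


@dataclass
class MMaxNumericResult:
    m_max: float
    mechanism: str  # "boundary_exchange" | "fold" | "closed_form"
    phi: float
    rho: float | str


def m_max_numeric(
    params: ModelParameters,
    *,
    rel_tol: float = 1e-6,
    n_scan: int = 24,
) -> MMaxNumericResult:
    """Maximum migration rate for a stable full polymorphism at general rho.

    Tracks the stable internal equilibrium by parameter continuation in the
    total rate ``m`` and brackets, by bisection, the smallest ``m`` at which
    it disappears -- either by colliding with a boundary equilibrium
    (exchange of stability) or in a saddle-node fold.  For the LE sentinel
    and for ``rho = 0`` the closed forms are returned directly.
    """
    from .equilibria import find_internal  # deferred: avoids import cycle
    from .stability import classify

    sel = params.selection
    phi = params.migration.phi
    if math.isnan(phi):
        raise ValueError("m_max needs a defined migration ratio (m > 0)")
    if params.is_le:
        return MMaxNumericResult(m_max_LE(sel, phi), "closed_form", phi, LE)
    rho = params.rho_value
    if rho == 0.0:
        return MMaxNumericResult(m_max_rho0(sel, phi), "closed_form", phi, 0.0)

    th = m_thresholds(sel, phi, rho)
    finite = [abs(v) for v in (th.m_A, th.m_B) if math.isfinite(v)]
    hi = max(finite + [m_max_rho0(sel, phi)] + [abs(sel.alpha1) + abs(sel.beta1)])
    if not math.isfinite(hi):
        return MMaxNumericResult(math.inf, "closed_form", phi, rho)
    hi *= 1.05

    def stable_internal(m: float, seed: np.ndarray | None):
        p = params.with_migration(m, phi)
        roots = find_internal(p, extra_seeds=None if seed is None else [seed])
        best = None
        for rec in roots:
            verdict = classify(rec, p)
            if verdict.classification == "asymptotically_stable":
                if best is None:
                    best = rec
        return best

    # upward scan with continuation seeding
    grid = np.linspace(hi / n_scan, hi, n_scan)
    seed = None
    last_good_m, last_good_state = 0.0, None
    first_bad = None
    for m in grid:
        rec = stable_internal(float(m), seed)
        if rec is None:
            first_bad = float(m)
            break
        seed = rec.y
        last_good_m, last_good_state = float(m), rec.y
    if first_bad is None:
        return MMaxNumericResult(math.inf, "boundary_exchange", phi, rho)

    lo_m, lo_state = last_good_m, last_good_state
    hi_m = first_bad
    while hi_m - lo_m > rel_tol * max(hi_m, 1e-12):
        mid = 0.5 * (lo_m + hi_m)
        rec = stable_internal(mid, lo_state)
        if rec is None:
            hi_m = mid
        else:
            lo_m, lo_state = mid, rec.y
    # mechanism: approach to the boundary marks an exchange of stability,
    # an interior disappearance marks a fold (saddle-node)
    mechanism = "fold"
    if lo_state is not None:
        from .state import pqd_to_gametes

        if pqd_to_gametes(lo_state).min() < 1e-2:
            mechanism = "boundary_exchange"
    return MMaxNumericResult(0.5 * (lo_m + hi_m), mechanism, phi, rho)
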