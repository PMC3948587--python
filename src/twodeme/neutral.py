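"""Effective migration rate at a neutral site between two selected loci.

A neutral diallelic locus N sits between the selected loci A and B, with
recombination rates ``rho_AN`` (A--N) and ``rho_NB`` (N--B), so that
``rho = rho_AN + rho_NB`` (at most one crossover per event; no
interference parameter is defined).  Evolution of the eight three-locus
gametes per deme follows the same selection/recombination/migration
construction as the two-locus system, with no selection at N.  The
selected-locus marginal dynamics is exactly the two-locus system, and the
states with equal neutral frequencies in both demes and no
N-disequilibria form an invariant line of equilibria.

At a stable fully polymorphic selected-locus equilibrium the Jacobian of
the 14-coordinate system (allele frequencies plus all disequilibria)
block-diagonalises into a selected block and a neutral block ``J_N``.
``J_N`` carries one structural zero eigenvalue along the neutral line;
the rate of decay of neutral differentiation is its second-largest
eigenvalue ``lambda_N``, and the effective migration rate is
``m_eff = -lambda_N``.  Linked selection makes ``m_eff < m``: the
selected loci act as a barrier to gene flow, and two flanking selected
loci are a much stronger barrier than either alone.  For weak migration

    m_eff ~ m1 * rho_AN*rho_NB / ((rho_AN + alpha1)(rho_NB + beta1))
          + m2 * rho_AN*rho_NB / ((rho_AN - alpha2)(rho_NB - beta2)),

the sum of the two effective one-way rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .dynamics import allele_ld_rhs
from .parameters import ModelParameters

__all__ = [
    "NeutralGeometry",
    "EffectiveMigrationResult",
    "gametes8_rhs",
    "gametes8_to_moments",
    "moments_to_gametes8",
    "three_locus_rhs",
    "neutral_equilibrium",
    "m_eff_weak",
    "m_eff_numeric",
]

# gamete index: bits (a, n, b), 0 = allele 1; e.g. index 0 is A1 N1 B1
_BITS = np.array(list(product((0, 1), repeat=3)))  # shape (8, 3)
_SA = 1.0 - 2.0 * _BITS[:, 0]  # +1 for A1, -1 for A2
_SN = 1.0 - 2.0 * _BITS[:, 1]
_SB = 1.0 - 2.0 * _BITS[:, 2]


@dataclass(frozen=True)
class NeutralGeometry:
    """Recombination geometry A -- N -- B."""

    rho_AN: float
    rho_NB: float

    def __post_init__(self) -> None:
        if self.rho_AN <= 0 or self.rho_NB <= 0:
            raise ValueError(
                "the neutral site must recombine with both selected loci "
                "(rho_AN > 0 and rho_NB > 0)"
            )

    @property
    def rho(self) -> float:
        return self.rho_AN + self.rho_NB


def gametes8_rhs(
    x: np.ndarray, params: ModelParameters, geometry: NeutralGeometry
) -> np.ndarray:
    """Time derivative of the (2, 8) three-locus gamete array."""
    sel, mig = params.selection, params.migration
    alpha = np.array([sel.alpha1, sel.alpha2])
    beta = np.array([sel.beta1, sel.beta2])
    m = np.array([mig.m1, mig.m2])
    x = np.asarray(x)
    # additive allelic contribution of each gamete (neutral allele: zero)
    c = 0.5 * (alpha[:, None] * _SA[None, :] + beta[:, None] * _SB[None, :])
    cbar = (x * c).sum(axis=1, keepdims=True)
    dx = x * (c - cbar)
    # single-crossover recombination in the two intervals
    a, n, b = _BITS[:, 0], _BITS[:, 1], _BITS[:, 2]
    # marginals: f_A[a], f_NB[n,b], f_AN[a,n], f_B[b] per deme
    for k in (0, 1):
        xk = x[k]
        f_A = np.array([xk[_BITS[:, 0] == i].sum() for i in (0, 1)])
        f_B = np.array([xk[_BITS[:, 2] == i].sum() for i in (0, 1)])
        f_NB = np.zeros((2, 2), dtype=xk.dtype)
        f_AN = np.zeros((2, 2), dtype=xk.dtype)
        for g in range(8):
            f_NB[n[g], b[g]] += xk[g]
            f_AN[a[g], n[g]] += xk[g]
        rec = geometry.rho_AN * (f_A[a] * f_NB[n, b] - xk) + geometry.rho_NB * (
            f_AN[a, n] * f_B[b] - xk
        )
        dx[k] = dx[k] + rec
    dx += m[:, None] * (x[::-1] - x)
    return dx


def gametes8_to_moments(x: np.ndarray) -> np.ndarray:
    """Convert (2, 8) gametes to the 14 moment coordinates
    ``(p1,p2,q1,q2,DAB1,DAB2, n1,n2, DAN1,DAN2, DNB1,DNB2, DANB1,DANB2)``."""
    x = np.asarray(x)
    a, nn, b = _BITS[:, 0], _BITS[:, 1], _BITS[:, 2]
    p = x[:, a == 0].sum(axis=1)
    n = x[:, nn == 0].sum(axis=1)
    q = x[:, b == 0].sum(axis=1)
    f_ab = x[:, (a == 0) & (b == 0)].sum(axis=1)
    f_an = x[:, (a == 0) & (nn == 0)].sum(axis=1)
    f_nb = x[:, (nn == 0) & (b == 0)].sum(axis=1)
    f_anb = x[:, (a == 0) & (nn == 0) & (b == 0)].sum(axis=1)
    D_AB = f_ab - p * q
    D_AN = f_an - p * n
    D_NB = f_nb - n * q
    D_ANB = f_anb - q * D_AN - n * D_AB - p * D_NB - p * n * q
    return np.concatenate([p, q, D_AB, n, D_AN, D_NB, D_ANB])


def moments_to_gametes8(mom: np.ndarray) -> np.ndarray:
    """Inverse of :func:`gametes8_to_moments`."""
    mom = np.asarray(mom)
    p, q = mom[0:2], mom[2:4]
    D_AB = mom[4:6]
    n = mom[6:8]
    D_AN, D_NB, D_ANB = mom[8:10], mom[10:12], mom[12:14]
    x = np.empty((2, 8), dtype=mom.dtype)
    for g in range(8):
        sa, sn, sb = _SA[g], _SN[g], _SB[g]
        pa = p if _BITS[g, 0] == 0 else 1.0 - p
        nn_ = n if _BITS[g, 1] == 0 else 1.0 - n
        qb = q if _BITS[g, 2] == 0 else 1.0 - q
        x[:, g] = (
            pa * nn_ * qb
            + pa * sn * sb * D_NB
            + nn_ * sa * sb * D_AB
            + qb * sa * sn * D_AN
            + sa * sn * sb * D_ANB
        )
    return x


def three_locus_rhs(
    mom: np.ndarray, params: ModelParameters, geometry: NeutralGeometry
) -> np.ndarray:
    """Time derivative of the 14 moment coordinates.

    Computed by mapping to gametes, evaluating the gamete flow and pushing
    forward through the differential of the moment map; the selected-locus
    components coincide exactly with the two-locus dynamics.
    """
    mom = np.asarray(mom)
    x = moments_to_gametes8(mom)
    dx = gametes8_rhs(x, params, geometry)
    a, nn, b = _BITS[:, 0], _BITS[:, 1], _BITS[:, 2]
    p, q = mom[0:2], mom[2:4]
    n = mom[6:8]
    D_AB, D_AN, D_NB = mom[4:6], mom[8:10], mom[10:12]
    dp = dx[:, a == 0].sum(axis=1)
    dn = dx[:, nn == 0].sum(axis=1)
    dq = dx[:, b == 0].sum(axis=1)
    df_ab = dx[:, (a == 0) & (b == 0)].sum(axis=1)
    df_an = dx[:, (a == 0) & (nn == 0)].sum(axis=1)
    df_nb = dx[:, (nn == 0) & (b == 0)].sum(axis=1)
    df_anb = dx[:, (a == 0) & (nn == 0) & (b == 0)].sum(axis=1)
    dD_AB = df_ab - dp * q - p * dq
    dD_AN = df_an - dp * n - p * dn
    dD_NB = df_nb - dn * q - n * dq
    dD_ANB = (
        df_anb
        - dq * D_AN
        - q * dD_AN
        - dn * D_AB
        - n * dD_AB
        - dp * D_NB
        - p * dD_NB
        - dp * n * q
        - p * dn * q
        - p * n * dq
    )
    return np.concatenate([dp, dq, dD_AB, dn, dD_AN, dD_NB, dD_ANB])


def neutral_equilibrium(n1_0: float, n2_0: float, migration) -> float:
    """Equilibrium neutral allele frequency (equal in both demes): the
    initial frequencies averaged with weights set by the opposite deme's
    immigration rate."""
    m = migration.m
    if m == 0:
        raise ValueError("no mixing at m = 0: per-deme frequencies persist")
    return (migration.m2 * n1_0 + migration.m1 * n2_0) / m


def m_eff_weak(params: ModelParameters, geometry: NeutralGeometry) -> float:
    """Weak-migration approximation of the effective migration rate: the
    sum of the two effective one-way rates, each discounted by the linked
    barrier loci."""
    sel, mig = params.selection, params.migration
    rAN, rNB = geometry.rho_AN, geometry.rho_NB
    t1 = mig.m1 * rAN * rNB / ((rAN + sel.alpha1) * (rNB + sel.beta1))
    t2 = mig.m2 * rAN * rNB / ((rAN - sel.alpha2) * (rNB - sel.beta2))
    return t1 + t2


@dataclass
class EffectiveMigrationResult:
    lambda_N: float
    m_eff: float
    m_eff_weak: float
    n_hat: float
    selected_state: np.ndarray
    block_coupling_norm: float


def m_eff_numeric(
    params: ModelParameters,
    geometry: NeutralGeometry,
    *,
    n_hat: float = 0.5,
    selected_equilibrium: np.ndarray | None = None,
) -> EffectiveMigrationResult:
    """Effective migration rate from the neutral block of the Jacobian.

    Requires an admissible, stable fully polymorphic selected-locus
    equilibrium (located numerically unless supplied).  The structural
    zero of the neutral block is identified by eigenvector alignment with
    the tangent of the neutral line of equilibria, not by magnitude, so a
    tiny ``lambda_N`` is never misclassified.
    """
    if not math.isclose(
        geometry.rho, params.rho_value, rel_tol=1e-9, abs_tol=1e-12
    ):
        raise ValueError("geometry.rho_AN + geometry.rho_NB must equal params.rho")
    if selected_equilibrium is None:
        from .equilibria import find_internal
        from .stability import classify

        stable = None
        for rec in find_internal(params):
            if classify(rec, params).stable:
                stable = rec.y
                break
        if stable is None:
            raise ValueError(
                "no stable fully polymorphic selected-locus equilibrium found"
            )
        selected_equilibrium = stable
    y = np.asarray(selected_equilibrium, dtype=float)
    res = np.abs(allele_ld_rhs(y, params)).max()
    if res > 1e-8:
        raise ValueError(f"selected state is not an equilibrium (residual {res:.1e})")
    mom = np.concatenate([y, [n_hat, n_hat], np.zeros(6)])
    # complex-step Jacobian of the polynomial 14-dim flow
    dim = 14
    J = np.empty((dim, dim))
    h = 1e-200
    for j in range(dim):
        mc = mom.astype(complex)
        mc[j] += 1j * h
        J[:, j] = three_locus_rhs(mc, params, geometry).imag / h
    sel_idx = np.arange(6)
    neu_idx = np.arange(6, 14)
    coupling = max(
        np.abs(J[np.ix_(sel_idx, neu_idx)]).max(),
        np.abs(J[np.ix_(neu_idx, sel_idx)]).max(),
    )
    JN = J[np.ix_(neu_idx, neu_idx)]
    w, v = np.linalg.eig(JN)
    tangent = np.zeros(8)
    tangent[0:2] = 1.0 / math.sqrt(2.0)
    align = np.abs(v.conj().T @ tangent)
    structural = int(np.argmax(align))
    rest = [i for i in range(8) if i != structural]
    lam = float(max(w[i].real for i in rest))
    return EffectiveMigrationResult(
        lambda_N=lam,
        m_eff=-lam,
        m_eff_weak=m_eff_weak(params, geometry),
        n_hat=n_hat,
        selected_state=y,
        block_coupling_norm=float(coupling),
    )
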