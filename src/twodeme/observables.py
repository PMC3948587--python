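"""Migration load and multilocus F_ST.

The migration load of a deme is the deviation of its mean fitness from
the local optimum (attained when the locally adapted haplotype is fixed):

    L1 = 2 (alpha1 (1 - p1) + beta1 (1 - q1)),
    L2 = 2 (-alpha2 p2 - beta2 q2),

and the total load is ``L = (L1 + L2) / 2`` for demes of equal size.

Differentiation is measured by a genuinely multilocus (haplotype-based)
fixation index.  With deme weights ``c_k`` and mean haplotype frequencies
``xbar_i = sum_k c_k x_{i,k}``, the within-subdivision haplotype
heterozygosity is ``hbar_S = sum_i (xbar_i - mean(x_i^2))`` and the
panmictic heterozygosity is ``h_T = sum_i xbar_i (1 - xbar_i)``; then

    F_ST = 1 - hbar_S / h_T = sum_i Var(x_i) / sum_i xbar_i (1 - xbar_i),

with the variance taken over demes with weights ``c_k`` (a population,
not sample, variance, in the tradition of fixation indices defined from
subpopulation moments).  The pairwise matrix ``F_ST,ij`` standardises the
haplotype-frequency covariances the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, SelectionRegime
from .state import pqd_to_gametes

__all__ = [
    "LoadReport",
    "FstReport",
    "migration_load",
    "load_weak_approx",
    "fst",
    "fst_weak_approx",
]


@dataclass
class LoadReport:
    L1: float
    L2: float

    @property
    def L(self) -> float:
        return 0.5 * (self.L1 + self.L2)


def migration_load(y: np.ndarray, selection: SelectionRegime) -> LoadReport:
    """Per-deme and total migration load at a state ``(p1,p2,q1,q2,D1,D2)``."""
    p1, p2, q1, q2 = np.asarray(y, dtype=float)[:4]
    L1 = 2.0 * (selection.alpha1 * (1.0 - p1) + selection.beta1 * (1.0 - q1))
    L2 = 2.0 * (-selection.alpha2 * p2 - selection.beta2 * q2)
    return LoadReport(L1, L2)


def load_weak_approx(params: ModelParameters) -> LoadReport:
    """Leading-order load at the weak-migration polymorphism.

    ``L1 ~ 2 m1 (alpha1 + beta1 + 2 rho)/(alpha1 + beta1 + rho)`` and the
    deme-2 analogue; exact at m = 0, O(m^2) error, increasing in each
    migration rate and in rho (between 2 m_k at complete linkage and
    4 m_k under free recombination).
    """
    sel, mig = params.selection, params.migration
    rho = params.rho_value
    s1 = sel.alpha1 + sel.beta1
    s2 = -(sel.alpha2 + sel.beta2)
    L1 = 2.0 * mig.m1 * (s1 + 2.0 * rho) / (s1 + rho)
    L2 = 2.0 * mig.m2 * (s2 + 2.0 * rho) / (s2 + rho)
    return LoadReport(L1, L2)


@dataclass
class FstReport:
    c1: float
    c2: float
    xbar: np.ndarray
    fst: float | None  # None when the total population is monomorphic
    fst_matrix: np.ndarray
    h_S_bar: float
    h_T: float
    fst_locus_A: float | None
    fst_locus_B: float | None

    @property
    def defined(self) -> bool:
        return self.fst is not None

    @property
    def fst_single_locus_average(self) -> float | None:
        """Heterozygosity-weighted average of the one-locus indices (the
        conventional multilocus estimator, for comparison)."""
        vals, weights = [], []
        for f, h in ((self.fst_locus_A, self._hA), (self.fst_locus_B, self._hB)):
            if f is not None:
                vals.append(f * h)
                weights.append(h)
        if not weights or sum(weights) == 0:
            return None
        return sum(vals) / sum(weights)

    _hA: float = 0.0
    _hB: float = 0.0


def _single_locus_fst(freqs: np.ndarray, c: np.ndarray) -> tuple[float | None, float]:
    pbar = float(c @ freqs)
    h = pbar * (1.0 - pbar)
    if h == 0:
        return None, 0.0
    var = float(c @ (freqs - pbar) ** 2)
    return var / h, h


def fst(
    state: np.ndarray, c1: float = 0.5, c2: float | None = None
) -> FstReport:
    """Multilocus F_ST of a two-deme state.

    ``state`` is either the 6-vector ``(p1,p2,q1,q2,D1,D2)`` or a (2, 4)
    gamete array.  ``c1``/``c2`` are the deme weights (proportions of the
    total population; default equal demes).  When the total population is
    monomorphic (``h_T = 0``) the index is undefined and reported as None.
    """
    if c2 is None:
        c2 = 1.0 - c1
    if c1 < 0 or c2 < 0 or abs(c1 + c2 - 1.0) > 1e-12:
        raise ValueError("deme weights must be nonnegative and sum to 1")
    state = np.asarray(state, dtype=float)
    x = state if state.shape == (2, 4) else pqd_to_gametes(state)
    c = np.array([c1, c2])
    xbar = c @ x  # mean haplotype frequencies
    second = np.einsum("k,ki,kj->ij", c, x, x)  # E[x_i x_j] over demes
    h_T = float(np.sum(xbar * (1.0 - xbar)))
    h_S_bar = float(np.sum(xbar - np.diag(second)))
    n = 4
    F = np.full((n, n), np.nan)
    for i in range(n):
        den = xbar[i] * (1.0 - xbar[i])
        if den > 0:
            F[i, i] = (second[i, i] - xbar[i] ** 2) / den
        for j in range(n):
            if i != j and xbar[i] * xbar[j] > 0:
                F[i, j] = 1.0 - second[i, j] / (xbar[i] * xbar[j])
    fst_val = None if h_T == 0 else 1.0 - h_S_bar / h_T
    p = x[:, 0] + x[:, 1]
    q = x[:, 0] + x[:, 2]
    fA, hA = _single_locus_fst(p, c)
    fB, hB = _single_locus_fst(q, c)
    rep = FstReport(
        c1=c1, c2=c2, xbar=xbar, fst=fst_val, fst_matrix=F,
        h_S_bar=h_S_bar, h_T=h_T, fst_locus_A=fA, fst_locus_B=fB,
    )
    rep._hA, rep._hB = hA, hB
    return rep


def fst_weak_approx(
    params: ModelParameters, c1: float = 0.5, c2: float | None = None
) -> float:
    """Leading-order multilocus F_ST at the weak-migration polymorphism:
    1 minus a term linear in ``m``, decreasing in ``m`` and increasing as
    linkage tightens."""
    if c2 is None:
        c2 = 1.0 - c1
    sel, mig = params.selection, params.migration
    a1, a2, b1, b2 = sel.alpha1, sel.alpha2, sel.beta1, sel.beta2
    rho = params.rho_value
    m, phi = mig.m, mig.phi
    if m == 0:
        return 1.0
    term1 = (phi / c2) * (a1 * b1 + (a1 + b1) * rho) / (a1 * b1 * (a1 + b1 + rho))
    term2 = ((1.0 - phi) / c1) * (a2 * b2 - (a2 + b2) * rho) / (
        a2 * b2 * (a2 + b2 - rho)
    )
    return 1.0 - m * (term1 - term2)
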