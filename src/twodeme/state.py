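"""Population states for the two-locus, two-deme system.

A state is described per deme either by the four gamete (haplotype)
frequencies ``x1..x4`` of ``A1B1, A1B2, A2B1, A2B2`` on the simplex, or by
the allele frequencies ``p`` (of ``A1``), ``q`` (of ``B1``) and the linkage
disequilibrium ``D = x1*x4 - x2*x3``.  The two coordinate systems are
related by the bijection

    x1 = p*q + D        x2 = p*(1-q) - D
    x3 = (1-p)*q - D    x4 = (1-p)*(1-q) + D

with the box constraint
``-min(pq, (1-p)(1-q)) <= D <= min(p(1-q), (1-p)q)``.

Throughout the package the combined state of both demes is the 6-vector
``y = (p1, p2, q1, q2, D1, D2)`` or the (2, 4) array of gamete frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DemeState",
    "PopulationState",
    "pqd_to_gametes",
    "gametes_to_pqd",
    "d_bounds",
    "validate_gametes",
    "validate_pqd",
]


def d_bounds(p: float, q: float) -> tuple[float, float]:
    """Admissible range of the LD measure at allele frequencies (p, q)."""
    lo = -min(p * q, (1.0 - p) * (1.0 - q))
    hi = min(p * (1.0 - q), (1.0 - p) * q)
    return lo, hi


def pqd_to_gametes(y: np.ndarray) -> np.ndarray:
    """Convert ``(p1, p2, q1, q2, D1, D2)`` to a (2, 4) gamete array."""
    y = np.asarray(y)
    p = y[0:2]
    q = y[2:4]
    D = y[4:6]
    x = np.empty((2, 4), dtype=y.dtype)
    x[:, 0] = p * q + D
    x[:, 1] = p * (1.0 - q) - D
    x[:, 2] = (1.0 - p) * q - D
    x[:, 3] = (1.0 - p) * (1.0 - q) + D
    return x


def gametes_to_pqd(x: np.ndarray) -> np.ndarray:
    """Convert a (2, 4) gamete array to ``(p1, p2, q1, q2, D1, D2)``."""
    x = np.asarray(x)
    p = x[:, 0] + x[:, 1]
    q = x[:, 0] + x[:, 2]
    D = x[:, 0] * x[:, 3] - x[:, 1] * x[:, 2]
    return np.concatenate([p, q, D])


def validate_gametes(x: np.ndarray, tol: float = 1e-9) -> None:
    x = np.asarray(x, dtype=float)
    if x.shape != (2, 4):
        raise ValueError("gamete state must have shape (2, 4)")
    if np.any(x < -tol) or np.any(np.abs(x.sum(axis=1) - 1.0) > tol):
        raise ValueError("gamete frequencies must be nonnegative and sum to 1 per deme")


def validate_pqd(y: np.ndarray, tol: float = 1e-9) -> None:
    y = np.asarray(y, dtype=float)
    if y.shape != (6,):
        raise ValueError("allele/LD state must be a 6-vector (p1,p2,q1,q2,D1,D2)")
    p1, p2, q1, q2, D1, D2 = y
    for p, q, D in ((p1, q1, D1), (p2, q2, D2)):
        if not (-tol <= p <= 1 + tol and -tol <= q <= 1 + tol):
            raise ValueError("allele frequencies must lie in [0, 1]")
        lo, hi = d_bounds(min(max(p, 0.0), 1.0), min(max(q, 0.0), 1.0))
        if not (lo - tol <= D <= hi + tol):
            raise ValueError("LD outside its admissible box")


@dataclass(frozen=True)
class DemeState:
    """Allele frequencies and LD within a single deme."""

    p: float
    q: float
    D: float

    def __post_init__(self) -> None:
        validate_pqd(np.array([self.p, self.p, self.q, self.q, self.D, self.D]))

    @property
    def gametes(self) -> np.ndarray:
        return pqd_to_gametes(
            np.array([self.p, self.p, self.q, self.q, self.D, self.D])
        )[0]


@dataclass(frozen=True)
class PopulationState:
    """Joint state of both demes, stored as ``(p1, p2, q1, q2, D1, D2)``."""

    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float).copy())
        validate_pqd(self.y)

    @classmethod
    def from_demes(cls, deme1: DemeState, deme2: DemeState) -> "PopulationState":
        return cls(np.array([deme1.p, deme2.p, deme1.q, deme2.q, deme1.D, deme2.D]))

    @classmethod
    def from_gametes(cls, x: np.ndarray) -> "PopulationState":
        validate_gametes(np.asarray(x, dtype=float))
        return cls(gametes_to_pqd(np.asarray(x, dtype=float)))

    @property
    def deme1(self) -> DemeState:
        return DemeState(self.y[0], self.y[2], self.y[4])

    @property
    def deme2(self) -> DemeState:
        return DemeState(self.y[1], self.y[3], self.y[5])

    @property
    def gametes(self) -> np.ndarray:
        return pqd_to_gametes(self.y)
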