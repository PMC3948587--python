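"""Model parameters for the two-locus, two-deme migration-selection model.

Two diallelic loci A and B are under genic (additive, non-epistatic)
selection in two demes coupled by migration.  Allele ``A1`` (``B1``) is
favoured in deme 1 and disfavoured in deme 2; the Malthusian selection
coefficients are ``alpha_k`` for locus A and ``beta_k`` for locus B in deme
k.  Individuals in deme k are replaced by immigrants at rate ``m_k``, and
the two loci recombine at rate ``rho``.  All parameters are rates per unit
time (the continuous-time model arises as a weak-force limit, so they can
be arbitrarily large; only ratios matter for equilibrium structure).

Canonical form
--------------
By relabelling alleles, loci and demes every non-degenerate parameter set
can be brought to a normal form with

    alpha1 > 0 > alpha2,   beta1 > 0 > beta2,   beta1 >= alpha1,
    theta = alpha1*beta2 - alpha2*beta1 >= 0.

:func:`canonicalize` applies the required relabelings and returns the
transform record so that results can be mapped back to the caller's
labelling.  The degenerate ``theta = 0`` regime (including the
super-symmetric case) is allowed behind an explicit flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "LE",
    "SelectionRegime",
    "MigrationRegime",
    "CanonicalTransform",
    "ModelParameters",
    "canonicalize",
    "load_config",
]

#: Sentinel for the linkage-equilibrium (rho -> infinity) dynamics.  Kept as
#: a distinct dynamical mode rather than a huge finite rate so that the
#: exactly decoupled one-locus equations can be used without stiffness.
LE = "LE"

Rho = Union[float, str]


@dataclass(frozen=True)
class SelectionRegime:
    """Malthusian selection coefficients of the two loci in the two demes."""

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    @property
    def theta(self) -> float:
        """Selection asymmetry ``alpha1*beta2 - alpha2*beta1``."""
        return self.alpha1 * self.beta2 - self.alpha2 * self.beta1

    @property
    def theta_tilde(self) -> float:
        """Secondary asymmetry ``alpha1*alpha2 - beta1*beta2`` (orders the
        complete-linkage bifurcation sequences)."""
        return self.alpha1 * self.alpha2 - self.beta1 * self.beta2

    @property
    def alphas(self) -> tuple[float, float]:
        return (self.alpha1, self.alpha2)

    @property
    def betas(self) -> tuple[float, float]:
        return (self.beta1, self.beta2)

    def is_canonical(self, *, allow_theta_zero: bool = False) -> bool:
        ok = (
            self.alpha1 > 0 > self.alpha2
            and self.beta1 > 0 > self.beta2
            and self.beta1 >= self.alpha1
        )
        if allow_theta_zero:
            return ok and self.theta >= 0
        return ok and self.theta > 0


@dataclass(frozen=True)
class MigrationRegime:
    """Immigration replacement rates into the two demes."""

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if self.m1 < 0 or self.m2 < 0:
            raise ValueError("migration rates must be nonnegative")

    @property
    def m(self) -> float:
        """Total migration rate ``m1 + m2``."""
        return self.m1 + self.m2

    @property
    def phi(self) -> float:
        """Migration ratio ``m1/m`` in [0, 1]; NaN when ``m = 0``."""
        return self.m1 / self.m if self.m > 0 else math.nan

    @classmethod
    def from_total(cls, m: float, phi: float) -> "MigrationRegime":
        if not 0.0 <= phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        return cls(m1=m * phi, m2=m * (1.0 - phi))


@dataclass(frozen=True)
class CanonicalTransform:
    """Record of the relabelings applied by :func:`canonicalize`.

    The four involutions commute at the level of what they do to states, so
    the record composes to a normal form without ordering ambiguity:
    ``flip_a``/``flip_b`` exchange the alleles at locus A/B, ``swap_loci``
    exchanges the roles of the two loci, ``swap_demes`` exchanges demes
    (which also swaps the migration rates).
    """

    flip_a: bool = False
    flip_b: bool = False
    swap_loci: bool = False
    swap_demes: bool = False

    @property
    def is_identity(self) -> bool:
        return not (self.flip_a or self.flip_b or self.swap_loci or self.swap_demes)

    def apply_state(self, y: np.ndarray) -> np.ndarray:
        """Map a state ``(p1, p2, q1, q2, D1, D2)`` from the user's labels
        to canonical labels."""
        p1, p2, q1, q2, D1, D2 = np.asarray(y, dtype=float)
        if self.flip_a:
            p1, p2, D1, D2 = 1.0 - p1, 1.0 - p2, -D1, -D2
        if self.flip_b:
            q1, q2, D1, D2 = 1.0 - q1, 1.0 - q2, -D1, -D2
        if self.swap_loci:
            p1, q1 = q1, p1
            p2, q2 = q2, p2
        if self.swap_demes:
            # deme exchange also relabels alleles so that A1/B1 stay the
            # deme-1-favoured alleles of the transformed system
            p1, p2 = 1.0 - p2, 1.0 - p1
            q1, q2 = 1.0 - q2, 1.0 - q1
            D1, D2 = D2, D1
        return np.array([p1, p2, q1, q2, D1, D2])

    def invert_state(self, y: np.ndarray) -> np.ndarray:
        """Map a canonical-label state back to the user's original labels."""
        p1, p2, q1, q2, D1, D2 = np.asarray(y, dtype=float)
        if self.swap_demes:
            p1, p2 = 1.0 - p2, 1.0 - p1
            q1, q2 = 1.0 - q2, 1.0 - q1
            D1, D2 = D2, D1
        if self.swap_loci:
            p1, q1 = q1, p1
            p2, q2 = q2, p2
        if self.flip_b:
            q1, q2, D1, D2 = 1.0 - q1, 1.0 - q2, -D1, -D2
        if self.flip_a:
            p1, p2, D1, D2 = 1.0 - p1, 1.0 - p2, -D1, -D2
        return np.array([p1, p2, q1, q2, D1, D2])


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set: selection, migration and recombination.

    ``rho`` is either a nonnegative rate or the :data:`LE` sentinel selecting
    the linkage-equilibrium dynamics.
    """

    selection: SelectionRegime
    migration: MigrationRegime
    rho: Rho = 0.0
    canonical_transform: CanonicalTransform = field(default_factory=CanonicalTransform)

    def __post_init__(self) -> None:
        if not self.is_le and float(self.rho) < 0:
            raise ValueError("recombination rate must be nonnegative (or LE)")

    @property
    def is_le(self) -> bool:
        return isinstance(self.rho, str) and self.rho == LE

    @property
    def rho_value(self) -> float:
        if self.is_le:
            raise ValueError("rho is the LE sentinel; no finite value available")
        return float(self.rho)

    def with_migration(self, m: float, phi: float | None = None) -> "ModelParameters":
        """Return a copy with total migration rate ``m`` (keeping ``phi``
        unless a new ratio is given)."""
        if phi is None:
            phi = self.migration.phi
            if math.isnan(phi):
                raise ValueError("phi undefined at m=0; pass phi explicitly")
        return replace(self, migration=MigrationRegime.from_total(m, phi))

    def with_rho(self, rho: Rho) -> "ModelParameters":
        return replace(self, rho=rho)

    @classmethod
    def create(
        cls,
        alpha1: float,
        alpha2: float,
        beta1: float,
        beta2: float,
        *,
        m1: float | None = None,
        m2: float | None = None,
        m: float | None = None,
        phi: float | None = None,
        rho: Rho = 0.0,
        canonicalize_params: bool = True,
        allow_theta_zero: bool = False,
    ) -> "ModelParameters":
        """Convenience constructor accepting either (m1, m2) or (m, phi)."""
        if m1 is not None and m2 is not None:
            mig = MigrationRegime(m1, m2)
        elif m is not None and phi is not None:
            mig = MigrationRegime.from_total(m, phi)
        elif m is not None and m == 0:
            mig = MigrationRegime(0.0, 0.0)
        else:
            raise ValueError("supply migration as (m1, m2) or (m, phi)")
        params = cls(SelectionRegime(alpha1, alpha2, beta1, beta2), mig, rho)
        if canonicalize_params:
            return canonicalize(params, allow_theta_zero=allow_theta_zero)
        return params


def _transformed(sel: SelectionRegime, mig: MigrationRegime, t: CanonicalTransform):
    a1, a2, b1, b2 = sel.alpha1, sel.alpha2, sel.beta1, sel.beta2
    m1, m2 = mig.m1, mig.m2
    if t.flip_a:
        a1, a2 = -a1, -a2
    if t.flip_b:
        b1, b2 = -b1, -b2
    if t.swap_loci:
        a1, b1 = b1, a1
        a2, b2 = b2, a2
    if t.swap_demes:
        a1, a2 = -a2, -a1
        b1, b2 = -b2, -b1
        m1, m2 = m2, m1
    return SelectionRegime(a1, a2, b1, b2), MigrationRegime(m1, m2)


def canonicalize(
    params: ModelParameters, *, allow_theta_zero: bool = False
) -> ModelParameters:
    """Bring a parameter set to the canonical normal form.

    Searches the sixteen relabelings (allele flips at each locus, locus
    exchange, deme exchange) for one that satisfies the canonical sign and
    ordering constraints; the identity is preferred, then transforms with
    fewer component relabelings.

    Raises ``ValueError`` if a selection coefficient vanishes (unless the
    degenerate mode is requested) or if no relabelling yields diversifying
    selection at both loci (i.e. the same allele is favoured in both demes
    at some locus).
    """
    sel = params.selection
    coeffs = (sel.alpha1, sel.alpha2, sel.beta1, sel.beta2)
    if not allow_theta_zero and any(c == 0 for c in coeffs):
        raise ValueError(
            "zero selection coefficient: the model assumes diversifying "
            "selection at both loci; pass allow_theta_zero=True for the "
            "degenerate regime"
        )
    candidates = []
    for swap_demes in (False, True):
        for swap_loci in (False, True):
            for flip_a in (False, True):
                for flip_b in (False, True):
                    t = CanonicalTransform(flip_a, flip_b, swap_loci, swap_demes)
                    s2, m2 = _transformed(sel, params.migration, t)
                    if s2.is_canonical(allow_theta_zero=allow_theta_zero):
                        cost = flip_a + flip_b + swap_loci + swap_demes
                        candidates.append((cost, t, s2, m2))
    if not candidates:
        raise ValueError(
            "parameters admit no canonical relabelling (selection is not "
            "diversifying at both loci)"
        )
    candidates.sort(key=lambda c: c[0])
    _, t, s2, m2 = candidates[0]
    return ModelParameters(s2, m2, params.rho, t)


def load_config(path: str | Path) -> ModelParameters:
    """Read model parameters from a TOML or JSON config file.

    Recognised keys: ``alpha1, alpha2, beta1, beta2``, either ``m1, m2`` or
    ``m, phi``, and ``rho`` (number or the string ``"LE"``).
    """
    path = Path(path)
    if path.suffix in {".toml", ".tml"}:
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    rho = data.get("rho", 0.0)
    if isinstance(rho, str):
        if rho.upper() != "LE":
            raise ValueError(f"unrecognised rho value: {rho!r}")
        rho = LE
    kwargs = dict(rho=rho)
    for key in ("m1", "m2", "m", "phi"):
        if key in data:
            kwargs[key] = float(data[key])
    return ModelParameters.create(
        float(data["alpha1"]),
        float(data["alpha2"]),
        float(data["beta1"]),
        float(data["beta2"]),
        allow_theta_zero=bool(data.get("allow_theta_zero", False)),
        **kwargs,
    )
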