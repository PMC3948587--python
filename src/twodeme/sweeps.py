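"""Reproducible parameter sweeps and random draws.

The sweep generator produces canonical parameter sets for property checks
and grid surveys.  Three constraint modes mirror the model's regimes:

* ``canonical`` -- diversifying selection at both loci with the normal
  form ordering (the generic regime);
* ``theta_zero`` -- the degenerate regime ``theta = 0`` with
  ``|alpha_k| <= |beta_k|`` (no genotype-environment interaction on the
  underlying trait);
* ``super_symmetric`` -- mirrored demes and exchangeable loci
  (``alpha_k = beta_k``, ``alpha_k = -alpha_{k*}``, ``m1 = m2``).

Draws are driven by a seeded generator, so the same seed always yields
the same sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, Rho

__all__ = ["SweepSpec", "generate_sweep", "random_interior_state"]


@dataclass
class SweepSpec:
    """Specification of a random parameter sweep.

    Selection coefficients are drawn log-uniformly in magnitude from
    ``[sel_low, sel_high]``; the migration rate uniformly from
    ``[0, m_high]`` (with ``phi`` uniform on (0, 1)) and ``rho`` is fixed
    per spec unless ``rho_range`` is given.
    """

    n: int = 100
    seed: int = 0
    mode: str = "canonical"  # canonical | theta_zero | super_symmetric
    sel_low: float = 0.05
    sel_high: float = 2.0
    m_high: float = 1.0
    rho: Rho = 1.0
    rho_range: tuple[float, float] | None = None


def _draw_magnitude(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_sweep(spec: SweepSpec) -> list[ModelParameters]:
    """Draw ``spec.n`` canonicalized parameter sets."""
    rng = np.random.default_rng(spec.seed)
    out: list[ModelParameters] = []
    while len(out) < spec.n:
        if spec.mode == "canonical":
            a1 = _draw_magnitude(rng, spec.sel_low, spec.sel_high)
            a2 = -_draw_magnitude(rng, spec.sel_low, spec.sel_high)
            b1 = _draw_magnitude(rng, spec.sel_low, spec.sel_high)
            b2 = -_draw_magnitude(rng, spec.sel_low, spec.sel_high)
            allow0 = False
        elif spec.mode == "theta_zero":
            a1 = _draw_magnitude(rng, spec.sel_low, spec.sel_high)
            a2 = -_draw_magnitude(rng, spec.sel_low, spec.sel_high)
            scale = rng.uniform(1.0, 4.0)
            # beta proportional to alpha makes theta vanish identically
            b1, b2 = scale * a1, scale * a2
            allow0 = True
        elif spec.mode == "super_symmetric":
            a1 = _draw_magnitude(rng, spec.sel_low, spec.sel_high)
            a2, b1, b2 = -a1, a1, -a1
            allow0 = True
        else:
            raise ValueError(f"unknown sweep mode: {spec.mode}")
        m = rng.uniform(0.0, spec.m_high)
        phi = 0.5 if spec.mode == "super_symmetric" else rng.uniform(0.0, 1.0)
        rho = spec.rho
        if spec.rho_range is not None:
            rho = float(rng.uniform(*spec.rho_range))
        try:
            p = ModelParameters.create(
                a1, a2, b1, b2, m=m, phi=phi, rho=rho, allow_theta_zero=allow0
            )
        except ValueError:
            continue
        out.append(p)
    return out


def random_interior_state(rng: np.random.Generator) -> np.ndarray:
    """A uniformly drawn valid interior state ``(p1,p2,q1,q2,D1,D2)``."""
    from .state import d_bounds

    p = rng.uniform(0.02, 0.98, size=2)
    q = rng.uniform(0.02, 0.98, size=2)
    D = np.array(
        [rng.uniform(*d_bounds(p[k], q[k])) for k in range(2)]
    )
    return np.concatenate([p, q, 0.98 * D])
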