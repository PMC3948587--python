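"""Bifurcation diagrams in the total migration rate ``m``.

With the selection coefficients, the recombination rate and the migration
ratio ``phi = m1/m`` held fixed, the equilibrium configuration changes at
a handful of critical values of ``m``.  Two regimes admit a complete
symbolic classification:

* **linkage equilibrium** (``rho -> inf``): three diagram shapes labelled
  ``a``--``c``, with role assignments ``L1``--``L5`` mapping the abstract
  equilibria ``P_X``/``P_Y``/``M_i`` and critical rates ``m^X``/``m^Y``
  onto concrete ones.  Generic shape ``a``: the full polymorphism hands
  stability to a single-locus polymorphism, which hands it to a
  monomorphism.  ``b`` (measure-zero): the polymorphism exits directly
  through the monomorphism.  ``c`` (measure-zero): the terminal stable
  equilibrium is a single-locus polymorphism that never exits.

* **complete linkage** (``rho = 0``): ten diagram shapes ``a``--``j`` with
  role assignments ``R1``--``R4`` and primed variants.  The new actors are
  the two-gamete polymorphism ``F0`` (admissible for ``m < |m^F0|``,
  stable for ``m < m*``) and the marginal line of tri-gametic equilibria
  at ``m = m*``.

For general finite ``rho`` no closed form exists; :func:`scan_numeric`
locates events on a grid by bisection on the stability signature and can
detect the saddle-node (fold) patterns that arise under highly asymmetric
migration at intermediate recombination rates.

Equality of ``phi`` with a threshold is decided exactly when the inputs
are exact (``fractions.Fraction`` or integers survive the threshold
arithmetic unscathed), otherwise within a relative tolerance of 1e-12;
degenerate diagrams live on measure-zero sets of parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from numbers import Rational

import numpy as np

from .critical_rates import m_thresholds, phi_thresholds
from .parameters import ModelParameters, SelectionRegime

__all__ = [
    "BifurcationEvent",
    "MInterval",
    "BifurcationDiagram",
    "classify_LE",
    "classify_rho0",
    "phi_sweep",
    "scan_numeric",
]

_REL_TOL = 1e-12


def _cmp(phi, threshold) -> int:
    """Three-way comparison, exact for rational inputs."""
    if isinstance(phi, Rational) and isinstance(threshold, Rational):
        return (phi > threshold) - (phi < threshold)
    a, b = float(phi), float(threshold)
    if math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=1e-300):
        return 0
    return (a > b) - (a < b)


@dataclass
class BifurcationEvent:
    m: float
    kind: str  # exchange_of_stability | saddle_node | exit | entry | marginal_line
    participants: tuple[str, ...]


@dataclass
class MInterval:
    m_lo: float
    m_hi: float
    stable: tuple[str, ...]
    equilibria: dict[str, dict] = field(default_factory=dict)  # label -> flags


@dataclass
class BifurcationDiagram:
    regime: str  # "LE" | "rho0" | "numeric"
    diagram_label: str
    role_assignment: dict
    events: list[BifurcationEvent]
    intervals: list[MInterval]
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# closed-form admissibility/stability predicates at a given total rate m
# ---------------------------------------------------------------------------


def _le_flags(sel: SelectionRegime, phi: float, m: float) -> dict[str, dict]:
    th = m_thresholds(sel, phi)
    pt = phi_thresholds(sel)
    mA, mB = th.m_A, th.m_B
    absA, absB = abs(mA), abs(mB)
    mmax = min(absA, absB)
    flags: dict[str, dict] = {}
    flags["Finf"] = {"admissible": m < mmax, "stable": m < mmax}
    flags["PA1"] = {
        "admissible": m < absA,
        "stable": (mB < 0) and (-mB < m < absA),
    }
    flags["PA2"] = {"admissible": m < absA, "stable": False}
    flags["PB1"] = {
        "admissible": m < absB,
        "stable": (mA < 0) and (mB < 0) and (-mA < m < -mB),
    }
    flags["PB2"] = {
        "admissible": m < absB,
        "stable": (mA > 0) and (mA < m < absB),
    }
    big = m >= max(absA, absB)
    flags["M1"] = {"admissible": True, "stable": big and _cmp(phi, pt.phi_A) < 0}
    flags["M2"] = {"admissible": True, "stable": False}
    flags["M3"] = {
        "admissible": True,
        "stable": big and _cmp(phi, pt.phi_A) > 0 and _cmp(phi, pt.phi_B) < 0,
    }
    flags["M4"] = {"admissible": True, "stable": big and _cmp(phi, pt.phi_B) > 0}
    return flags


def _rho0_flags(sel: SelectionRegime, phi: float, m: float) -> dict[str, dict]:
    th = m_thresholds(sel, phi, 0.0)
    pt = phi_thresholds(sel, 0.0)
    mA, mB, mF0, mstar = th.m_A, th.m_B, th.m_F0, th.m_star
    absA, absB, absF0 = abs(mA), abs(mB), abs(mF0)
    flags: dict[str, dict] = {}
    flags["F0"] = {
        "admissible": m < absF0,
        "stable": m < min(absF0, mstar),
    }
    flags["PA1"] = {
        "admissible": m < absA,
        "stable": (mstar < m < absA)
        and _cmp(phi, pt.phi_M1) > 0
        and _cmp(phi, pt.phi_AB) < 0,
    }
    flags["PB2"] = {
        "admissible": m < absB,
        "stable": (mstar < m < absB)
        and _cmp(phi, pt.phi_AB) > 0
        and _cmp(phi, pt.phi_M4) < 0,
    }
    flags["PA2"] = {"admissible": m < absA, "stable": False}
    flags["PB1"] = {"admissible": m < absB, "stable": False}
    m1_stable = (m > -mF0 and _cmp(phi, pt.phi_M1) < 0) or (
        m > -mA and _cmp(phi, pt.phi_M1) >= 0 and _cmp(phi, pt.phi_A) < 0
    )
    m4_stable = (m > mB and _cmp(phi, pt.phi_B) > 0 and _cmp(phi, pt.phi_M4) <= 0) or (
        m > mF0 and _cmp(phi, pt.phi_M4) > 0
    )
    flags["M1"] = {"admissible": True, "stable": bool(m1_stable)}
    flags["M2"] = {"admissible": True, "stable": False}
    flags["M3"] = {
        "admissible": True,
        "stable": m > max(absA, absB)
        and _cmp(phi, pt.phi_A) > 0
        and _cmp(phi, pt.phi_B) < 0,
    }
    flags["M4"] = {"admissible": True, "stable": bool(m4_stable)}
    return flags


def _build_intervals(flag_fn, critical: list[float]) -> list[MInterval]:
    crit = sorted({c for c in critical if math.isfinite(c) and c > 0})
    merged: list[float] = []
    for c in crit:
        if not merged or c - merged[-1] > 1e-10 * max(1.0, c):
            merged.append(c)
    edges = [0.0] + merged
    intervals = []
    for lo, hi in zip(edges, edges[1:] + [math.inf]):
        mid = 0.5 * (lo + hi) if math.isfinite(hi) else lo * 2 + 1.0
        flags = flag_fn(mid)
        shown = {
            k: v
            for k, v in flags.items()
            if v["admissible"]
        }
        stable = tuple(k for k, v in flags.items() if v["admissible"] and v["stable"])
        intervals.append(MInterval(lo, hi, stable, shown))
    return intervals


# ---------------------------------------------------------------------------
# linkage equilibrium: Theorem-level classification
# ---------------------------------------------------------------------------

_L_ROLES = {
    "L1": dict(P_X="PB1", P_Y="PA1", M_i="M1", m_X="-m_B", m_Y="-m_A"),
    "L2": dict(P_X="PA1", P_Y="PB1", M_i="M1", m_X="-m_A", m_Y="-m_B"),
    "L3": dict(P_X="PA1", P_Y="PB2", M_i="M3", m_X="m_A", m_Y="-m_B"),
    "L4": dict(P_X="PB2", P_Y="PA1", M_i="M3", m_X="-m_B", m_Y="m_A"),
    "L5": dict(P_X="PB2", P_Y="PA2", M_i="M4", m_X="m_B", m_Y="m_A"),
}


def _role_rate(expr: str, th) -> float:
    sign = -1.0 if expr.startswith("-") else 1.0
    name = expr.lstrip("-")
    return sign * getattr(th, name)


def classify_LE(selection: SelectionRegime, phi) -> BifurcationDiagram:
    """Symbolic bifurcation diagram of the linkage-equilibrium dynamics.

    ``phi`` may be a float or an exact rational; exact inputs make the
    measure-zero degenerate diagrams (``b``, ``c``) detectable exactly.
    """
    pt = phi_thresholds(selection)
    b2_lt_a2 = selection.beta2 < selection.alpha2
    label, role_key = None, None
    cA = _cmp(phi, pt.phi_A)
    cB = _cmp(phi, pt.phi_B)
    cAB = _cmp(phi, pt.phi_AB)
    cABt = _cmp(phi, pt.phi_AB_tilde)
    if cA < 0:
        if b2_lt_a2:
            if cABt < 0:
                label, role_key = "a", "L1"
            elif cABt == 0:
                label, role_key = "b", "L1"
            else:
                label, role_key = "a", "L2"
        else:
            label, role_key = "a", "L2"
    elif cA == 0:
        label, role_key = "c", "L2"  # P_X = PA1, m_Y = -m_B; m_X = infinity
    elif cAB < 0:
        label, role_key = "a", "L3"
    elif cAB == 0:
        label, role_key = "b", "L4"
    elif cB < 0:
        label, role_key = "a", "L4"
    elif cB == 0:
        label, role_key = "c", "L5"  # P_X = PB2, m_Y = m_A; m_X = infinity
    else:
        label, role_key = "a", "L5"

    roles = dict(_L_ROLES[role_key])
    th = m_thresholds(selection, float(phi))
    m_X = abs(_role_rate(roles["m_X"], th))
    m_Y = abs(_role_rate(roles["m_Y"], th))
    events: list[BifurcationEvent] = []
    if label == "a":
        events.append(BifurcationEvent(m_Y, "exchange_of_stability", ("Finf", roles["P_X"])))
        events.append(BifurcationEvent(m_Y, "exit", (roles["P_Y"], roles["M_i"])))
        events.append(BifurcationEvent(m_X, "exchange_of_stability", (roles["P_X"], roles["M_i"])))
    elif label == "b":
        events.append(BifurcationEvent(m_X, "exchange_of_stability", ("Finf", roles["M_i"])))
        events.append(BifurcationEvent(m_X, "exit", (roles["P_X"], roles["M_i"])))
        events.append(BifurcationEvent(m_X, "exit", (roles["P_Y"], roles["M_i"])))
    else:  # "c": terminal SLP, m_X = infinity
        events.append(BifurcationEvent(m_Y, "exchange_of_stability", ("Finf", roles["P_X"])))
    events.sort(key=lambda e: e.m)
    intervals = _build_intervals(
        lambda m: _le_flags(selection, float(phi), m),
        [abs(th.m_A), abs(th.m_B)],
    )
    return BifurcationDiagram("LE", label, {"role": role_key, **roles}, events, intervals)


# ---------------------------------------------------------------------------
# complete linkage: Theorem-level classification
# ---------------------------------------------------------------------------

_R_ROLES = {
    "R1": dict(P_X="PA1", P_Y="PB2", M_i="M1", m_X="|m_A|", m_Y="|m_B|"),
    "R2": dict(P_X="PB2", P_Y="PA1", M_i="M4", m_X="|m_B|", m_Y="|m_A|"),
    "R3": dict(P_X="PA1", P_Y="PB2", M_i="M4", m_X="|m_A|", m_Y="|m_B|"),
    "R4": dict(P_X="PB2", P_Y="PA1", M_i="M1", m_X="|m_B|", m_Y="|m_A|"),
    "R1'": dict(P_X="PA1", M_i="M1", m_X="|m_A|"),
    "R2'": dict(P_X="PB2", M_i="M4", m_X="|m_B|"),
    "R3'": dict(P_X="PA1", P_Y="PB2", m_X="|m_A|", m_Y="|m_B|"),
    "R4'": dict(P_X="PB2", P_Y="PA1", m_X="|m_B|", m_Y="|m_A|"),
}


def classify_rho0(selection: SelectionRegime, phi) -> BifurcationDiagram:
    """Symbolic bifurcation diagram of the complete-linkage dynamics.

    The branch order follows the strict threshold chain
    ``0 < phi^M1 < phi^A < phi^AF0 < {phi^F0, phi^AB} < phi^BF0 < phi^B <
    phi^M4 < 1`` (whether ``phi^F0`` precedes ``phi^AB`` is decided by the
    sign of ``theta~ = alpha1*alpha2 - beta1*beta2``).
    """
    pt = phi_thresholds(selection, 0)
    c = {
        name: _cmp(phi, getattr(pt, attr))
        for name, attr in [
            ("M1", "phi_M1"),
            ("A", "phi_A"),
            ("AF0", "phi_AF0"),
            ("F0", "phi_F0"),
            ("AB", "phi_AB"),
            ("BF0", "phi_BF0"),
            ("B", "phi_B"),
            ("M4", "phi_M4"),
        ]
    }
    cF0AB = _cmp(pt.phi_F0, pt.phi_AB)

    if c["M1"] < 0:
        label, role_key = "a", "R1'"
    elif c["M1"] == 0:
        label, role_key = "b", "R1'"
    elif c["A"] < 0:
        label, role_key = "c", "R1'"
    elif c["A"] == 0:
        label, role_key = "d", "R1'"
    elif c["AF0"] < 0:
        label, role_key = "e", "R4"
    elif c["AF0"] == 0:
        label, role_key = "f", "R2"
    elif c["F0"] == 0 and c["AB"] == 0:
        label, role_key = "h", ""
    elif c["F0"] == 0:
        label, role_key = ("i", "R3'") if cF0AB > 0 else ("i", "R4'")
    elif c["AB"] == 0:
        label, role_key = "j", ""
    elif c["F0"] < 0 and c["AB"] < 0:
        label, role_key = "g", "R4"
    elif c["F0"] > 0 and c["AB"] < 0:
        label, role_key = "g", "R2"
    elif c["AB"] > 0 and c["F0"] < 0:
        label, role_key = "g", "R1"
    elif c["BF0"] < 0:
        label, role_key = "g", "R3"
    elif c["BF0"] == 0:
        label, role_key = "f", "R1"
    elif c["B"] < 0:
        label, role_key = "e", "R3"
    elif c["B"] == 0:
        label, role_key = "d", "R2'"
    elif c["M4"] < 0:
        label, role_key = "c", "R2'"
    elif c["M4"] == 0:
        label, role_key = "b", "R2'"
    else:
        label, role_key = "a", "R2'"

    roles = dict(_R_ROLES.get(role_key, {}))
    if label == "j":
        roles["M_i"] = "M1" if cF0AB > 0 else "M4"

    th = m_thresholds(selection, float(phi), 0.0)
    mstar = th.m_star
    absF0 = abs(th.m_F0)
    events: list[BifurcationEvent] = []
    flags_at = lambda m: _rho0_flags(selection, float(phi), m)

    # F0 bifurcations
    if math.isfinite(absF0):
        target = "M1" if th.m_F0 < 0 else "M4"
        kind = "exchange_of_stability" if absF0 <= mstar else "exit"
        events.append(BifurcationEvent(absF0, kind, ("F0", target)))
    if math.isfinite(mstar) and mstar < absF0:
        # stability passes from F0 through the marginal tri-gametic line
        if c["AB"] < 0:
            partner = "PA1"
        elif c["AB"] > 0:
            partner = "PB2"
        else:
            partner = "M3"
        events.append(BifurcationEvent(mstar, "marginal_line", ("F0", partner)))
    # SLP exits
    if math.isfinite(th.m_A):
        target = "M1" if th.m_A < 0 else "M3"
        below = flags_at(abs(th.m_A) * (1 - 1e-9))["PA1"]["stable"]
        events.append(
            BifurcationEvent(abs(th.m_A), "exchange_of_stability" if below else "exit", ("PA1", target))
        )
    if math.isfinite(th.m_B):
        target = "M3" if th.m_B < 0 else "M4"
        below = flags_at(abs(th.m_B) * (1 - 1e-9))["PB2"]["stable"]
        events.append(
            BifurcationEvent(abs(th.m_B), "exchange_of_stability" if below else "exit", ("PB2", target))
        )
    events.sort(key=lambda e: e.m)
    intervals = _build_intervals(
        flags_at, [abs(th.m_A), abs(th.m_B), absF0, mstar]
    )
    return BifurcationDiagram(
        "rho0", label, {"role": role_key, **roles}, events, intervals
    )


def phi_sweep(
    selection: SelectionRegime, regime: str = "LE"
) -> list[tuple[float, float, str, str]]:
    """Diagram sequence as phi increases from 0 to 1.

    Returns ``(phi_lo, phi_hi, diagram_label, role)`` for the open
    intervals between thresholds plus the degenerate diagrams at the
    thresholds themselves (zero-width entries).
    """
    rho = 0.0
    pt = phi_thresholds(selection, rho)
    if regime == "LE":
        marks = [pt.phi_AB_tilde, pt.phi_A, pt.phi_AB, pt.phi_B]
        classify = classify_LE
    elif regime == "rho0":
        marks = [
            pt.phi_M1,
            pt.phi_A,
            pt.phi_AF0,
            pt.phi_F0,
            pt.phi_AB,
            pt.phi_BF0,
            pt.phi_B,
            pt.phi_M4,
        ]
        classify = classify_rho0
    else:
        raise ValueError("regime must be 'LE' or 'rho0'")
    marks = sorted({m for m in marks if 0.0 < m < 1.0})
    out = []
    edges = [0.0] + marks + [1.0]
    for lo, hi in zip(edges, edges[1:]):
        mid = 0.5 * (lo + hi)
        d = classify(selection, mid)
        out.append((lo, hi, d.diagram_label, d.role_assignment.get("role", "")))
        if hi < 1.0:
            d = classify(selection, hi)
            out.append((hi, hi, d.diagram_label, d.role_assignment.get("role", "")))
    return out


# ---------------------------------------------------------------------------
# general rho: numerical scan
# ---------------------------------------------------------------------------


def _signature(params: ModelParameters, seeds) -> tuple[dict, list]:
    """Stability/admissibility fingerprint of the equilibrium set at one m."""
    from .equilibria import (
        f_zero,
        find_internal,
        monomorphic_equilibria,
        slp_equilibria,
    )
    from .stability import classify

    recs = monomorphic_equilibria() + slp_equilibria(params)
    internal = []
    if params.rho_value == 0.0:
        f0 = f_zero(params)
        if f0.admissible:
            recs.append(f0)
    else:
        internal = find_internal(params, extra_seeds=seeds)
        recs.extend(internal)
    sig = {}
    for rec in recs:
        if not rec.admissible:
            sig[rec.label] = "absent"
            continue
        try:
            v = classify(rec, params, residual_tol=1e-6)
            sig[rec.label] = v.classification
        except ValueError:
            sig[rec.label] = "unknown"
    sig["n_internal"] = str(len(internal))
    return sig, [r.y for r in internal]


def scan_numeric(
    params: ModelParameters,
    m_grid: np.ndarray,
    *,
    bisect_tol: float = 1e-4,
) -> BifurcationDiagram:
    """Numerical bifurcation scan in ``m`` at fixed finite rho and phi.

    Equilibria (closed-form boundary ones plus numerically located
    interior ones) are classified at each grid value; a change of the
    stability signature between neighbours is bracketed by bisection.  A
    drop in the number of interior equilibria without a boundary collision
    is reported as a saddle-node; intervals where an interior equilibrium
    coexists stably with a stable boundary equilibrium mark Type-2
    (fold) patterns, otherwise the pattern is Type 1.
    """
    phi = params.migration.phi
    m_grid = np.asarray(sorted(float(m) for m in m_grid))
    sigs, seeds_list = [], []
    seeds = None
    for m in m_grid:
        p = params.with_migration(m, phi)
        sig, seeds = _signature(p, seeds)
        sigs.append(sig)
        seeds_list.append(seeds)
    events: list[BifurcationEvent] = []
    intervals: list[MInterval] = []
    for i in range(len(m_grid) - 1):
        lo, hi = m_grid[i], m_grid[i + 1]
        slo, shi = sigs[i], sigs[i + 1]
        if slo == shi:
            continue
        seeds = seeds_list[i]
        a, b, sa = lo, hi, slo
        while b - a > bisect_tol * max(1.0, b):
            mid = 0.5 * (a + b)
            sm, seeds_mid = _signature(params.with_migration(mid, phi), seeds)
            if sm == sa:
                a, seeds = mid, seeds_mid
            else:
                b = mid
        changed = sorted(
            k for k in set(slo) | set(shi) if slo.get(k) != shi.get(k)
        )
        n_lo = int(slo.get("n_internal", "0"))
        n_hi = int(shi.get("n_internal", "0"))
        boundary_changed = any(k for k in changed if not k.startswith(("F", "n_")))
        if n_hi < n_lo and not boundary_changed:
            kind = "saddle_node"
        elif n_hi > n_lo and not boundary_changed:
            kind = "entry"
        else:
            kind = "exchange_of_stability" if changed else "unresolved"
        events.append(
            BifurcationEvent(0.5 * (a + b), kind, tuple(k for k in changed if k != "n_internal"))
        )
    bistable = []
    for i, m in enumerate(m_grid):
        stable = tuple(
            k
            for k, v in sigs[i].items()
            if v == "asymptotically_stable" and k != "n_internal"
        )
        intervals.append(MInterval(float(m), float(m), stable, dict(sigs[i])))
        internal_stable = any(s.startswith("F") for s in stable)
        boundary_stable = any(not s.startswith("F") for s in stable)
        bistable.append(internal_stable and boundary_stable)
    pattern = "type2" if any(e.kind == "saddle_node" for e in events) or any(bistable) else "type1"
    return BifurcationDiagram(
        "numeric",
        pattern,
        {"phi": phi, "rho": params.rho},
        events,
        intervals,
    )
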