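import numpy as np
import pytest

from twodeme import (
    ModelParameters,
    classify,
    f_zero,
    f_zero_stability,
    find_internal,
    integrate,
    m_tilde,
    monomorphic_equilibria,
    monomorphic_stability,
    slp_equilibria,
    slp_stability_rho0,
    weak_migration_F,
)
from twodeme.stability import classify_rho0_subsystem
from twodeme.state import pqd_to_gametes
from twodeme.sweeps import random_interior_state

from conftest import random_canonical_params


def _boundary_margin(p):
    """Distance of the draw from the closed-form condition boundaries."""
    from twodeme import compute_ratios

    r = compute_ratios(p)
    return min(
        abs(abs(r.sigma_sum) - 1.0),
        abs(abs(r.tau_sum) - 1.0),
        abs(abs(r.kappa_sum) - 1.0),
    )


class TestMonomorphicStability:
    def test_small_m_no_monomorphism_stable(self, rng):
        for _ in range(50):
            p = random_canonical_params(rng, rho=float(rng.uniform(0, 2)), m_high=0.03)
            verdicts = monomorphic_stability(p)
            assert all(v.classification == "unstable" for v in verdicts.values())

    def test_m2_always_unstable_numerically(self, rng):
        m2 = next(r for r in monomorphic_equilibria() if r.label == "M2")
        for _ in range(100):
            p = random_canonical_params(rng, rho=float(rng.uniform(0, 2)), m_high=5.0)
            assert classify(m2, p).classification == "unstable"

    def test_m3_stability_independent_of_rho(self):
        # sigma-sum > 1 and tau-sum < -1 is achievable when each locus is
        # under stronger selection in a different deme
        base = dict(m=2.0, phi=0.5)
        verdicts = [
            monomorphic_stability(
                ModelParameters.create(0.4, -2.0, 2.0, -0.4, rho=rho, **base)
            )["M3"].classification
            for rho in (0.0, 0.5, 5.0)
        ]
        assert len(set(verdicts)) == 1
        assert verdicts[0] == "asymptotically_stable"

    def test_closed_form_matches_eigenvalues(self, rng):
        """Proposition-level conditions agree with the 6x6 spectrum away
        from the condition boundaries."""
        checked = 0
        mono = monomorphic_equilibria()
        while checked < 1000:
            p = random_canonical_params(rng, rho=float(rng.uniform(0, 3)), m_high=6.0)
            closed = monomorphic_stability(p)
            for rec in mono:
                c = closed[rec.label]
                if c.classification == "marginal" or (
                    c.leading_real_part is not np.nan
                    and abs(c.leading_real_part) < 1e-3
                ):
                    continue
                e = classify(rec, p)
                if abs(e.leading_real_part) < 1e-6:
                    continue
                assert c.classification == e.classification, (
                    rec.label,
                    p.selection,
                    p.migration,
                    p.rho,
                )
                checked += 1

    def test_at_most_one_of_m1_m3_m4_stable(self, rng):
        for _ in range(1000):
            p = random_canonical_params(rng, rho=float(rng.uniform(0, 3)), m_high=8.0)
            verdicts = monomorphic_stability(p)
            stable = [k for k, v in verdicts.items() if v.stable]
            assert len(stable) <= 1


class TestWeakMigration:
    def test_weak_migration_polymorphism_is_stable(self, rng):
        for _ in range(20):
            p = random_canonical_params(rng, rho=float(rng.uniform(0.2, 2)), m_high=0.01)
            if p.migration.m == 0:
                continue
            res = integrate(weak_migration_F(p).y, p, rhs_tol=1e-12)
            assert classify(res.y, p).classification == "asymptotically_stable"


class TestRho0ClosedForms:
    def test_m_tilde_worked_value(self, sel_weak_a):
        # -(0.5)(-1)(2)(-2)(2.5)(-3)/1 = 15
        assert m_tilde(sel_weak_a) == pytest.approx(15.0)

    def test_f_zero_stable_iff_product_below_threshold(self):
        p_stable = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m1=0.5, m2=0.5, rho=0.0)
        assert f_zero_stability(p_stable).stable
        # m1*m2 = 16 > 15 with F0 still admissible needs a different phi
        p_unstable = ModelParameters.create(
            0.5, -1.0, 2.0, -2.0, m1=4.0, m2=4.5, rho=0.0
        )
        rec = f_zero(p_unstable)
        assert rec.admissible
        v = f_zero_stability(p_unstable)
        assert v.classification == "unstable"
        # eigenvalues of the tri-gametic subsystem agree
        e = classify_rho0_subsystem(rec.y, p_unstable)
        assert e.classification == "unstable"

    def test_marginal_line_on_the_product_boundary(self, sel_weak_a):
        # m1*m2 = m~ = 15 exactly: a line of equilibria appears
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m1=3.5, m2=15.0 / 3.5, rho=0.0)
        assert f_zero_stability(p).classification == "marginal"
        rec = f_zero(p)
        e = classify_rho0_subsystem(rec.y, p, tol=1e-7)
        assert e.classification == "marginal"

    def test_closed_form_agrees_with_subsystem_eigenvalues(self, rng):
        checked = 0
        while checked < 300:
            p = random_canonical_params(rng, rho=0.0, m_high=4.0)
            rec = f_zero(p)
            if not rec.admissible or _boundary_margin(p) < 1e-3:
                continue
            mt = m_tilde(p.selection)
            if abs(p.migration.m1 * p.migration.m2 - mt) < 1e-3 * max(mt, 1.0):
                continue
            closed = f_zero_stability(p)
            eig = classify_rho0_subsystem(rec.y, p)
            assert closed.classification == eig.classification
            checked += 1

    def test_m3_never_stable_together_with_f_zero(self, rng):
        for _ in range(500):
            p = random_canonical_params(rng, rho=0.0, m_high=6.0)
            rec = f_zero(p)
            if not rec.admissible:
                continue
            try:
                f0_stable = f_zero_stability(p).stable
            except ValueError:
                continue
            m3_stable = monomorphic_stability(p)["M3"].stable
            assert not (f0_stable and m3_stable)


class TestSLPStabilityRho0:
    def test_unstable_below_product_threshold(self, rng):
        for _ in range(200):
            p = random_canonical_params(rng, rho=0.0, m_high=2.0)
            if p.migration.m1 * p.migration.m2 >= m_tilde(p.selection):
                continue
            verdicts = slp_stability_rho0(p)
            for v in verdicts.values():
                assert v.classification != "asymptotically_stable"

    def test_closed_form_agrees_with_subsystem_eigenvalues(self, rng):
        labels = {"PA1", "PB2"}
        checked = 0
        while checked < 300:
            p = random_canonical_params(rng, rho=0.0, m_high=6.0)
            if _boundary_margin(p) < 1e-3:
                continue
            mt = m_tilde(p.selection)
            if abs(p.migration.m1 * p.migration.m2 - mt) < 1e-3 * max(mt, 1.0):
                continue
            closed = slp_stability_rho0(p)
            for rec in slp_equilibria(p):
                if rec.label not in labels or not rec.admissible:
                    continue
                eig = classify_rho0_subsystem(rec.y, p)
                if eig.classification == "marginal":
                    continue
                assert closed[rec.label].classification == eig.classification
                checked += 1

    def test_repulsion_gamete_always_lost(self, rng):
        """Under complete linkage the repulsion haplotype A1B2 vanishes
        from every interior starting point."""
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m1=0.4, m2=0.3, rho=0.0)
        for _ in range(5):
            y0 = random_interior_state(rng)
            res = integrate(y0, p, horizon=1e5, rhs_tol=1e-11)
            x = pqd_to_gametes(res.y)
            assert x[:, 1].max() < 1e-5


class TestClassifyGuards:
    def test_non_equilibrium_rejected(self, params_weak_a):
        with pytest.raises(ValueError, match="not an equilibrium"):
            classify(np.array([0.6, 0.4, 0.6, 0.4, 0.0, 0.0]), params_weak_a)

    def test_internal_equilibrium_stable_in_weak_migration(self, params_weak_a):
        p = params_weak_a.with_migration(0.05)
        rec = find_internal(p)[0]
        assert classify(rec, p).stable
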