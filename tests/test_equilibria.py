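import numpy as np
import pytest

from twodeme import (
    LE,
    ModelParameters,
    compute_ratios,
    f_infinity,
    f_zero,
    find_internal,
    integrate,
    le_rhs,
    monomorphic_equilibria,
    qle_F,
    slp_equilibria,
    weak_migration_F,
)

from conftest import random_canonical_params


class TestMonomorphic:
    def test_coordinates(self):
        recs = {r.label: r for r in monomorphic_equilibria()}
        assert np.allclose(recs["M1"].y, [1, 1, 1, 1, 0, 0])
        assert np.allclose(recs["M4"].y, [0, 0, 0, 0, 0, 0])

    def test_always_roots_of_the_flow(self, rng):
        for _ in range(50):
            p = random_canonical_params(rng, rho=float(rng.uniform(0, 2)))
            for rec in monomorphic_equilibria():
                assert rec.residual(p) < 1e-14


class TestSLP:
    def test_no_migration_full_differentiation(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=0.0, phi=0.5, rho=1.0)
        pa1 = next(r for r in slp_equilibria(p) if r.label == "PA1")
        assert pa1.y[0] == 1.0 and pa1.y[1] == 0.0

    def test_slp_coordinates_are_marginal_one_locus_roots(self, sel_weak_a):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.375, rho=1.0)
        pa1 = next(r for r in slp_equilibria(p) if r.label == "PA1")
        # the locus-A frequencies solve the decoupled one-locus dynamics
        res = le_rhs(np.array([pa1.y[0], pa1.y[1], 1.0, 1.0]), p)
        assert np.abs(res[:2]).max() < 1e-12

    def test_exit_towards_neighbouring_monomorphism(self, sel_weak_a):
        """As the admissibility bound is approached the SLP collapses onto
        the monomorphism it exits through (sigma-sum up to 1 -> M3/M4)."""
        phi = 0.375  # m_A = 8 > 0
        last = None
        for m in [7.9, 7.99, 7.999]:
            p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=m, phi=phi, rho=1.0)
            pa1 = next(r for r in slp_equilibria(p) if r.label == "PA1")
            assert pa1.extras["exit_target"] == "M3"
            gap = np.abs(pa1.y - np.array([0, 0, 1, 1, 0, 0])).max()
            if last is not None:
                assert gap < last
            last = gap
        assert last < 0.02

    def test_residuals_on_random_draws(self, rng):
        for _ in range(200):
            p = random_canonical_params(rng, rho=float(rng.uniform(0, 2)))
            for rec in slp_equilibria(p):
                if rec.admissible:
                    assert rec.residual(p) < 1e-10


class TestFInfinity:
    def test_admissible_iff_all_slps_admissible(self, rng):
        for _ in range(200):
            p = random_canonical_params(rng, rho=LE, m_high=3.0)
            slps = slp_equilibria(p)
            assert f_infinity(p).admissible == all(r.admissible for r in slps)

    def test_le_residual(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=4.0, phi=0.375, rho=LE)
        rec = f_infinity(p)
        assert rec.admissible
        assert np.abs(le_rhs(rec.y[:4], p)).max() < 1e-12

    def test_no_migration_is_full_local_adaptation(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=0.0, phi=0.5, rho=LE)
        assert np.allclose(f_infinity(p).y, [1, 0, 1, 0, 0, 0])


class TestFZero:
    def test_no_migration_limit(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=0.0, phi=0.5, rho=0.0)
        assert np.allclose(f_zero(p).y[:4], [1, 0, 1, 0])

    def test_worked_example_ratios_and_residual(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m1=0.5, m2=0.5, rho=0.0)
        r = compute_ratios(p)
        assert r.kappa1 == pytest.approx(0.2)
        assert r.kappa2 == pytest.approx(-1.0 / 6.0)
        rec = f_zero(p)
        assert rec.admissible
        assert rec.residual(p) < 1e-12
        # the closed form agrees with a long integration from nearby
        y0 = rec.y.copy()
        y0[:4] = 0.95 * y0[:4] + 0.025
        y0[4:] *= 0.8
        res = integrate(y0, p, horizon=1e5)
        assert np.abs(res.y - rec.y).max() < 1e-6

    def test_exit_to_m4_as_kappa_sum_grows(self):
        # kappa1+kappa2 -> 1 from below pushes F0 onto M4
        for m, tol in [(2.9, 0.05), (3.05, 0.005)]:
            p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=m, phi=0.9, rho=0.0)
            rec = f_zero(p)
            assert rec.extras["exit_target"] == "M4"
            assert np.abs(rec.y).max() < tol


class TestWeakMigrationExpansion:
    def test_exact_at_zero_migration(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=0.0, phi=0.5, rho=1.0)
        assert np.allclose(weak_migration_F(p).y, [1, 0, 1, 0, 0, 0])

    def test_ld_formula(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m1=0.01, m2=0.0, rho=0.0)
        # D1 = m1 / (alpha1 + beta1 + rho) = 0.01 / 2.5
        assert weak_migration_F(p).y[4] == pytest.approx(0.004)

    def test_error_scales_quadratically_in_m(self):
        errs = []
        for m in (1e-2, 1e-3, 1e-4):
            p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=m, phi=0.375, rho=1.0)
            approx = weak_migration_F(p)
            res = integrate(approx.y, p, rhs_tol=1e-13)
            errs.append(np.abs(res.y - approx.y).max())
        slopes = np.diff(np.log(errs)) / np.diff(np.log([1e-2, 1e-3, 1e-4]))
        assert np.all(np.abs(slopes - 2.0) < 0.2)


class TestQLE:
    def test_converges_to_le_product(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.375, rho=1e8)
        rec = qle_F(p)
        le = f_infinity(p)
        assert np.abs(rec.y - le.y).max() < 1e-6

    def test_positive_ld_in_both_demes(self, rng):
        for _ in range(100):
            p = random_canonical_params(rng, rho=float(rng.uniform(20, 200)))
            if not f_infinity(p).admissible or p.migration.m == 0:
                continue
            rec = qle_F(p)
            assert rec.y[4] >= 0 and rec.y[5] >= 0

    def test_error_scales_as_inverse_rho_squared(self):
        errs, rhos = [], [10.0, 100.0, 1000.0]
        for rho in rhos:
            p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.375, rho=rho)
            approx = qle_F(p)
            res = integrate(approx.y, p, rhs_tol=1e-13)
            errs.append(np.abs(res.y - approx.y).max())
        slopes = np.diff(np.log(errs)) / np.diff(np.log(rhos))
        assert np.all(np.abs(slopes + 2.0) < 0.2)

    def test_rejects_inadmissible_le_equilibrium(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=20.0, phi=0.375, rho=50.0)
        with pytest.raises(ValueError, match="admissible"):
            qle_F(p)


class TestFindInternal:
    def test_weak_migration_unique_root_near_expansion(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=0.01, phi=0.375, rho=1.0)
        roots = find_internal(p)
        assert len(roots) == 1
        assert np.abs(roots[0].y - weak_migration_F(p).y).max() < 1e-3

    def test_internal_roots_always_carry_ld(self, rng):
        found = 0
        for _ in range(60):
            p = random_canonical_params(rng, rho=float(rng.uniform(0.1, 3)))
            for rec in find_internal(p):
                found += 1
                assert min(abs(rec.y[4]), abs(rec.y[5])) > 1e-12
        assert found > 10

    def test_bistable_continent_island_like_regime(self):
        """Highly asymmetric migration at intermediate recombination can
        hold one stable and one unstable full polymorphism."""
        from twodeme import classify

        p = ModelParameters.create(
            1.0, -1.05, 1.1, -1.0, m=1.2, phi=0.97, rho=1.0
        )
        roots = find_internal(p)
        kinds = sorted(
            classify(r, p).classification for r in roots
        )
        assert len(roots) == 2
        assert kinds == ["asymptotically_stable", "unstable"]
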