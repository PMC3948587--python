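import math

import numpy as np
import pytest

from twodeme import (
    LE,
    ModelParameters,
    SelectionRegime,
    compute_ratios,
    m_max_LE,
    m_max_numeric,
    m_max_qle,
    m_max_rho0,
    m_thresholds,
    m_tilde,
    phi_thresholds,
)

from conftest import random_canonical_params


class TestRatios:
    def test_zero_migration_gives_zero_ratios(self):
        p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=0.0, phi=0.5, rho=0.0)
        r = compute_ratios(p)
        assert r.sigma_sum == r.tau_sum == r.kappa_sum == 0.0

    def test_sign_pattern(self, rng):
        for _ in range(100):
            p = random_canonical_params(rng)
            if p.migration.m1 == 0 or p.migration.m2 == 0:
                continue
            r = compute_ratios(p)
            assert r.sigma1 > 0 > r.sigma2
            assert r.tau1 > 0 > r.tau2

    def test_harmonic_identity(self, rng):
        # 1/kappa_k = 1/sigma_k + 1/tau_k
        for _ in range(200):
            p = random_canonical_params(rng)
            if min(p.migration.m1, p.migration.m2) < 1e-6:
                continue
            r = compute_ratios(p)
            for kap, sig, tau in ((r.kappa1, r.sigma1, r.tau1), (r.kappa2, r.sigma2, r.tau2)):
                assert 1.0 / kap == pytest.approx(1.0 / sig + 1.0 / tau, rel=1e-12)


class TestPhiThresholds:
    def test_printed_fractions_weak_a_regime(self, sel_weak_a):
        t = phi_thresholds(sel_weak_a, rho=0.0)
        assert t.phi_A == pytest.approx(1 / 3)
        assert t.phi_AB == pytest.approx(3 / 8)
        assert t.phi_B == pytest.approx(1 / 2)
        assert t.phi_AB_tilde == pytest.approx(1 / 4)
        assert t.phi_M1 == pytest.approx(5 / 17)
        assert t.phi_M4 == pytest.approx(5 / 8)

    def test_printed_fractions_crossed_regime(self, sel_crossed):
        t = phi_thresholds(sel_crossed, rho=0.0)
        assert t.phi_M1 == pytest.approx(1 / 26)
        assert t.phi_A == pytest.approx(1 / 6)
        assert t.phi_AB == pytest.approx(1 / 2)
        assert t.phi_B == pytest.approx(5 / 6)
        assert t.phi_M4 == pytest.approx(25 / 26)

    def test_symmetric_selection_centres_thresholds(self):
        t = phi_thresholds(SelectionRegime(1.0, -1.0, 2.0, -2.0), rho=0.0)
        assert t.phi_A == pytest.approx(0.5)
        assert t.phi_B == pytest.approx(0.5)

    def test_ordering_chain(self, rng):
        # 0 < phi^A < phi^AF0 < phi^AB < phi^BF0 < phi^B < 1
        for _ in range(300):
            p = random_canonical_params(rng)
            t = phi_thresholds(p.selection, rho=0.0)
            chain = [0.0, t.phi_A, t.phi_AF0, t.phi_AB, t.phi_BF0, t.phi_B, 1.0]
            assert all(a < b for a, b in zip(chain, chain[1:]))
            assert t.phi_AF0 < t.phi_F0 < t.phi_BF0
            if p.selection.beta2 < p.selection.alpha2:
                assert 0.0 < t.phi_AB_tilde < t.phi_A
                assert t.phi_AB_tilde < t.phi_M1

    def test_rho0_chain_with_m_thresholds(self, rng):
        for _ in range(300):
            p = random_canonical_params(rng)
            t = phi_thresholds(p.selection, rho=0.0)
            chain = [0.0, t.phi_M1, t.phi_A, t.phi_AF0]
            if p.selection.theta_tilde > 0:
                chain += [t.phi_AB, t.phi_F0]
            else:
                chain += [t.phi_F0, t.phi_AB] if p.selection.theta_tilde < 0 else []
            chain += [t.phi_BF0, t.phi_B, t.phi_M4, 1.0]
            assert all(a <= b for a, b in zip(chain, chain[1:]))


class TestMThresholds:
    def test_phi_zero_attains_lower_bound(self, sel_weak_a):
        th = m_thresholds(sel_weak_a, 0.0)
        assert th.m_A == pytest.approx(sel_weak_a.alpha2)
        assert th.m_B == pytest.approx(sel_weak_a.beta2)

    def test_weak_a_values_at_phi_ab(self, sel_weak_a):
        th = m_thresholds(sel_weak_a, 3 / 8)
        assert th.m_A == pytest.approx(8.0)
        assert th.m_B == pytest.approx(-8.0)  # m^A = -m^B at phi^AB
        assert th.m_star == pytest.approx(8.0)
        assert m_tilde(sel_weak_a) == pytest.approx(15.0)

    def test_infinity_sentinels_at_defining_ratios(self, sel_weak_a):
        t = phi_thresholds(sel_weak_a)
        th = m_thresholds(sel_weak_a, t.phi_A)
        assert math.isinf(th.m_A)
        assert math.isinf(m_thresholds(sel_weak_a, t.phi_B).m_B)
        assert math.isinf(m_thresholds(sel_weak_a, 0.0).m_star)

    def test_bounds_over_random_ratios(self, rng):
        for _ in range(300):
            p = random_canonical_params(rng)
            s = p.selection
            phi = float(rng.uniform(0, 1))
            th = m_thresholds(s, phi)
            # the critical rates are bounded away from zero by the selection
            # coefficients: 1/m^X interpolates linearly between their
            # reciprocals, so m^X never falls strictly between them
            if math.isfinite(th.m_A):
                assert not (s.alpha2 + 1e-12 < th.m_A < s.alpha1 - 1e-12)
            if math.isfinite(th.m_B):
                assert not (s.beta2 + 1e-12 < th.m_B < s.beta1 - 1e-12)
            if math.isfinite(th.m_F0):
                assert not (
                    s.alpha2 + s.beta2 + 1e-12
                    < th.m_F0
                    < s.alpha1 + s.beta1 - 1e-12
                )

    def test_collision_identities(self, rng):
        """At their defining ratios the critical rates collide pairwise."""
        for _ in range(200):
            p = random_canonical_params(rng)
            s = p.selection
            t = phi_thresholds(s, rho=0.0)
            th = m_thresholds(s, t.phi_AB, 0.0)
            assert th.m_A == pytest.approx(-th.m_B, rel=1e-9)
            assert th.m_A == pytest.approx(th.m_star, rel=1e-9)
            th = m_thresholds(s, t.phi_M4, 0.0)
            assert th.m_B == pytest.approx(th.m_F0, rel=1e-9)
            assert th.m_B == pytest.approx(th.m_star, rel=1e-9)
            th = m_thresholds(s, t.phi_M1, 0.0)
            assert -th.m_A == pytest.approx(-th.m_F0, rel=1e-9)
            assert -th.m_A == pytest.approx(th.m_star, rel=1e-9)
            if s.beta2 < s.alpha2:
                th = m_thresholds(s, t.phi_AB_tilde, 0.0)
                assert th.m_A == pytest.approx(th.m_B, rel=1e-9)
                assert th.m_A < 0
            # with complete linkage m^F0 = m^M4 = -m^M1
            th = m_thresholds(s, float(rng.uniform(0, 1)), 0.0)
            assert th.m_F0 == pytest.approx(th.m_M4, rel=1e-9)
            assert th.m_F0 == pytest.approx(-th.m_M1, rel=1e-9)

    def test_m_star_convex_symmetric(self, sel_weak_a):
        phis = np.linspace(0.05, 0.95, 19)
        vals = np.array([m_thresholds(sel_weak_a, ph).m_star for ph in phis])
        assert np.allclose(vals, vals[::-1], rtol=1e-9)  # symmetric about 1/2
        assert np.argmin(vals) == len(vals) // 2
        assert np.all(np.diff(vals, 2) > -1e-9)  # convex


class TestMMax:
    def test_le_value_and_maximum_at_phi_ab(self, sel_weak_a):
        assert m_max_LE(sel_weak_a, 3 / 8) == pytest.approx(8.0)
        t = phi_thresholds(sel_weak_a)
        phis = np.linspace(0.02, 0.98, 97)
        vals = [m_max_LE(sel_weak_a, ph) for ph in phis]
        assert abs(phis[int(np.argmax(vals))] - t.phi_AB) < 0.02

    def test_kink_at_phi_ab_tilde(self, sel_weak_a):
        # one-sided slopes differ at the tilde threshold when beta2 < alpha2
        t = phi_thresholds(sel_weak_a)
        h = 1e-5
        left = (
            m_max_LE(sel_weak_a, t.phi_AB_tilde)
            - m_max_LE(sel_weak_a, t.phi_AB_tilde - h)
        ) / h
        right = (
            m_max_LE(sel_weak_a, t.phi_AB_tilde + h)
            - m_max_LE(sel_weak_a, t.phi_AB_tilde)
        ) / h
        assert abs(left - right) > 0.1

    def test_rho0_weak_a_value(self, sel_weak_a):
        assert m_max_rho0(sel_weak_a, 3 / 8) == pytest.approx(8.0)
        assert m_max_rho0(sel_weak_a, 3 / 8) == pytest.approx(
            min(120 / 7, 8.0)
        )

    def test_le_never_exceeds_rho0(self, rng):
        for _ in range(1000):
            p = random_canonical_params(rng)
            phi = float(rng.uniform(0.001, 0.999))
            assert (
                m_max_LE(p.selection, phi)
                <= m_max_rho0(p.selection, phi) + 1e-9
            )

    def test_equality_exactly_at_phi_ab(self, rng):
        for _ in range(50):
            p = random_canonical_params(rng)
            t = phi_thresholds(p.selection)
            assert m_max_LE(p.selection, t.phi_AB) == pytest.approx(
                m_max_rho0(p.selection, t.phi_AB), rel=1e-9
            )

    def test_theta_zero_at_phi_ab_unbounded(self):
        s = SelectionRegime(1.0, -1.0, 2.0, -2.0)  # theta = 0
        t = phi_thresholds(s)
        assert math.isinf(m_max_rho0(s, t.phi_AB))
        assert math.isinf(m_max_LE(s, t.phi_AB))

    def test_qle_limits_to_le(self, sel_weak_a):
        assert m_max_qle(sel_weak_a, 1e12, 0.45) == pytest.approx(
            m_thresholds(sel_weak_a, 0.45).m_A, rel=1e-9
        )

    def test_qle_correction_sign_varies(self, rng):
        signs = set()
        for _ in range(300):
            p = random_canonical_params(rng)
            t = phi_thresholds(p.selection)
            phi = float(rng.uniform(t.phi_AB + 0.01, 0.99))
            mA = m_thresholds(p.selection, phi).m_A
            val = m_max_qle(p.selection, 100.0, phi)
            if math.isfinite(val) and abs(val - mA) > 1e-12:
                signs.add(val > mA)
            if len(signs) == 2:
                break
        assert signs == {True, False}

    def test_qle_matches_numeric_to_second_order(self, sel_weak_a):
        errs, rhos = [], [50.0, 100.0]
        for rho in rhos:
            p = ModelParameters.create(
                0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.45, rho=rho
            )
            num = m_max_numeric(p, rel_tol=1e-8).m_max
            errs.append(abs(num - m_max_qle(sel_weak_a, rho, 0.45)))
        # halving 1/rho should cut the error about fourfold
        ratio = errs[0] / errs[1]
        assert 2.5 < ratio < 6.0

    def test_numeric_matches_closed_forms(self, sel_weak_a):
        pLE = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.3, rho=LE)
        assert m_max_numeric(pLE).m_max == pytest.approx(m_max_LE(sel_weak_a, 0.3))
        p0 = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.3, rho=0.0)
        assert m_max_numeric(p0).m_max == pytest.approx(m_max_rho0(sel_weak_a, 0.3))

    def test_numeric_monotone_in_rho(self):
        vals = []
        for rho in (0.1, 1.0, 10.0):
            p = ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.3, rho=rho)
            vals.append(m_max_numeric(p, rel_tol=1e-4).m_max)
        assert vals[0] >= vals[1] >= vals[2] - 1e-6
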