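"""Rod-rod pair potentials, the A' identity, and nematic-spacing solving."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from fibrilphase import pair_potential as pp
from fibrilphase import phase_model as pm
from fibrilphase.electrolyte import SolutionConditions
from fibrilphase.geometry import FibrilGeometry


def k1_quadrature(z: float) -> float:
    return quad(lambda t: math.exp(-z * math.cosh(t)) * math.cosh(t), 0, 30, limit=200)[0]


def crossed_cylinder_hamaker_oracle(A, R, d, n=3000):
    """Brute-force pairwise (Hamaker) integration for perpendicular cylinders.

    Reduces the 6-D pairwise r^-6 sum to a 2-D integral over the two
    cross-sections: integrating both axes analytically gives a pi/(2 h^4)
    kernel in the axis gap h = d - z1 + z2; the substitution z = R sin t
    removes the edge square-root singularities.
    """
    x, w = np.polynomial.legendre.leggauss(n)
    t = 0.5 * np.pi * x
    wt = 0.5 * np.pi * w
    z = R * np.sin(t)
    cos2 = R * R * np.cos(t) ** 2
    F = cos2[:, None] * cos2[None, :] / (d + z[None, :] - z[:, None]) ** 4
    return -(2 * A / np.pi) * (wt @ F @ wt)


def parallel_cylinder_hamaker_oracle(A, R, d, n=400, m=200):
    """Brute-force pairwise integration for parallel cylinders, per unit length.

    The axial integral of r^-6 between two parallel lines gives a
    (3 pi / 8) rho^-5 kernel over the two cross-sections; the transverse
    coordinate is folded into a chord-overlap convolution and the remaining
    kernel integrated with a tangent substitution.
    """
    xa, wa = np.polynomial.legendre.leggauss(n)
    a = 0.5 * np.pi * xa
    wa = 0.5 * np.pi * wa
    u = R * np.sin(a)
    du_w = wa * R * np.cos(a)
    half = np.sqrt(np.maximum(R * R - u * u, 0.0))
    xp, wp = np.polynomial.legendre.leggauss(m)
    tot = 0.0
    for i in range(n):
        X = d + u - u[i]
        Ymax = half[i] + half
        psimax = np.arctan(Ymax / X)
        psi = 0.5 * psimax[:, None] * (xp[None, :] + 1.0)
        wpsi = 0.5 * psimax[:, None] * wp[None, :]
        Y = X[:, None] * np.tan(psi)
        lam = np.maximum(
            0.0, np.minimum(Ymax[:, None] - Y, 2 * np.minimum(half[i], half)[:, None])
        )
        inner = 2.0 / X[:, None] ** 4 * np.cos(psi) ** 3 * lam
        tot += du_w[i] * np.sum(du_w * np.sum(inner * wpsi, axis=1))
    return -(3 * A / (8 * np.pi)) * tot


class TestEffectiveLineCharge:
    def test_amplitude_identity_over_grid(self):
        # A' = 2 pi lam_eff^2 Q / kappa must hold to machine precision
        for lam in (0.5, 1.5, 3.0):
            for kappa in (0.1, 0.3, 1.0):
                for D in (2.0, 3.9, 8.0):
                    Q = 0.72
                    lam_eff = pp.effective_line_charge(lam, kappa, D)
                    lhs = 2 * math.pi * lam_eff**2 * Q / kappa
                    rhs = pm.electrostatic_amplitude(lam, Q, kappa, D)
                    assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_thin_rod_limit(self):
        assert pp.effective_line_charge(3.0, 1e-6, 3.9) == pytest.approx(3.0, rel=1e-4)

    def test_against_quadrature_oracle(self):
        lam, kappa, D = 3.0, 0.3, 3.9
        z = kappa * D / 2
        expected = lam * math.exp(-z) / (z * k1_quadrature(z))
        assert pp.effective_line_charge(lam, kappa, D) == pytest.approx(
            expected, rel=1e-8
        )


class TestElectrostaticPair:
    @pytest.fixture
    def cond(self):
        return SolutionConditions(pH=3.0).with_internal(0.007)

    def test_neutral_is_zero(self, cond):
        ip = pp.InteractionParams(lam_eff=0.0)
        assert pp.electrostatic_pair(10.0, 0.0, 370.0, ip, cond) == 0.0
        assert pp.electrostatic_pair(10.0, 90.0, 370.0, ip, cond) == 0.0

    def test_perpendicular_ties_to_amplitude(self, cond, lysozyme):
        ip = pp.InteractionParams.from_bare_charge(3.0, lysozyme.D, cond)
        x = 20.0
        A_prime = pm.electrostatic_amplitude(3.0, cond.Q, cond.kappa, lysozyme.D)
        u = pp.electrostatic_pair(x, 90.0, lysozyme.L, ip, cond)
        assert u == pytest.approx(A_prime * math.exp(-cond.kappa * x), rel=1e-12)

    def test_positive_and_decreasing(self, cond, lysozyme):
        ip = pp.InteractionParams.from_bare_charge(3.0, lysozyme.D, cond)
        xs = np.linspace(5.0, 60.0, 30)
        for theta in (0.0, 45.0, 90.0):
            us = [pp.electrostatic_pair(x, theta, lysozyme.L, ip, cond) for x in xs]
            assert all(u > 0 for u in us)
            assert all(a > b for a, b in zip(us, us[1:]))

    def test_parallel_exceeds_perpendicular_at_ph2(self, lysozyme):
        cond = SolutionConditions(pH=2.0).with_internal(0.0195)
        ip = pp.InteractionParams.from_bare_charge(3.0, lysozyme.D, cond)
        x = 5.4 * lysozyme.D
        assert pp.electrostatic_pair(x, 0.0, lysozyme.L, ip, cond) > pp.electrostatic_pair(
            x, 90.0, lysozyme.L, ip, cond
        )


class TestVanDerWaals:
    def test_zero_hamaker(self):
        assert pp.vdw_pair(10.0, 0.0, 3.9, 370.0, 0.0) == 0.0

    def test_crossed_inverse_s_law(self):
        u1 = pp.vdw_pair(3.9 + 2.0, 90.0, 3.9, 370.0, 3.0)
        u2 = pp.vdw_pair(3.9 + 4.0, 90.0, 3.9, 370.0, 3.0)
        assert u1 == pytest.approx(2 * u2, rel=1e-12)
        assert u1 < 0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pp.vdw_pair(3.0, 0.0, 3.9, 370.0, 3.0)

    @pytest.mark.parametrize("s_over_R", [0.005, 0.01])
    def test_crossed_closed_form_vs_hamaker_oracle(self, s_over_R):
        # Derjaguin-type closed form in its near-contact regime of validity
        A, R = 3.0, 1.95
        s = s_over_R * R
        closed = pp.vdw_pair(2 * R + s, 90.0, 2 * R, 1.0, A)
        oracle = crossed_cylinder_hamaker_oracle(A, R, 2 * R + s)
        assert closed == pytest.approx(oracle, rel=0.05)

    @pytest.mark.parametrize("s_over_R", [0.005, 0.01])
    def test_parallel_closed_form_vs_hamaker_oracle(self, s_over_R):
        A, R, L = 3.0, 1.95, 1.0
        s = s_over_R * R
        closed = pp.vdw_pair(2 * R + s, 0.0, 2 * R, L, A)
        oracle = parallel_cylinder_hamaker_oracle(A, R, 2 * R + s)
        assert closed == pytest.approx(oracle, rel=0.05)

    def test_far_field_asymptote_of_oracle(self):
        # sanity-check the oracle itself against the exact thin-rod far field
        # w(d) = -3 pi A R^4 / (8 d^5) per unit length
        A, R = 3.0, 1.0
        d = 40.0 * R
        oracle = parallel_cylinder_hamaker_oracle(A, R, d, n=200, m=100)
        far = -(3 * np.pi * A * R**4) / (8 * d**5)
        assert oracle == pytest.approx(far, rel=0.01)


class TestTotalAndProbability:
    def test_additivity(self, lysozyme, cond_ph2):
        cond = cond_ph2.with_internal(0.0195)
        ip = pp.InteractionParams.from_bare_charge(3.0, lysozyme.D, cond)
        for x_over_D in (1.5, 3.0, 5.4, 10.0):
            x = x_over_D * lysozyme.D
            for theta in (0.0, 90.0):
                tot = pp.total_pair_potential(x, theta, lysozyme, ip, cond)
                el = pp.electrostatic_pair(x, theta, lysozyme.L, ip, cond)
                vdw = pp.vdw_pair(x, theta, lysozyme.D, lysozyme.L, ip.A_H)
                assert tot == el + vdw

    def test_decays_at_large_separation(self, lysozyme, cond_ph2):
        cond = cond_ph2.with_internal(0.0195)
        ip = pp.InteractionParams.from_bare_charge(3.0, lysozyme.D, cond)
        for theta in (0.0, 90.0):
            # the power-law vdW tail decays slowest; micron-scale separation
            assert abs(pp.total_pair_potential(5000.0, theta, lysozyme, ip, cond)) < 1e-3

    def test_probability_reference_points(self):
        assert pp.relative_probability(1.0, 1.0) == 1.0
        assert pp.relative_probability(math.log(100.0), 0.0) == pytest.approx(0.01)
        assert pp.relative_probability(0.0, 1.0) > 1.0


class TestNematicSpacing:
    @pytest.fixture
    def state(self, lysozyme):
        cond = SolutionConditions(pH=3.0).with_internal(0.002)
        ip = pp.InteractionParams.from_bare_charge(2.5, lysozyme.D, cond)
        return lysozyme, ip, cond

    def test_round_trip(self, state):
        geom, ip, cond = state
        lo, hi = pp.rising_branch_bracket(geom, ip, cond)
        x0 = 0.4 * lo + 0.6 * hi
        P0 = np.exp(
            -(
                pp.total_pair_potential(x0 * geom.D, 0.0, geom, ip, cond)
                - pp.total_pair_potential(x0 * geom.D, 90.0, geom, ip, cond)
            )
        )
        x_sol = pp.solve_nematic_spacing(P0, geom, ip, cond, bracket=(lo, hi))
        assert x_sol == pytest.approx(x0, abs=1e-3)

    def test_spacing_grows_as_screening_weakens(self, lysozyme):
        xs = []
        for I in (2e-3, 1e-3):
            cond = SolutionConditions(pH=3.0, I_nom=I)
            ip = pp.InteractionParams.from_bare_charge(2.5, lysozyme.D, cond)
            lo, hi = pp.rising_branch_bracket(lysozyme, ip, cond)
            xs.append(pp.solve_nematic_spacing(0.012, lysozyme, ip, cond, bracket=(lo, hi)))
        assert xs[1] > xs[0]

    def test_unreachable_target_raises(self, state):
        geom, ip, cond = state
        lo, hi = pp.rising_branch_bracket(geom, ip, cond)
        with pytest.raises(pp.NoSpacingSolutionError):
            pp.solve_nematic_spacing(0.9999, geom, ip, cond, bracket=(lo, hi))
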