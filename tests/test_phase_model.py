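"""Charged-rod isotropic-nematic threshold theory and Donnan inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from fibrilphase import phase_model as pm
from fibrilphase.constants import EULER_GAMMA
from fibrilphase.electrolyte import SolutionConditions
from fibrilphase.geometry import FibrilGeometry


def k1_quadrature(z: float) -> float:
    """Independent oracle for K1 via the integral representation
    K1(z) = int_0^inf exp(-z cosh t) cosh t dt."""
    return quad(lambda t: math.exp(-z * math.cosh(t)) * math.cosh(t), 0, 30, limit=200)[0]


class TestElectrostaticAmplitude:
    def test_neutral_rod_is_zero(self):
        assert pm.electrostatic_amplitude(0.0, 0.7, 0.3, 3.9) == 0.0

    def test_lambda_squared_scaling(self):
        a1 = pm.electrostatic_amplitude(1.5, 0.7, 0.3, 3.9)
        a2 = pm.electrostatic_amplitude(3.0, 0.7, 0.3, 3.9)
        assert a2 == pytest.approx(4 * a1, rel=1e-14)

    def test_against_quadrature_oracle(self):
        # closed-form arithmetic with K1 evaluated by its integral representation
        lam, Q, kappa, D = 3.0, 0.7, 0.3, 3.9
        k1 = k1_quadrature(kappa * D / 2)
        expected = (
            8 * math.pi * lam**2 * Q * math.exp(-kappa * D) / (kappa**3 * D**2 * k1**2)
        )
        assert pm.electrostatic_amplitude(lam, Q, kappa, D) == pytest.approx(
            expected, rel=1e-8
        )

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            pm.electrostatic_amplitude(-1.0, 0.7, 0.3, 3.9)
        with pytest.raises(ValueError):
            pm.electrostatic_amplitude(1.0, 0.7, -0.3, 3.9)


class TestEffectiveDiameter:
    def test_bracket_root_gives_bare_diameter(self):
        A_root = math.exp(0.5 - EULER_GAMMA - math.log(2.0))
        assert pm.effective_diameter(3.9, 0.3, A_root) == pytest.approx(3.9, rel=1e-12)

    def test_clamp_below_bracket_root(self):
        A_root = math.exp(0.5 - EULER_GAMMA - math.log(2.0))
        assert pm.effective_diameter(3.9, 0.3, 0.5 * A_root) == 3.9

    def test_arithmetic_example(self):
        # D + kappa^-1 (ln A' + C_E + ln2 - 0.5) by direct hand arithmetic
        kappa = 1.0 / 3.05
        expected = 3.9 + 3.05 * (math.log(50.0) + EULER_GAMMA + math.log(2.0) - 0.5)
        assert pm.effective_diameter(3.9, kappa, 50.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_neutral_limit_returns_bare_diameter(self):
        assert pm.effective_diameter(3.9, 0.3, 0.0) == 3.9


class TestTwistingFactor:
    def test_unit_product(self):
        assert pm.twisting_factor(0.5, 2.0) == 1.0

    def test_reference_value(self):
        # kappa D_eff = 7.44 is the state at which 3.290/(1-0.75h) = 3.659
        h = pm.twisting_factor(1.0, 7.4367)
        assert h == pytest.approx(0.13447, abs=2e-4)
        assert pm.ONSAGER_B0 / (1 - 0.75 * h) == pytest.approx(3.659, rel=1e-3)

    def test_decreases_with_screening(self):
        assert pm.twisting_factor(0.6, 5.0) < pm.twisting_factor(0.3, 5.0)


class TestThresholdVolumeFraction:
    def test_hard_rod_onsager_limit(self, lysozyme):
        params = pm.ElectrostaticRodParams(
            A_prime=0.0, D_eff=lysozyme.D, h=0.0, prefactor=pm.ONSAGER_B0
        )
        pred = pm.threshold_volume_fraction(lysozyme, params)
        assert pred.phi_IN == pytest.approx(
            pm.ONSAGER_B0 * lysozyme.D / lysozyme.L, rel=1e-12
        )

    def test_monotone_in_effective_diameter(self, lysozyme):
        phis = []
        for d_eff in (5.0, 10.0, 20.0):
            params = pm.ElectrostaticRodParams(
                A_prime=1.0, D_eff=d_eff, h=0.1, prefactor=pm.ONSAGER_B0 / (1 - 0.075)
            )
            phis.append(pm.threshold_volume_fraction(lysozyme, params).phi_IN)
        assert phis[0] > phis[1] > phis[2]

    def test_increases_with_twist(self, lysozyme):
        mk = lambda h: pm.ElectrostaticRodParams(
            A_prime=1.0, D_eff=10.0, h=h, prefactor=pm.ONSAGER_B0 / (1 - 0.75 * h)
        )
        assert (
            pm.threshold_volume_fraction(lysozyme, mk(0.3)).phi_IN
            > pm.threshold_volume_fraction(lysozyme, mk(0.1)).phi_IN
        )

    def test_out_of_regime_twist_rejected(self, lysozyme):
        params = pm.ElectrostaticRodParams(A_prime=1.0, D_eff=1.0, h=1.5, prefactor=0.0)
        with pytest.raises(pm.OutOfRegimeError, match="twisting"):
            pm.threshold_volume_fraction(lysozyme, params)


class TestWeightConversion:
    def test_endpoints(self):
        assert pm.wt_from_volume_fraction(0.0) == 0.0
        assert pm.wt_from_volume_fraction(1.0) == 100.0

    def test_reference_value(self):
        # 100 * 0.013 / (0.013 + 0.99) = 1.29611...
        assert pm.wt_from_volume_fraction(0.01, 1.3, 1.0) == pytest.approx(
            1.2961, abs=1e-4
        )

    @settings(derandomize=True, max_examples=80)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_round_trip_identity(self, phi):
        c = pm.wt_from_volume_fraction(phi)
        assert pm.volume_fraction_from_wt(c) == pytest.approx(phi, abs=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.wt_from_volume_fraction(1.5)
        with pytest.raises(ValueError):
            pm.volume_fraction_from_wt(-0.1)


class TestPredictThreshold:
    def test_neutral_rod_reduces_to_hard_rod(self, lysozyme, cond_ph2):
        pred = pm.predict_threshold_concentration(lysozyme, 0.0, cond_ph2)
        # A'=0 -> D_eff=D, h=1/(kappa D): twist correction only
        h = 1.0 / (cond_ph2.kappa * lysozyme.D)
        expected_phi = pm.ONSAGER_B0 / (1 - 0.75 * h) * lysozyme.D / lysozyme.L
        assert pred.phi_IN == pytest.approx(expected_phi, rel=1e-12)

    def test_threshold_increases_with_internal_ionic_strength(self, lysozyme, cond_ph2):
        cs = [
            pm.predict_threshold_concentration(
                lysozyme, 3.0, cond_ph2.with_internal(I)
            ).c_IN
            for I in np.geomspace(0.01, 0.3, 8)
        ]
        assert all(b > a for a, b in zip(cs, cs[1:]))


class TestDonnanSolver:
    def test_round_trip_recovers_internal_ionic_strength(self, lysozyme, cond_ph2):
        I_true = 0.03
        c_obs = pm.predict_threshold_concentration(
            lysozyme, 3.0, cond_ph2.with_internal(I_true)
        ).c_IN
        I_sol = pm.solve_internal_ionic_strength(c_obs, lysozyme, 3.0, cond_ph2)
        assert I_sol == pytest.approx(I_true, rel=1e-6)

    def test_unreachably_low_threshold_raises(self, lysozyme, cond_ph2):
        with pytest.raises(pm.NoSolutionError, match="achievable"):
            pm.solve_internal_ionic_strength(1e-4, lysozyme, 3.0, cond_ph2)

    def test_solution_matches_observation_to_tolerance(self, lysozyme, cond_ph2):
        I = pm.solve_internal_ionic_strength(1.49, lysozyme, 3.0, cond_ph2)
        c = pm.predict_threshold_concentration(
            lysozyme, 3.0, cond_ph2.with_internal(I)
        ).c_IN
        assert abs(c - 1.49) / 1.49 < 1e-6


class TestClassifyRegime:
    def test_three_regimes(self):
        assert pm.classify_regime(3.0, 1.0, c_IN=1.5) == "isotropic"
        assert pm.classify_regime(3.0, 2.0, c_IN=1.5) == "LLCPS"
        assert pm.classify_regime(0.9, 2.0, c_IN=1.5) == "LLPS"


class TestPhaseDiagram:
    LYS_OBS = [
        (2.0, 1.49, 1.25),
        (3.0, 0.97, 0.90),
        (4.0, 0.90, 0.70),
        (5.0, 0.83, 0.70),
        (6.0, 0.68, 0.45),
        (7.0, 0.58, 0.45),
    ]

    @pytest.fixture
    def lam_of_pH(self):
        from fibrilphase.electrokinetics import smooth_charge_vs_pH

        return smooth_charge_vs_pH([(2.0, 3.0), (7.0, 1.17), (8.0, 1.0)])

    def test_single_row(self, lysozyme, lam_of_pH):
        obs = [pm.PhaseObservation(pH=2.0, c_mean=1.49, c_min=1.25)]
        df = pm.build_phase_diagram(obs, lam_of_pH, lysozyme)
        assert len(df) == 1
        row = df.iloc[0]
        assert row.status == "ok"
        for col in ("I_in_M", "D_eff_nm", "h", "prefactor", "c_IN_wt"):
            assert np.isfinite(row[col])

    def test_lysozyme_set_solves_with_monotone_internal_ionic_strength(
        self, lysozyme, lam_of_pH
    ):
        obs = [
            pm.PhaseObservation(pH=p, c_mean=c, c_min=m) for p, c, m in self.LYS_OBS
        ]
        df = pm.build_phase_diagram(obs, lam_of_pH, lysozyme)
        assert (df.status == "ok").all()
        # retained counterions wash out as pH rises toward lower charge
        assert np.all(np.diff(df.I_in_M.to_numpy()) < 0)
        assert (df.I_in_M >= df.I_nom_M).all()
        assert (df.regime_predicted == "LLCPS").all()

    def test_unsorted_observations_rejected(self, lysozyme, lam_of_pH):
        obs = [
            pm.PhaseObservation(pH=3.0, c_mean=0.97),
            pm.PhaseObservation(pH=2.0, c_mean=1.49),
        ]
        with pytest.raises(ValueError, match="sorted"):
            pm.build_phase_diagram(obs, lam_of_pH, lysozyme)
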