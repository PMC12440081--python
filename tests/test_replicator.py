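"""Replicator dynamics, sigma_m identities and deterministic regimes."""

import numpy as np
import pytest

from ecogames import (
    GameDecomposition,
    RegimeSpec,
    classify_regime_dynamics,
    deterministic_regime_coefficients,
    fitnesses,
    fixed_points,
    integrate,
    replicator_rhs,
    sigma,
    steady_state_equivalence,
)
from ecogames.replicator import SingularParameterError, solve_sigma_identity

from conftest import random_valid_decomposition

GRID = np.linspace(0.0, 1.0, 101)


class TestFitnesses:
    def test_no_interactions_frequency_independent(self):
        dec = GameDecomposition(s_m=0.2, alpha_wm=0.0, alpha_mw=0.0)
        for x in (0.0, 0.3, 1.0):
            f_w, f_m = fitnesses(dec, x)
            assert (f_w, f_m) == (1.0, pytest.approx(1.2))

    def test_matches_expected_payoff_form(self, standard_dec):
        # f_w = a(1-x)+bx and f_m = c(1-x)+dx of the composed matrix
        from ecogames import compose

        P = compose(standard_dec)
        for x in GRID[::10]:
            f_w, f_m = fitnesses(standard_dec, x)
            assert f_w == pytest.approx(P.a * (1 - x) + P.b * x, abs=1e-14)
            assert f_m == pytest.approx(P.c * (1 - x) + P.d * x, abs=1e-14)

    def test_pure_mutant_limit_returns_column_entries(self):
        dec = GameDecomposition(s_m=0.1, alpha_wm=0.2, alpha_mw=0.3)
        f_w, f_m = fitnesses(dec, 1.0)
        assert (f_w, f_m) == (pytest.approx(1.2), pytest.approx(1.1))

    def test_x_outside_simplex_rejected(self, standard_dec):
        with pytest.raises(ValueError):
            fitnesses(standard_dec, 1.5)


class TestSigma:
    def test_reduces_to_s_m_without_interactions(self):
        dec = GameDecomposition(s_m=0.17, alpha_wm=0.0, alpha_mw=0.0)
        assert np.allclose(sigma(dec, GRID), 0.17)

    def test_masking_pair_nullifies_selection_everywhere(self):
        dec = GameDecomposition(s_m=0.2, alpha_wm=0.2, alpha_mw=-0.2)
        assert np.max(np.abs(sigma(dec, GRID))) == 0.0

    def test_vanishes_at_interior_equilibrium(self, standard_dec):
        assert sigma(standard_dec, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_relative_fitness_identity(self):
        """sigma * f_w == f_m - f_w across 1000 random games and fractions."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            dec = random_valid_decomposition(rng)
            x = rng.uniform(0, 1)
            f_w, f_m = fitnesses(dec, x)
            assert abs(sigma(dec, x) * f_w - (f_m - f_w)) < 1e-12


class TestRhs:
    def test_boundaries_stationary(self, standard_dec):
        assert replicator_rhs(standard_dec, 0.0) == 0.0
        assert replicator_rhs(standard_dec, 1.0) == 0.0

    def test_masking_freezes_dynamics_on_grid(self):
        dec = GameDecomposition(s_m=0.3, alpha_wm=0.3, alpha_mw=-0.3)
        assert np.max(np.abs(replicator_rhs(dec, GRID))) == 0.0

    def test_logistic_value(self):
        dec = GameDecomposition(s_m=0.1, alpha_wm=0.0, alpha_mw=0.0)
        assert replicator_rhs(dec, 0.5) == pytest.approx(0.025, abs=1e-15)

    def test_velocity_is_selection_times_fitness(self, standard_dec):
        # dx/dt = x(1-x) sigma f_w: the time-rescaling factor is f_w
        for x in GRID[1:-1:7]:
            f_w, _ = fitnesses(standard_dec, x)
            assert replicator_rhs(standard_dec, x) == pytest.approx(
                x * (1 - x) * sigma(standard_dec, x) * f_w, abs=1e-14
            )


class TestFixedPoints:
    def test_selection_only_two_stationary_solutions(self):
        fps = fixed_points(GameDecomposition(s_m=0.1, alpha_wm=0.0, alpha_mw=0.0))
        assert len(fps.points) == 2
        labels = {p.x: p.stability for p in fps.points}
        assert labels == {0.0: "unstable", 1.0: "stable"}

    def test_negative_selection_flips_stability(self):
        fps = fixed_points(GameDecomposition(s_m=-0.1, alpha_wm=0.0, alpha_mw=0.0))
        labels = {p.x: p.stability for p in fps.points}
        assert labels == {0.0: "stable", 1.0: "unstable"}

    def test_interior_coexistence_point(self, standard_dec):
        fps = fixed_points(standard_dec)
        labels = {p.x: p.stability for p in fps.points}
        assert labels[0.0] == "unstable" and labels[1.0] == "unstable"
        x_int = [x for x in labels if 0 < x < 1]
        assert x_int == [pytest.approx(0.5, abs=1e-12)]
        assert labels[x_int[0]] == "stable"

    def test_interior_point_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            dec = random_valid_decomposition(rng)
            denom = dec.alpha_wm + dec.alpha_mw
            if denom == 0:
                continue
            x_star = (dec.s_m + dec.alpha_mw) / denom
            fps = fixed_points(dec)
            interior = [p.x for p in fps.points if 0 < p.x < 1]
            if 0 < x_star < 1:
                assert interior and interior[0] == pytest.approx(x_star, abs=1e-12)
            else:
                assert not interior

    def test_fully_neutral_is_degenerate(self):
        fps = fixed_points(GameDecomposition(0.0, 0.0, 0.0))
        assert fps.degenerate


class TestIntegrate:
    def test_constant_at_fixed_point(self, standard_dec):
        traj = integrate(standard_dec, 0.5, horizon=50)
        assert np.max(np.abs(traj.x - 0.5)) < 1e-9

    def test_logistic_closed_form(self):
        """No-interaction replicator equals the logistic sweep x0 e^{st}/(1-x0+x0 e^{st})."""
        s, x0 = 0.1, 0.01
        dec = GameDecomposition(s_m=s, alpha_wm=0.0, alpha_mw=0.0)
        traj = integrate(dec, x0, horizon=200)
        expected = x0 * np.exp(s * traj.times) / (1 - x0 + x0 * np.exp(s * traj.times))
        assert np.max(np.abs(traj.x - expected)) < 1e-6
        assert abs(traj.final - 1.0) < 1e-6

    def test_masking_trajectory_constant(self):
        dec = GameDecomposition(s_m=0.2, alpha_wm=0.2, alpha_mw=-0.2)
        traj = integrate(dec, 0.37, horizon=100)
        assert np.max(np.abs(traj.x - 0.37)) < 1e-12


class TestDeterministicRegimes:
    @pytest.mark.parametrize("s", [0.05, 0.1, 0.2, 0.3])
    @pytest.mark.parametrize("kind", ["maintenance", "masking", "mirroring", "mimicry"])
    def test_sigma_identity_on_grid(self, kind, s):
        """Regime pairs make sigma_m(x) equal the target identically (<= 1e-12)."""
        if kind == "mimicry":
            spec = RegimeSpec(kind, target=s)
            s_m, target = 0.0, s
        else:
            spec = RegimeSpec(kind)
            s_m = s
            target = {"maintenance": s, "masking": 0.0, "mirroring": -s}[kind]
        alpha_mw, alpha_wm = deterministic_regime_coefficients(spec, s_m)
        dec = GameDecomposition(s_m=s_m, alpha_wm=alpha_wm, alpha_mw=alpha_mw)
        assert np.max(np.abs(sigma(dec, GRID) - target)) <= 1e-12

    def test_known_coefficient_values(self):
        assert deterministic_regime_coefficients(RegimeSpec("maintenance"), 0.1) == (0.0, 0.0)
        amw, awm = deterministic_regime_coefficients(RegimeSpec("masking"), 0.3)
        assert (amw, awm) == (pytest.approx(-0.3), pytest.approx(0.3))
        amw, awm = deterministic_regime_coefficients(RegimeSpec("mirroring"), 0.2)
        assert (amw, awm) == (pytest.approx(-0.4), pytest.approx(0.5))
        amw, awm = deterministic_regime_coefficients(RegimeSpec("mimicry", target=0.1), 0.0)
        assert (amw, awm) == (pytest.approx(0.1), pytest.approx(-0.1 / 1.1))

    def test_singular_parameters_raise(self):
        with pytest.raises(SingularParameterError):
            deterministic_regime_coefficients(RegimeSpec("mirroring"), 1.0)
        with pytest.raises(SingularParameterError):
            solve_sigma_identity(0.0, -1.0)

    def test_mimicry_requires_zero_s_m(self):
        with pytest.raises(ValueError):
            deterministic_regime_coefficients(RegimeSpec("mimicry", target=0.1), 0.2)

    def test_time_rescaled_equivalence(self):
        """Interacting regime velocity / f_w equals the non-interacting velocity."""
        s = 0.2
        for kind, target in [("masking", 0.0), ("mirroring", -s), ("maintenance", s)]:
            amw, awm = deterministic_regime_coefficients(RegimeSpec(kind), s)
            dec = GameDecomposition(s_m=s, alpha_wm=awm, alpha_mw=amw)
            for x in GRID[1:-1:5]:
                f_w, _ = fitnesses(dec, x)
                rescaled = replicator_rhs(dec, x) / f_w
                assert rescaled == pytest.approx(x * (1 - x) * target, abs=1e-13)

    def test_no_time_rescaling_when_alpha_wm_zero(self):
        # f_w == 1 when alpha_wm = 0, so the interacting velocity already
        # equals the sigma-equivalent non-interacting one pointwise in time
        rng = np.random.default_rng(3)
        for _ in range(50):
            dec = random_valid_decomposition(rng)
            dec0 = GameDecomposition(s_m=dec.s_m, alpha_wm=0.0, alpha_mw=dec.alpha_mw)
            for x in (0.2, 0.5, 0.8):
                assert replicator_rhs(dec0, x) == pytest.approx(
                    x * (1 - x) * sigma(dec0, x), abs=1e-14
                )


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [
            ((0.2, 0.2, -0.2), "masking"),
            ((0.2, 0.5, -0.4), "mirroring"),
            ((0.2, 0.0, 0.0), "maintenance"),
            ((0.0, -0.1 / 1.1, 0.1), "mimicry"),
            ((0.2, 0.3, 0.1), None),
        ],
    )
    def test_labels(self, coeffs, expected):
        s, awm, amw = coeffs
        dec = GameDecomposition(s_m=s, alpha_wm=awm, alpha_mw=amw)
        assert classify_regime_dynamics(dec, 0.2, tol=1e-9) == expected


class TestSteadyStateEquivalence:
    def test_alternate_masking_reaches_half(self, standard_dec):
        # family alpha_mw = alpha_wm - 2 s_m puts the stable point at 1/2
        assert standard_dec.alpha_mw == pytest.approx(standard_dec.alpha_wm - 2 * standard_dec.s_m)
        assert steady_state_equivalence(standard_dec, 0.1, 0.3) == "alternate-masking"

    def test_non_interacting_reference_is_maintenance(self):
        dec = GameDecomposition(s_m=0.1, alpha_wm=0.0, alpha_mw=0.0)
        assert steady_state_equivalence(dec, 0.1, 0.3) == "maintenance"

    def test_mirroring_outcome_inverted(self):
        dec = GameDecomposition(s_m=0.1, alpha_wm=0.3, alpha_mw=-0.2)
        # alpha_mw < -s_m and alpha_wm > s_m: wild-type wins despite s_m > 0
        assert steady_state_equivalence(dec, 0.1, 0.5) == "mirroring"

    def test_mimicry_fixation_without_selection(self):
        dec = GameDecomposition(s_m=0.0, alpha_wm=-0.1 / 1.1, alpha_mw=0.1)
        assert steady_state_equivalence(dec, 0.1, 0.3) == "mimicry"

    def test_degenerate_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            label = steady_state_equivalence(GameDecomposition(0, 0, 0), 0.1, 0.3)
        assert label == "none"
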