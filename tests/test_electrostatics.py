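"""Debye screening, Gouy-Chapman layer and the nonlinear PB gap solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectspec.electrostatics import (ConvergenceError, ElectrolyteSpec,
                                    debye_length, depletion_summary,
                                    gouy_chapman_potential, kTe_to_mV,
                                    solve_pb_gap)

WATER = dict(T=298.0, eps_r=78.5)


class TestDebye:
    def test_physiological_screening_length(self):
        assert debye_length(ElectrolyteSpec(c0=0.1, **WATER)) == \
            pytest.approx(0.96, abs=0.01)

    def test_buffer_concentration(self):
        assert debye_length(ElectrolyteSpec(c0=0.05, **WATER)) == \
            pytest.approx(1.36, abs=0.01)

    def test_textbook_constant(self):
        # kappa^-1 = 0.304 nm / sqrt(c[M]) in water at room temperature
        k = debye_length(ElectrolyteSpec(c0=1.0, **WATER))
        assert k == pytest.approx(0.304, rel=0.005)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(1e-3, 1.0))
    def test_inverse_square_root_scaling(self, c0):
        k1 = debye_length(ElectrolyteSpec(c0=c0, **WATER))
        k4 = debye_length(ElectrolyteSpec(c0=4 * c0, **WATER))
        assert k4 == pytest.approx(k1 / 2.0, rel=1e-12)

    def test_thermal_voltage(self):
        assert kTe_to_mV(298.0) == pytest.approx(25.7, abs=0.1)


class TestGouyChapman:
    def test_uncharged_wall_is_zero(self):
        spec = ElectrolyteSpec(c0=0.1, **WATER)
        z = np.linspace(0, 5, 50)
        np.testing.assert_array_equal(gouy_chapman_potential(0.0, spec, z), 0.0)

    def test_linearized_debye_limit(self):
        spec = ElectrolyteSpec(c0=0.1, **WATER)
        z = np.linspace(0, 3, 60)
        psi = gouy_chapman_potential(0.1, spec, z)
        lin = 0.1 * np.exp(-z / debye_length(spec))
        np.testing.assert_allclose(psi, lin, rtol=0.01)

    def test_strong_wall_direct_evaluation(self):
        spec = ElectrolyteSpec(c0=0.1, **WATER)
        kinv = debye_length(spec)
        got = gouy_chapman_potential(4.0, spec, np.array([kinv]))[0]
        assert got == pytest.approx(4 * np.arctanh(np.tanh(1.0) * np.exp(-1)),
                                    rel=1e-12)


@pytest.fixture(scope="module")
def buffer_spec():
    return ElectrolyteSpec(c0=0.05, **WATER)


class TestPBGap:
    def test_uncharged_walls_trivial_solution(self, buffer_spec):
        sol = solve_pb_gap(buffer_spec, 3.0, (0.0, 0.0), n_grid=201)
        np.testing.assert_allclose(sol.psi, 0.0, atol=1e-12)
        np.testing.assert_allclose(sol.c_plus, buffer_spec.c0, rtol=1e-12)

    def test_boltzmann_relation_pointwise(self, buffer_spec):
        sol = solve_pb_gap(buffer_spec, 3.0, (1.1, 1.1))
        np.testing.assert_allclose(sol.c_plus,
                                   buffer_spec.c0 * np.exp(-sol.psi), rtol=1e-9)
        np.testing.assert_allclose(sol.c_minus,
                                   buffer_spec.c0 * np.exp(sol.psi), rtol=1e-9)

    def test_superposition_limit_of_distant_walls(self, buffer_spec):
        kinv = debye_length(buffer_spec)
        sol = solve_pb_gap(buffer_spec, 20 * kinv, (1.1, 1.1), n_grid=4001)
        mid = sol.psi[sol.psi.size // 2]
        single = gouy_chapman_potential(1.1, buffer_spec,
                                        np.array([10 * kinv]))[0]
        assert mid == pytest.approx(2 * single, abs=1e-4)

    def test_single_wall_limit_matches_gouy_chapman(self, buffer_spec):
        kinv = debye_length(buffer_spec)
        sol = solve_pb_gap(buffer_spec, 20 * kinv, (2.0, 0.0), n_grid=4001)
        near = sol.z <= 5 * kinv
        analytic = gouy_chapman_potential(2.0, buffer_spec, sol.z[near])
        np.testing.assert_allclose(sol.psi[near], analytic, atol=1e-4)

    def test_linear_limit_matches_cosh_profile(self, buffer_spec):
        kinv = debye_length(buffer_spec)
        sol = solve_pb_gap(buffer_spec, 4.0, (0.05, 0.08))
        L, x = 4.0 / kinv, sol.z / kinv
        lin = (0.05 * np.sinh(L - x) + 0.08 * np.sinh(x)) / np.sinh(L)
        np.testing.assert_allclose(sol.psi, lin, atol=0.01 * 0.08)

    def test_second_order_grid_convergence(self, buffer_spec):
        a = solve_pb_gap(buffer_spec, 4.0, (1.0, 1.0), n_grid=1001)
        b = solve_pb_gap(buffer_spec, 4.0, (1.0, 1.0), n_grid=2001)
        assert abs(a.psi[500] - b.psi[1000]) < 1e-6

    def test_electroneutrality(self, buffer_spec):
        kinv = debye_length(buffer_spec)
        sol = solve_pb_gap(buffer_spec, 5.0, (2.0, -1.0), n_grid=4001)
        x = sol.z / kinv
        net_ionic = np.trapezoid(np.sinh(sol.psi), x)
        dpsi = np.gradient(sol.psi, x, edge_order=2)
        wall_charge = dpsi[-1] - dpsi[0]
        assert net_ionic == pytest.approx(wall_charge, rel=1e-3)

    def test_confined_gap_sustains_field_and_depletes_cations(self, buffer_spec):
        # 3 nm protein-protein gap in 50 mM buffer, walls at the +-1.1 kT/e
        # contour bound: the potential survives to mid-gap
        sol = solve_pb_gap(buffer_spec, 3.0, (1.1, 1.1))
        mid = sol.psi.size // 2
        assert sol.psi[mid] > 0.3
        assert sol.c_plus[mid] < buffer_spec.c0

    def test_strong_walls_converge_by_continuation(self, buffer_spec):
        sol = solve_pb_gap(buffer_spec, 5.0, (15.0, -10.0))
        assert sol.residual < 1e-8
        assert sol.psi[0] == 15.0 and sol.psi[-1] == -10.0

    def test_wall_potential_beyond_validated_range_rejected(self, buffer_spec):
        with pytest.raises(ValueError, match="validated range"):
            solve_pb_gap(buffer_spec, 3.0, (25.0, 0.0))


class TestDepletion:
    def test_trivial_solution_min_is_bulk(self, buffer_spec):
        sol = solve_pb_gap(buffer_spec, 3.0, (0.0, 0.0), n_grid=201)
        c_min, _ = depletion_summary(sol)
        assert c_min == pytest.approx(buffer_spec.c0)

    def test_symmetric_positive_walls_deplete_cations_at_walls(self, buffer_spec):
        sol = solve_pb_gap(buffer_spec, 3.0, (3.0, 3.0))
        c_min, z_min = depletion_summary(sol)
        assert c_min == pytest.approx(buffer_spec.c0 * np.exp(-3.0), rel=1e-9)
        assert z_min in (pytest.approx(0.0), pytest.approx(3.0))
        # anions accumulate where cations deplete
        assert sol.c_minus.max() == pytest.approx(buffer_spec.c0 * np.exp(3.0),
                                                  rel=1e-9)
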