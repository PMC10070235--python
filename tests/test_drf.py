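"""Discrete Reaction Field environment: tensors, induced dipoles, shifts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from excitonct.drf import (
    EnvironmentSite,
    env_potentials,
    interaction_tensor,
    le_difference_charges,
    response_coupling_correction,
    site_energy_shift,
    solve_induced_dipoles,
)
from excitonct.errors import InvalidParameterError, SingularityError
from excitonct.fragments import make_toy_fragment, make_transition_charges
from excitonct.units import HARTREE_TO_EV


def site(pos, q=0.0, alpha=0.0):
    return EnvironmentSite(position=np.asarray(pos, float), charge=q, alpha=alpha)


class TestInteractionTensor:
    def test_first_order_example(self):
        t1 = interaction_tensor([0, 0, 2.0], [0, 0, 0], 1)
        assert t1 == pytest.approx([0, 0, 0.25], abs=1e-15)

    def test_second_order_traceless(self, rng):
        for _ in range(5):
            R = rng.normal(size=3)
            assert np.trace(interaction_tensor(R, np.zeros(3), 2)) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_second_order_matches_finite_differences(self):
        """T2 = grad grad (1/R) by central differences to 1e-8."""
        p = np.array([1.3, -0.7, 2.1])
        q = np.array([-0.2, 0.4, 0.3])
        h = 1e-4
        num = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                def f(dp):
                    return interaction_tensor(p + dp, q, 0)
                ea, eb = np.eye(3)[a] * h, np.eye(3)[b] * h
                num[a, b] = (f(ea + eb) - f(ea - eb) - f(-ea + eb) + f(-ea - eb)) / (
                    4 * h * h
                )
        assert np.max(np.abs(num - interaction_tensor(p, q, 2))) < 1e-8

    def test_coincident_points_rejected(self):
        with pytest.raises(SingularityError):
            interaction_tensor([1, 1, 1], [1, 1, 1], 1)

    def test_bad_order(self):
        with pytest.raises(InvalidParameterError):
            interaction_tensor([0, 0, 1], [0, 0, 0], 3)


class TestInducedDipoles:
    def test_single_site_uniform_field(self):
        sol = solve_induced_dipoles(
            [site([0, 0, 0], alpha=1.0)], external_field=[0, 0, 0.01]
        )
        assert sol.dipoles[0] == pytest.approx([0, 0, 0.01], abs=1e-14)
        assert sol.residual < 1e-12

    def test_no_field_no_dipoles(self):
        sites = [site([0, 0, 0], alpha=1.0), site([0, 0, 3.0], alpha=2.0)]
        sol = solve_induced_dipoles(sites)
        assert np.allclose(sol.dipoles, 0.0)

    def test_direct_solve_equals_fixed_point_iteration(self, rng):
        """Direct linear solve vs 50-cycle Jacobi iteration to 1e-10."""
        sites = [
            site(rng.uniform(-5, 5, 3), q=rng.normal(0, 0.1), alpha=rng.uniform(0.5, 2))
            for _ in range(5)
        ]
        sol = solve_induced_dipoles(sites, damping="none")
        # independent fixed-point oracle
        from excitonct.drf import _permanent_field

        E0 = _permanent_field(sites, None, None, True)
        mu = np.zeros((5, 3))
        for _ in range(50):
            new = np.zeros_like(mu)
            for s in range(5):
                field = E0[s].copy()
                for t in range(5):
                    if t != s:
                        field += interaction_tensor(
                            sites[s].position, sites[t].position, 2
                        ) @ mu[t]
                new[s] = sites[s].alpha * field
            mu = new
        assert np.max(np.abs(mu - sol.dipoles)) < 1e-10

    def test_thole_damping_tames_close_contact(self):
        # alpha * 2/R^3 ~ 1.02: just past the undamped polarization catastrophe
        close = [site([0, 0, 0], alpha=8.0), site([0, 0, 2.5], alpha=8.0)]
        damped = solve_induced_dipoles(close, external_field=[0, 0, 0.01])
        assert np.all(np.isfinite(damped.dipoles))
        undamped = solve_induced_dipoles(
            close, external_field=[0, 0, 0.01], damping="none"
        )
        # undamped dipoles blow up relative to the damped solution
        assert np.max(np.abs(undamped.dipoles)) > 5 * np.max(np.abs(damped.dipoles))

    def test_induction_energy_nonpositive(self, rng):
        for _ in range(5):
            sites = [
                site(rng.uniform(-6, 6, 3), q=rng.normal(0, 0.2),
                     alpha=rng.uniform(0, 1.5))
                for _ in range(6)
            ]
            sol = solve_induced_dipoles(sites)
            assert sol.induction_energy <= 1e-12


class TestPotentials:
    def test_single_charge(self):
        v_el, v_pol = env_potentials([site([0, 0, 0], q=1.0)], None, [[0, 0, 2.0]])
        assert v_el[0] == pytest.approx(0.5)
        assert v_pol[0] == 0.0

    def test_dipole_on_axis(self):
        s = [site([0, 0, 0], alpha=1.0)]
        sol = solve_induced_dipoles(s, external_field=[0, 0, 1.0])
        v_el, v_pol = env_potentials(s, sol, [[0, 0, 2.0]])
        assert v_pol[0] == pytest.approx(0.25)

    def test_superposition(self):
        s1 = [site([0, 0, 0], q=0.5)]
        s2 = [site([0, 3, 0], q=-0.2)]
        both = s1 + s2
        pt = [[1.0, 1.0, 1.0]]
        v1 = env_potentials(s1, None, pt)[0][0]
        v2 = env_potentials(s2, None, pt)[0][0]
        v12 = env_potentials(both, None, pt)[0][0]
        assert v12 == pytest.approx(v1 + v2, abs=1e-14)

    def test_query_at_site_rejected(self):
        with pytest.raises(SingularityError):
            env_potentials([site([0, 0, 0], q=1.0)], None, [[0, 0, 0]])


class TestSiteEnergyShift:
    def test_zero_difference_charges(self):
        env = [site([0, 0, 5], q=0.5, alpha=1.0)]
        assert site_energy_shift([[0, 0, 0]], [0.0], env) == 0.0

    def test_stabilizing_sign(self):
        """Difference dipole pointing toward a positive charge stabilizes."""
        env = [site([0, 0, 5.0], q=0.5)]
        pos = [[0, 0, 0.5], [0, 0, -0.5]]
        dq = [-0.1, 0.1]  # negative end toward the positive charge
        assert site_energy_shift(pos, dq, env) < 0

    def test_linear_in_env_charge_without_polarizability(self):
        pos = [[0, 0, 0.5], [0, 0, -0.5]]
        dq = [0.1, -0.1]
        shifts = []
        for q in (0.2, 0.4):
            shifts.append(site_energy_shift(pos, dq, [site([0, 0, 4.0], q=q)]))
        assert shifts[1] == pytest.approx(2 * shifts[0], abs=1e-12)

    def test_le_difference_charges_sum_zero(self):
        frag = make_toy_fragment()
        _, dq = le_difference_charges(frag)
        assert dq.sum() == pytest.approx(0.0, abs=1e-10)


class TestResponseCorrection:
    def make_tq(self, center, axis):
        frag = make_toy_fragment(origin=center, axis=axis)
        return make_transition_charges(frag)

    def test_unpolarizable_environment_gives_zero(self):
        a = self.make_tq((0, 0, 0), (1, 0, 0))
        b = self.make_tq((0, 0, 10.0), (1, 0, 0))
        env = [site([3, 0, 5.0], q=0.4, alpha=0.0)]
        assert response_coupling_correction(a, b, env) == 0.0

    def test_reciprocity(self):
        a = self.make_tq((0, 0, 0), (1, 0, 0))
        b = self.make_tq((1, 1, 9.0), (0, 1, 0))
        env = [
            site([4, 0, 4.0], alpha=1.5),
            site([-3, 2, 6.0], alpha=0.8),
        ]
        vab = response_coupling_correction(a, b, env)
        vba = response_coupling_correction(b, a, env)
        assert abs(vab - vba) < 1e-10
        assert vab != 0.0

    def test_single_site_hand_contraction(self):
        """One polarizable site: dV = -(q_B T1) . alpha (T1 q_A), by hand."""
        a = self.make_tq((0, 0, 0), (1, 0, 0))
        b = self.make_tq((0, 0, 12.0), (1, 0, 0))
        alpha = 1.3
        spos = np.array([1.0, 2.0, 6.0])
        env = [site(spos, alpha=alpha)]
        field = sum(
            q * interaction_tensor(spos, r, 1) for r, q in zip(a.positions, a.charges)
        )
        mu = alpha * field
        expect = -sum(
            q * float(mu @ interaction_tensor(r, spos, 1))
            for r, q in zip(b.positions, b.charges)
        ) * HARTREE_TO_EV
        assert response_coupling_correction(a, b, env) == pytest.approx(
            expect, abs=1e-12
        )


def test_rigid_transformation_invariance(rng):
    """All environment quantities invariant under rotating env + QM together."""
    rot = Rotation.from_euler("xyz", [0.2, 0.9, -1.3]).as_matrix()
    shift = np.array([1.0, -2.0, 0.5])
    env = [
        site([3, 1, 4.0], q=0.3, alpha=1.2),
        site([-2, 2, 5.0], q=-0.1, alpha=0.7),
    ]
    pos = np.array([[0, 0, 0.5], [0, 0, -0.5]])
    dq = np.array([0.1, -0.1])
    s1 = site_energy_shift(pos, dq, env)
    env2 = [
        EnvironmentSite(position=rot @ s.position + shift, charge=s.charge,
                        alpha=s.alpha)
        for s in env
    ]
    s2 = site_energy_shift(pos @ rot.T + shift, dq, env2)
    assert s2 == pytest.approx(s1, abs=1e-10)
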