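"""Forces, drag, thermal noise, integration and boundary conditions."""

import math

import numpy as np
import pytest

from conftest import quiet_params
from lamelliflow import _layout as L
from lamelliflow import mechanics
from lamelliflow.errors import DomainError
from lamelliflow.fixtures import make_fixture
from lamelliflow.params import build_reference_config
from lamelliflow.state import SystemState


class TestDrag:
    def test_cylinder_formula(self):
        # zeta = 3 pi mu rc (3 + 2 r0/rc) / 5, evaluated by hand
        r0, rc, mu = 140e-9, 7e-9, 0.86
        expect = 3 * math.pi * 0.86 * 7e-9 * (3 + 2 * 140 / 7) / 5
        assert mechanics.drag_coefficient(r0, rc, mu) == \
            pytest.approx(expect, rel=1e-12)

    def test_linear_in_viscosity(self):
        z1 = mechanics.drag_coefficient(140e-9, 7e-9, 0.86)
        z2 = mechanics.drag_coefficient(140e-9, 7e-9, 1.72)
        assert z2 == pytest.approx(2 * z1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            mechanics.drag_coefficient(0.0, 7e-9, 0.86)
        with pytest.raises(DomainError):
            mechanics.drag_coefficient(140e-9, 7e-9, -1.0)


@pytest.mark.parametrize("name", ["single_filament", "branch_junction",
                                  "filament_plus_motor",
                                  "two_filaments_acp"])
def test_forces_match_finite_difference_of_energy(name):
    """Analytic forces equal the central finite difference of the total
    potential energy to 1e-6 relative tolerance on perturbed fixtures."""
    st = make_fixture(name, quiet_params())
    rng = np.random.default_rng(7)
    act = np.flatnonzero(st.active == 1)
    st.x[act] += rng.normal(0, 3e-9, (act.size, 3))
    F, _ = st.compute_forces(walls=False)
    h = 1e-12
    for p in act:
        for c in range(3):
            st.x[p, c] += h
            ep = mechanics.total_energy(st)
            st.x[p, c] -= 2 * h
            em = mechanics.total_energy(st)
            st.x[p, c] += h
            fd = -(ep - em) / (2 * h)
            scale = max(abs(fd), abs(F[p, c]))
            if scale > 1e-15:
                assert abs(fd - F[p, c]) / scale < 1e-6


def test_equilibrium_fixtures_are_force_free():
    for name in ("single_filament", "two_filaments_acp"):
        st = make_fixture(name, quiet_params())
        F, _ = st.compute_forces(walls=False)
        assert np.abs(F[st.active == 1]).max() < 1e-18


def test_stretched_segment_restoring_force():
    st = make_fixture("single_filament", quiet_params())
    pts = st.filament_points(int(st.filament_ids[0]))
    delta = 5e-9
    st.x[pts[-1], 1] += delta  # stretch the terminal bond by delta
    F, _ = st.compute_forces(walls=False)
    ks = st.P[L.P_KS_A]
    assert F[pts[-1], 1] == pytest.approx(-ks * delta, rel=1e-9)
    assert F[pts[-2], 1] == pytest.approx(ks * delta, rel=1e-9)


def test_action_reaction_internal_forces_sum_to_zero():
    st = make_fixture("branch_junction", quiet_params())
    rng = np.random.default_rng(3)
    act = np.flatnonzero(st.active == 1)
    st.x[act] += rng.normal(0, 5e-9, (act.size, 3))
    F, mF = st.compute_forces(walls=False)
    assert np.abs(F.sum(axis=0) + mF.sum(axis=0)).max() < 1e-20


class TestRepulsion:
    def _two_parallel(self, gap_nm):
        st = make_fixture("single_filament", quiet_params())
        lx, ly, _ = st.params.domain_size
        r0 = 0.14
        st.new_filament([[0.5 * lx + gap_nm * 1e-3, ly / 2 - r0 * 3 + i * r0,
                          0.05] for i in range(8)])
        return st

    def test_no_force_beyond_contact_distance(self):
        st = self._two_parallel(gap_nm=8.0)   # > 7 nm diameter
        F = mechanics.repulsive_forces(st)
        assert np.abs(F).max() == 0.0

    def test_overlapping_pair_harmonic_magnitude(self):
        st = self._two_parallel(gap_nm=3.5)   # rc/2
        F = mechanics.repulsive_forces(st)
        P = st.P
        total_x = np.abs(F[:, 0]).sum() / 2
        # per overlapping interior pair the magnitude is kr*(rc - d)
        per_pair = P[L.P_KR_A] * (P[L.P_RC_A] - 3.5e-9)
        assert total_x > 0.5 * per_pair
        assert F.sum(axis=0) == pytest.approx([0, 0, 0], abs=1e-22)

    def test_cell_list_finds_every_brute_force_pair(self):
        st = self._two_parallel(gap_nm=3.5)
        F_brute = mechanics.repulsive_forces(st)
        F_kernel, _ = st.compute_forces(walls=False)
        assert np.allclose(F_kernel, F_brute, rtol=1e-10, atol=1e-22)


class TestThermal:
    def test_moments_and_independence(self):
        st = make_fixture("single_filament", quiet_params())
        rng = np.random.default_rng(5)
        n = 10_000
        pts = st.filament_points(int(st.filament_ids[0]))[:2]
        draws = np.array([mechanics.thermal_forces(st, rng)[pts]
                          for _ in range(n)])
        p = st.params
        var_expect = 2 * p.kBT * st.zeta[pts[0]] / p.dt
        flat = draws[:, 0, :].ravel()
        assert abs(flat.mean()) < 4 * flat.std() / math.sqrt(flat.size)
        assert flat.var() == pytest.approx(var_expect, rel=0.05)
        corr = np.corrcoef(draws[:, 0, 0], draws[:, 1, 0])[0, 1]
        assert abs(corr) < 0.05

    def test_anchored_endpoints_receive_no_noise(self):
        st = make_fixture("filament_plus_motor", quiet_params())
        rng = np.random.default_rng(5)
        ft = mechanics.thermal_forces(st, rng)
        anchored = np.flatnonzero(st.anchored == 1)
        assert np.abs(ft[anchored]).max() == 0.0


class TestEuler:
    def test_zero_force_zero_noise_is_a_fixed_point(self):
        st = make_fixture("single_filament",
                          quiet_params(kBT=0.0))
        x0 = st.x.copy()
        st.advance(50, phase=1)
        assert np.array_equal(st.x, x0)

    def test_constant_force_closed_form(self):
        st = make_fixture("single_filament", quiet_params(kBT=0.0))
        pts = st.filament_points(int(st.filament_ids[0]))
        F = np.zeros_like(st.x)
        fmag = 1e-12
        F[pts[3], 0] = fmag
        x0 = st.x[pts[3], 0]
        mechanics.euler_step(st, F, st.params.dt)
        assert st.x[pts[3], 0] - x0 == pytest.approx(
            fmag * st.params.dt / st.zeta[pts[3]], rel=1e-12)

    def test_free_point_diffusion_matches_einstein_relation(self):
        """Mean-square displacement per component of free diffusing agents
        equals 2 (kBT/zeta) t within 10% (fluctuation-dissipation)."""
        params = quiet_params()
        st = SystemState(params, seed=11)
        rng = np.random.default_rng(2)
        for _ in range(200):
            st.new_acp([rng.uniform(1, 4), rng.uniform(0.75, 1.75), 0.05])
        pts = st.acp_pts[st.acp_state == 1, 0]
        lag = 1000
        nwin = 10
        msd = []
        prev = st.x[pts, :2].copy()
        for _ in range(nwin):
            st.advance(lag, phase=1)
            cur = st.x[pts, :2]
            d = cur - prev
            # unwrap periodic x
            lxm = st.P[L.P_LX]
            d[:, 0] = (d[:, 0] + lxm / 2) % lxm - lxm / 2
            msd.append((d ** 2).mean(axis=0))
            prev = cur.copy()
        msd = np.mean(msd, axis=0)
        t = lag * params.dt
        expect = 2 * params.kBT / st.zeta[pts[0]] * t
        assert msd[0] == pytest.approx(expect, rel=0.10)
        assert msd[1] == pytest.approx(expect, rel=0.10)


class TestBoundaries:
    def test_periodic_wrap_in_x(self):
        st = make_fixture("single_filament", quiet_params())
        pts = st.filament_points(int(st.filament_ids[0]))
        lx = st.P[L.P_LX]
        st.x[pts[0], 0] = lx + 0.1e-6
        mechanics.apply_boundaries(st)
        assert st.x[pts[0], 0] == pytest.approx(0.1e-6)

    def test_sticky_minus_y_anchors_actin(self):
        st = make_fixture("single_filament", quiet_params())
        pts = st.filament_points(int(st.filament_ids[0]))
        st.x[pts[0], 1] = -0.01e-6
        mechanics.apply_boundaries(st)
        assert st.anchored[pts[0]] == 1
        assert st.x[pts[0], 1] == 0.0

    def test_plus_y_wall_force_is_inward_and_harmonic(self):
        st = make_fixture("single_filament", quiet_params())
        pts = st.filament_points(int(st.filament_ids[0]))
        ly = st.P[L.P_LY]
        delta = 5e-9
        st.x[pts[-1], 1] = ly + delta
        F = st.compute_forces(walls=True)[0].copy()
        ks = st.P[L.P_K_WALL]
        assert F[pts[-1], 1] < 0
        # isolate the wall contribution via the no-wall evaluation
        Fn = st.compute_forces(walls=False)[0]
        assert F[pts[-1], 1] - Fn[pts[-1], 1] == pytest.approx(
            -ks * delta, rel=1e-9)

    def test_substrate_nodes_stay_in_plane(self):
        from lamelliflow.substrate import domain_mesh
        params = quiet_params(kBT=4.142e-21)
        st = SystemState(params, seed=3, mesh=domain_mesh(params))
        st.new_filament([[2.5, 1.0 + 0.14 * i, 0.05] for i in range(5)])
        st.advance(500, phase=1)
        assert np.abs(st.mx[:, 2]).max() == 0.0
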