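"""Substrate mesh elasticity and nascent-adhesion kinetics."""

import math

import numpy as np
import pytest

from conftest import quiet_params
from lamelliflow import _layout as L
from lamelliflow.errors import DomainError
from lamelliflow.params import build_reference_config
from lamelliflow.state import SystemState
from lamelliflow.substrate import (PROBE_PATCH_UM, build_mesh, domain_mesh,
                                   fa_unbind_rate, probe_effective_stiffness,
                                   total_substrate_force)


class TestMesh:
    def test_relaxed_mesh_geometry(self):
        mesh = build_mesh(1.0, 0.9, 0.05, periodic_x=False)
        d = mesh.nodes[mesh.edges[:, 1]] - mesh.nodes[mesh.edges[:, 0]]
        lens = np.linalg.norm(d, axis=1)
        assert lens.mean() == pytest.approx(50e-9, rel=1e-6)
        # interior angles of every triangle are 60 degrees
        a, b, c = (mesh.nodes[mesh.triangles[:, i]] for i in range(3))
        for (v, w1, w2) in ((a, b, c), (b, a, c), (c, a, b)):
            u1 = w1 - v
            u2 = w2 - v
            cosang = (u1 * u2).sum(axis=1) / (
                np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1))
            assert np.allclose(np.degrees(np.arccos(cosang)), 60, atol=1e-6)
        assert np.abs(mesh.nodes[:, 2]).max() == 0.0

    def test_periodic_mesh_spans_domain(self):
        params = build_reference_config()
        mesh = domain_mesh(params)
        assert mesh.periodic_x
        assert mesh.nodes[:, 0].max() < 5e-6
        assert mesh.pinned.sum() > 0

    def test_too_small_domain_rejected(self):
        with pytest.raises(DomainError):
            build_mesh(0.01, 0.01, 0.05, periodic_x=False)


class TestEffectiveStiffness:
    @pytest.fixture(scope="class")
    def ref_kappa(self):
        params = build_reference_config()
        mesh = build_mesh(*PROBE_PATCH_UM, 0.05, periodic_x=False)
        return probe_effective_stiffness(mesh, params)

    def test_reference_value(self, ref_kappa):
        # ~2.4e-4 N/m for the reference substrate parameters
        assert ref_kappa == pytest.approx(2.4e-4, rel=0.25)

    def test_stiffens_with_chain_stiffness(self, ref_kappa):
        params = build_reference_config(kappa_s_sub=2e-4)
        mesh = build_mesh(*PROBE_PATCH_UM, 0.05, periodic_x=False)
        assert probe_effective_stiffness(mesh, params) > ref_kappa

    def test_stiffens_with_angle_stiffness(self, ref_kappa):
        params = build_reference_config(kappa_b_sub=2.4e-19)
        mesh = build_mesh(*PROBE_PATCH_UM, 0.05, periodic_x=False)
        assert probe_effective_stiffness(mesh, params) > ref_kappa

    def test_softens_with_coarser_mesh(self, ref_kappa):
        # geometrically similar patch (same node count, doubled chains)
        params = build_reference_config(r0_sub=100.0)
        mesh = build_mesh(2 * PROBE_PATCH_UM[0], 2 * PROBE_PATCH_UM[1],
                          0.1, periodic_x=False)
        assert probe_effective_stiffness(mesh, params) < ref_kappa


class TestAdhesionRates:
    def test_compressed_link_ruptures_at_base_rate(self, ref_params):
        k = fa_unbind_rate(50.0, 0.05, 0.10, ref_params)
        assert k == pytest.approx(ref_params.k0_u_C)

    def test_zero_force_rate(self, ref_params):
        assert fa_unbind_rate(0.0, 0.2, 0.1, ref_params) == \
            pytest.approx(ref_params.k0_u_C)

    def test_slip_bond_force_ratio(self, ref_params):
        f1, f2 = 1.0, 3.0
        r1 = fa_unbind_rate(f1, 0.2, 0.1, ref_params)
        r2 = fa_unbind_rate(f2, 0.2, 0.1, ref_params)
        lam = ref_params.lambda_u_C * 1e-9
        expect = math.exp(lam * (f2 - f1) * 1e-12 / ref_params.kBT)
        assert r2 / r1 == pytest.approx(expect, rel=1e-9)


def _linked_state(n_links=200, ext_nm=10.0, **overrides):
    """Pinned mesh nodes linked to anchored actin endpoints at a fixed
    extension: rupture statistics at clamped force."""
    params = quiet_params(**overrides)
    st = SystemState(params, seed=17, mesh=domain_mesh(params))
    st.m_pinned[:] = 1
    rng = np.random.default_rng(3)
    nodes = rng.choice(np.flatnonzero(st.mx[:, 1] > 0.3e-6), n_links,
                       replace=False)
    r0 = 0.14
    made = []
    for i, n in enumerate(nodes):
        nx = st.mx[n] / 1e-6
        f = st.new_filament([[nx[0], nx[1], 0.05],
                             [nx[0], nx[1] + r0, 0.05]])
        pts = st.filament_points(f)
        for p in pts:
            st.anchored[p] = 1
        st.m_link[n] = pts[0]
        st.m_link_r0[n] = 0.05e-6 - ext_nm * 1e-9  # extension = ext_nm
        made.append(n)
    return st, params, np.array(made)


class TestAdhesionEngine:
    def test_rupture_frequency_matches_slip_bond(self):
        st, params, nodes = _linked_state(n_links=300, ext_nm=10.0,
                                          k0_u_C=2.0)
        force = params.kappa_s_C * 10e-9
        rate = params.k0_u_C * math.exp(
            params.lambda_u_C * 1e-9 * force / params.kBT)
        nsteps = 4000
        st.advance(nsteps, phase=1)
        events = int(st.ev[L.EV_FA_RUPTURE])
        p = 1 - math.exp(-rate * nsteps * params.dt)
        expect = 300 * p
        sigma = math.sqrt(300 * p * (1 - p))
        assert abs(events - expect) < 3 * sigma + 1

    def test_rest_length_never_changes_and_one_link_per_node(self):
        params = quiet_params(k_plus_C=200.0, k0_u_C=0.0)
        st = SystemState(params, seed=2, mesh=domain_mesh(params))
        iv = st.regions.intervals_um(params.domain_size[1], params.A_FA)
        y_fa = 0.5 * (iv["fa"][0] + iv["fa"][1])
        st.new_filament([[2.0 + 0.14 * i, y_fa, 0.03] for i in range(6)])
        st.advance(4000, phase=1)
        linked = np.flatnonzero(st.m_link >= 0)
        assert linked.size >= 1
        r0s = st.m_link_r0[linked].copy()
        st.advance(2000, phase=1)
        still = set(np.flatnonzero(st.m_link >= 0))
        assert set(linked) <= still              # no rupture at k0_u = 0
        assert np.array_equal(st.m_link_r0[linked], r0s)
        # formation distance respected
        assert (r0s <= 200e-9 + 1e-12).all()

    def test_formation_requires_capture_distance_and_fa_region(self):
        params = quiet_params(k_plus_C=200.0)
        st = SystemState(params, seed=2, mesh=domain_mesh(params))
        # filament far above the FA region and further than 200 nm in z
        st.new_filament([[2.0 + 0.14 * i, 2.3, 0.09] for i in range(6)])
        st.advance(3000, phase=1)
        assert int(st.ev[L.EV_FA_FORM]) == 0

    def test_new_link_is_born_force_free(self):
        params = quiet_params(k_plus_C=500.0, k0_u_C=0.0, kBT=0.0)
        st = SystemState(params, seed=4, mesh=domain_mesh(params))
        iv = st.regions.intervals_um(params.domain_size[1], params.A_FA)
        y_fa = 0.5 * (iv["fa"][0] + iv["fa"][1])
        st.new_filament([[2.0 + 0.14 * i, y_fa, 0.03] for i in range(6)])
        st.advance(200, phase=1)
        linked = np.flatnonzero(st.m_link >= 0)
        if linked.size:
            from lamelliflow.substrate import link_forces_pN
            # forces stay tiny right after formation (rest length = birth
            # length; only subsequent motion loads the spring)
            assert link_forces_pN(st).max() < 0.05


def test_total_substrate_force_sums_link_magnitudes():
    st, params, nodes = _linked_state(n_links=3, ext_nm=10.0)
    per = params.kappa_s_C * 10e-9 / 1e-12  # pN
    assert total_substrate_force(st) == pytest.approx(3 * per, rel=1e-6)
    st.m_link[:] = -1
    assert total_substrate_force(st) == 0.0
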