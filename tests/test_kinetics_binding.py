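"""Cross-linking and Arp2/3 branching."""

import math

import numpy as np
import pytest

from conftest import quiet_params
from lamelliflow import _layout as L
from lamelliflow import kinetics_binding as kb
from lamelliflow.fixtures import make_fixture
from lamelliflow.state import SystemState


def test_binding_site_lattice_spacing_is_7nm():
    st = make_fixture("single_filament", quiet_params())
    f = int(st.filament_ids[0])
    sites = kb.site_positions_um(st, f)
    d = np.linalg.norm(np.diff(sites, axis=0), axis=1)
    assert d == pytest.approx(np.full(d.size, 7e-3), rel=1e-9)
    # a 7-segment (0.98 um) filament hosts 141 lattice points incl. both ends
    assert sites.shape[0] == 7 * 20 + 1


class TestAcp:
    def test_bridge_forms_between_two_filaments(self):
        # thermal motion lets the second arm find the other filament
        params = quiet_params(k_plus_ACP=300.0)
        st = SystemState(params, seed=4)
        r0 = 0.14
        for y in (1.0, 1.025):
            f = st.new_filament([[1.0 + i * r0, y, 0.05] for i in range(5)])
            for p_ in st.filament_points(f):
                st.anchored[p_] = 1
        st.new_acp([1.3, 1.012, 0.05])
        st.advance(60_000, phase=0)
        assert int(st.ev[L.EV_ACP_BIND1]) == 1
        assert int(st.ev[L.EV_ACP_BIND2]) == 1
        assert kb.n_crosslinks(st) == 1
        a = int(np.flatnonzero(st.acp_state == 2)[0])
        f0 = st.filid[st.acp_seg[a, 0]]
        f1 = st.filid[st.acp_seg[a, 1]]
        assert f0 != f1  # second arm binds the *other* filament

    def test_second_arm_needs_a_second_filament(self):
        params = quiet_params(k_plus_ACP=300.0, kBT=0.0)
        st = SystemState(params, seed=4)
        st.new_filament([[1.0 + i * 0.14, 1.0, 0.05] for i in range(5)])
        st.new_acp([1.3, 1.012, 0.05])
        st.advance(20_000, phase=0)
        assert int(st.ev[L.EV_ACP_BIND1]) == 1
        assert kb.n_one_armed(st) == 1
        assert kb.n_crosslinks(st) == 0

    def test_crosslinks_are_permanent(self):
        st = make_fixture("two_filaments_acp", quiet_params())
        assert kb.n_crosslinks(st) == 1
        st.advance(5000, phase=1)
        assert kb.n_crosslinks(st) == 1

    def test_occupied_site_excludes_second_binder(self):
        st = make_fixture("two_filaments_acp", quiet_params())
        a = int(np.flatnonzero(st.acp_state == 2)[0])
        s, site = int(st.acp_seg[a, 0]), int(st.acp_site[a, 0])
        assert st.occ[s, site] != 0


class TestBranching:
    def _mother_plus_arp(self, **overrides):
        # a thick slab keeps out-of-plane branches away from the z walls
        params = quiet_params(k_plus_Arp=300.0, kBT=0.0,
                              domain_size=(5.0, 2.5, 1.0), **overrides)
        st = SystemState(params, seed=8)
        st.new_filament([[1.0, 1.0 + i * 0.14, 0.5] for i in range(5)])
        st.new_arp([1.02, 1.3, 0.5])
        return st

    def test_branch_created_at_70_degrees_toward_leading_edge(self):
        st = self._mother_plus_arp()
        st.advance(40_000, phase=0)
        assert int(st.ev[L.EV_BRANCH]) == 1
        angles = kb.branch_angles_deg(st)
        assert angles.size == 1
        assert angles[0] == pytest.approx(70.0, abs=0.5)
        r = int(np.flatnonzero(st.arp_state == 2)[0])
        g = int(st.arp_dfil[r])
        pts = st.filament_points(g)
        # barbed-end direction biased toward the leading edge (+y)
        assert st.x[pts[-1], 1] > st.x[pts[0], 1]

    def test_branch_consumes_a_pool_segment(self):
        st = self._mother_plus_arp()
        pool0 = st.pool_free
        st.advance(20_000, phase=0)
        assert st.pool_free == pool0 - 1
        assert st.actin_conserved()

    def test_pool_floor_blocks_branching(self):
        st = self._mother_plus_arp()
        # shrink the pool bookkeeping to the floor
        st.counts[L.C_POOL_TOTAL] = 10 + st.n_segments_in_filaments
        st.counts[L.C_POOL_FREE] = 1
        st.advance(10_000, phase=0)
        assert int(st.ev[L.EV_BRANCH]) == 0

    def test_junction_relaxes_to_equilibrium_angles(self):
        """Zero-temperature relaxation from a perturbed junction restores
        the 90/20/70-degree equilibria of the junction potentials."""
        st = make_fixture("branch_junction", quiet_params(kBT=0.0))
        rng = np.random.default_rng(12)
        r = int(np.flatnonzero(st.arp_state == 2)[0])
        movable = list(st.arp_pts[r]) + st.filament_points(
            int(st.arp_dfil[r]))
        for p in movable:
            st.x[p] += rng.normal(0, 4e-9, 3)
        # anchor the mother so relaxation moves the junction, not the frame
        for p in st.filament_points(0):
            st.anchored[p] = 1
        st.advance(60_000, phase=1)
        geo = kb.junction_geometry_deg(st, r)
        assert geo["mother_daughter"] == pytest.approx(70.0, abs=2.0)
        assert geo["body_mother"] == pytest.approx(90.0, abs=2.0)
        assert geo["body_daughter"] == pytest.approx(20.0, abs=2.0)

    def test_junction_counts_never_decrease_without_turnover(self):
        st = self._mother_plus_arp()
        st.advance(20_000, phase=0)
        n0 = kb.n_branch_junctions(st)
        st.advance(5_000, phase=0)
        assert kb.n_branch_junctions(st) >= n0


def test_agent_counts_conserved_through_engine_steps():
    params = quiet_params(k_plus_ACP=100.0, k_plus_Arp=100.0,
                          kBT=4.142e-21)
    st = SystemState(params, seed=3)
    for i in range(4):
        st.new_filament([[0.6 + 0.3 * i, 1.0 + 0.14 * j, 0.05]
                         for j in range(6)])
    for i in range(10):
        st.new_acp([0.5 + 0.35 * i, 1.2, 0.05])
        st.new_arp([0.5 + 0.35 * i, 1.5, 0.05])
    st.advance(5000, phase=0)
    assert int((st.acp_state > 0).sum()) == 10
    assert int((st.arp_state > 0).sum()) == 10
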