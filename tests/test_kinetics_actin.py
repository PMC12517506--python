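"""Filament turnover: nucleation, growth, shrinkage, severing, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from conftest import quiet_params
from lamelliflow import _layout as L
from lamelliflow.errors import DomainError
from lamelliflow.fixtures import make_fixture
from lamelliflow.kinetics_actin import severing_rate
from lamelliflow.state import SystemState


class TestSeveringRate:
    def test_zero_angle_rate_is_k0(self, ref_params):
        assert severing_rate(0.0, ref_params) == pytest.approx(1e-45)

    def test_printed_example_at_100_degrees(self, ref_params):
        # 1e-45 * e^100 ~ 2.69e-2 1/s
        assert severing_rate(100.0, ref_params) == \
            pytest.approx(1e-45 * math.exp(100.0), rel=1e-12)
        assert severing_rate(100.0, ref_params) == pytest.approx(2.69e-2,
                                                                 rel=1e-2)

    @given(a=st_h.floats(0.0, 179.0))
    @settings(max_examples=40, deadline=None)
    def test_strictly_increasing_in_angle(self, ref_params, a):
        assert severing_rate(a + 1.0, ref_params) > \
            severing_rate(a, ref_params)

    def test_angle_domain_enforced(self, ref_params):
        with pytest.raises(DomainError):
            severing_rate(-5.0, ref_params)
        with pytest.raises(DomainError):
            severing_rate(181.0, ref_params)


def _bare_state(params, n_fil=0, nseg=7, y0=1.0):
    st = SystemState(params, seed=9)
    r0 = params.r0_A * 1e-3
    for i in range(n_fil):
        x0 = 0.2 + (i * 0.11) % (params.domain_size[0] - 0.4)
        st.new_filament([[x0, y0 + j * r0, 0.05] for j in range(nseg + 1)])
    return st


class TestPolymerization:
    def test_capped_filament_never_grows(self):
        params = quiet_params(k_plus_A=12.0, kBT=0.0)
        st = _bare_state(params, n_fil=1, nseg=7, y0=1.5)
        st.advance(2000, phase=0)
        assert int(st.fil_n[st.filament_ids[0]]) == 7

    def test_region_gate_in_steady_phase(self):
        params = quiet_params(k_plus_A=12.0, kBT=0.0)
        st = _bare_state(params, n_fil=1, nseg=3, y0=1.0)  # barbed ~1.42 um
        st.advance(2000, phase=1)
        assert int(st.fil_n[st.filament_ids[0]]) == 3  # outside assembly band

    def test_pool_floor_blocks_consumption(self):
        params = quiet_params(k_plus_A=12.0, kBT=0.0)
        st = _bare_state(params, n_fil=1, nseg=3, y0=2.0)
        # barbed end inside the assembly band; clamp the pool at the floor
        st.counts[L.C_POOL_TOTAL] = 1000
        st.counts[L.C_POOL_FREE] = 100
        before = int(st.fil_n[st.filament_ids[0]])
        st.advance(2000, phase=1)
        assert int(st.fil_n[st.filament_ids[0]]) == before
        # one segment above the floor is consumable
        st.counts[L.C_POOL_FREE] = 101
        st.advance(8000, phase=1)
        assert int(st.fil_n[st.filament_ids[0]]) == before + 1

    def test_growth_is_collinear_and_barbed_only(self):
        params = quiet_params(k_plus_A=12.0, kBT=0.0)
        st = _bare_state(params, n_fil=1, nseg=2, y0=2.2)
        f = int(st.filament_ids[0])
        pointed0 = int(st.fil_pt[f])
        st.advance(4000, phase=0)
        assert int(st.fil_n[f]) > 2
        assert int(st.fil_pt[f]) == pointed0
        pts = st.filament_points(f)
        seg = np.diff(st.x[pts], axis=0)
        cos = (seg[:-1] * seg[1:]).sum(axis=1) / (
            np.linalg.norm(seg[:-1], axis=1) * np.linalg.norm(seg[1:], axis=1))
        assert cos.min() > 0.999


class TestDepolymerization:
    def test_rate_matches_monte_carlo(self):
        """Empirical pointed-end removal frequency equals k_minus_A within
        3 sigma binomial error (>= 1e4 Bernoulli trials)."""
        params = quiet_params(k_minus_A=6.0, kBT=0.0)
        st = _bare_state(params, n_fil=60, nseg=7, y0=0.05)  # in rear band
        nsteps = 2000
        st.advance(nsteps, phase=1)
        events = int(st.ev[L.EV_DEPOLY])
        p = -math.expm1(-6.0 * params.dt)
        trials = 60 * nsteps  # every live filament trials once per step
        expect = trials * p
        sigma = math.sqrt(trials * p * (1 - p))
        assert abs(events - expect) < 3 * sigma

    def test_region_gate(self):
        params = quiet_params(k_minus_A=6.0, kBT=0.0)
        st = _bare_state(params, n_fil=5, nseg=7, y0=1.5)
        st.advance(3000, phase=1)
        assert int(st.ev[L.EV_DEPOLY]) == 0

    def test_bound_motor_arm_released_not_destroyed(self):
        params = quiet_params(k_minus_A=50.0, kBT=0.0)
        st = _bare_state(params, n_fil=1, nseg=7, y0=0.01)
        f = int(st.filament_ids[0])
        m = st.new_motor([st.x[st.fil_pt[f], 0] / 1e-6, 0.05, 0.05])
        st.bind_motor_arm(m, 0, int(st.fil_pt[f]), 3)
        st.advance(3000, phase=0)
        assert st.ev[L.EV_DEPOLY] > 0
        assert st.mot_bound[m, 0] == -1      # lost that connection
        assert st.mot_state[m] in (1, 2)     # motor itself persists
        assert st.actin_conserved()


class TestSevering:
    def _bent_filaments(self, params, n, angle_deg):
        st = SystemState(params, seed=13)
        r0 = params.r0_A * 1e-3
        th = math.radians(180.0 - angle_deg)  # interior angle of the elbow
        lx, ly, _ = params.domain_size
        for i in range(n):
            x0 = 0.3 + (i * 0.37) % (lx - 0.6)
            y0 = 0.3 + (i * 0.11) % (ly - 1.0)
            a = [x0 - r0, y0, 0.05]
            b = [x0, y0, 0.05]
            c = [x0 + r0 * math.cos(math.pi - th), y0 + r0 * math.sin(
                math.pi - th), 0.05]
            d = [c[0] + (c[0] - b[0]), c[1] + (c[1] - b[1]), 0.05]
            st.new_filament([a, b, c, d])
        return st

    def test_straight_filaments_never_sever_at_reference_k0(self):
        params = quiet_params(k0_sev=1e-45, lambda_sev=1.0, kBT=0.0)
        st = _bare_state(params, n_fil=20, nseg=7, y0=1.0)
        st.advance(5000, phase=1)
        assert int(st.ev[L.EV_SEVER]) == 0

    def test_bent_joint_rate_matches_monte_carlo(self):
        """Severing frequency at a clamped 100-degree bend follows
        k0*exp(lambda*theta) within 3 sigma (kappa_b = 0 keeps the angle)."""
        k0 = 5.0 * math.exp(-100.0)
        params = quiet_params(k0_sev=k0, lambda_sev=1.0, kBT=0.0,
                              kappa_b_A=0.0, kappa_s_A=0.0)
        n = 400
        st = self._bent_filaments(params, n, angle_deg=100.0)
        nsteps = 5000
        st.advance(nsteps, phase=1)
        events = int(st.ev[L.EV_SEVER])
        k = 5.0  # rate at the bent joint; straight joints are negligible
        p = -math.expm1(-k * params.dt)
        # each filament can sever at most once (fragments are too short)
        expect = n * (1 - (1 - p) ** nsteps)
        sigma = math.sqrt(n * (expect / n) * (1 - expect / n))
        assert abs(events - expect) < 3 * sigma + 1

    def test_split_bookkeeping_and_conservation(self):
        k0 = 50.0 * math.exp(-100.0)
        params = quiet_params(k0_sev=k0, lambda_sev=1.0, kBT=0.0,
                              kappa_b_A=0.0, kappa_s_A=0.0)
        st = self._bent_filaments(params, 30, angle_deg=100.0)
        total_before = st.n_segments_in_filaments
        pool_before = st.pool_free
        st.advance(4000, phase=1)
        ev = int(st.ev[L.EV_SEVER])
        assert ev > 0
        assert st.pool_free == pool_before + ev
        assert st.n_segments_in_filaments == total_before - ev
        assert st.actin_conserved()
        # fragments keep a consistent chain structure
        for f in st.filament_ids:
            pts = st.filament_points(int(f))
            assert len(pts) == int(st.fil_n[f]) + 1

    def test_never_severs_short_filaments(self):
        k0 = 100.0 * math.exp(-100.0)
        params = quiet_params(k0_sev=k0, lambda_sev=1.0, kBT=0.0,
                              kappa_b_A=0.0, kappa_s_A=0.0)
        st = SystemState(params, seed=5)
        r0 = params.r0_A * 1e-3
        # two-segment elbow at a sharp angle: below the 3-segment minimum
        st.new_filament([[1.0, 1.0, 0.05], [1.0 + r0, 1.0, 0.05],
                         [1.0 + r0, 1.0 + r0, 0.05]])
        st.advance(4000, phase=1)
        assert int(st.ev[L.EV_SEVER]) == 0


class TestNucleation:
    def test_zero_rate_means_no_filaments(self):
        params = quiet_params(k_n_A=0.0)
        st = SystemState(params, seed=1)
        st.advance(2000, phase=1)
        assert st.filament_ids.size == 0

    def test_new_segments_lie_in_the_substrate_plane(self):
        params = quiet_params(k_n_A=2000.0, kBT=0.0)
        st = SystemState(params, seed=1)
        st.advance(2000, phase=1)
        assert st.filament_ids.size > 0
        for f in st.filament_ids:
            for p in st.filament_points(int(f)):
                assert st.x[p, 2] == 0.0

    def test_event_count_matches_rate(self):
        params = quiet_params(k_n_A=500.0, kBT=0.0)
        st = SystemState(params, seed=2)
        nsteps = 20_000
        st.advance(nsteps, phase=1)
        p = -math.expm1(-500.0 * params.dt)
        expect = nsteps * p
        sigma = math.sqrt(nsteps * p * (1 - p))
        assert abs(int(st.ev[L.EV_NUCLEATE]) - expect) < 3.5 * sigma


def test_conservation_across_mixed_kinetics():
    params = quiet_params(k_n_A=50.0, k_plus_A=12.0, k_minus_A=6.0,
                          kBT=4.142e-21)
    st = _bare_state(params, n_fil=20, nseg=4, y0=0.1)
    st.advance(5000, phase=0)
    assert st.actin_conserved()
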