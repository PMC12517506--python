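"""Motor mechanochemistry: calibration anchors, catch bond, walking."""

import math

import numpy as np
import pytest

from conftest import quiet_params
from lamelliflow import _layout as L
from lamelliflow.errors import DomainError
from lamelliflow.fixtures import make_fixture
from lamelliflow.motors import (motor_rates, rate_curve, simulate_arm_walk)
from lamelliflow.state import SystemState


class TestRateCurve:
    def test_unloaded_velocity_anchor(self, ref_params):
        kw, _ = motor_rates(0.0, 17.0, ref_params)
        assert kw * ref_params.site_spacing == pytest.approx(120.0,
                                                             rel=1e-9)

    def test_stall_anchor(self, ref_params):
        kw, _ = motor_rates(5.33, 17.0, ref_params)
        assert kw == 0.0
        curve = rate_curve(ref_params)
        assert curve.stall_force_pN() == pytest.approx(5.33, abs=0.02)

    def test_monotone_non_increasing_up_to_stall(self, ref_params):
        curve = rate_curve(ref_params)
        assert np.all(np.diff(curve.k_w) <= 1e-12)
        assert np.all(np.diff(curve.k_u) <= 1e-12)

    def test_catch_bond_regime(self, ref_params):
        _, ku0 = motor_rates(0.0, 17.0, ref_params)
        _, ku2 = motor_rates(2.0, 17.0, ref_params)
        assert ku2 < ku0

    def test_rates_grow_with_k20(self, ref_params):
        kw_lo, ku_lo = motor_rates(0.0, 2.0, ref_params)
        kw_hi, ku_hi = motor_rates(0.0, 17.0, ref_params)
        assert kw_lo < kw_hi
        assert ku_lo < ku_hi

    def test_negative_k20_rejected(self, ref_params):
        with pytest.raises(DomainError):
            motor_rates(0.0, -1.0, ref_params)

    def test_kernel_and_python_rates_agree(self, ref_params):
        from lamelliflow._kernels import motor_rate_pair
        from lamelliflow.params import pack_kernel_params
        P = pack_kernel_params(ref_params)
        for load in (0.0, 1.5, 3.0, 5.0, 5.33, 8.0):
            kw_py, ku_py = motor_rates(load, 17.0, ref_params)
            kw_k, ku_k = motor_rate_pair(load * 1e-12, P)
            assert kw_k == pytest.approx(kw_py, rel=1e-12)
            assert ku_k == pytest.approx(ku_py, rel=1e-12)


class TestStochasticWalking:
    def test_ten_second_unloaded_run_hits_120_nm_s(self, ref_params):
        """Single bound arms walking 10 s at zero load: ensemble mean
        velocity within 10% of the 120 nm/s anchor (seeded)."""
        vs = [simulate_arm_walk(ref_params, duration=10.0, seed=s)
              for s in range(16)]
        assert np.mean(vs) == pytest.approx(120.0, rel=0.10)

    def test_stalled_arm_does_not_advance(self, ref_params):
        v = simulate_arm_walk(ref_params, duration=5.0, seed=1,
                              load_pN=5.4)
        assert v == 0.0

    def test_binding_propensity_is_40_per_head(self, ref_params):
        assert ref_params.motor_bind_per_head * ref_params.N_h == \
            pytest.approx(160.0)

    def test_empirical_unbinding_frequency(self):
        """An ensemble of bound arms at clamped zero load unbinds at k_u(0)
        within 3 sigma (binding off, so each arm releases at most once)."""
        params = quiet_params(kBT=0.0)
        st = SystemState(params, seed=21)
        r0 = 0.14
        n_mot = 17
        fils = []
        for i in range(n_mot):
            y = 0.3 + 0.1 * i
            f = st.new_filament([[1.0 + j * r0, y, 0.05] for j in range(8)])
            for p in st.filament_points(f):
                st.anchored[p] = 1
            fils.append(f)
        arms = 0
        for i, f in enumerate(fils):
            m = st.new_motor([1.5, 0.3 + 0.1 * i - 0.01, 0.05])
            for p in st.mot_pts[m]:
                st.anchored[p] = 1
            segs = st.filament_points(f)[:-1]
            for arm in range(8):
                # choose the lattice site right under each backbone point so
                # the longitudinal (load-bearing) extension is ~zero
                bx = st.x[st.mot_pts[m, arm], 0] / 1e-6
                g = int(round((bx - 1.0) / 7e-3))
                st.bind_motor_arm(m, arm, int(segs[g // 20]), g % 20)
                arms += 1
        _, ku = motor_rates(0.0, params.k20, params)
        nsteps = 2000
        st.advance(nsteps, phase=0)   # walking off; unbinding active
        events = int(st.ev[L.EV_MOT_UNBIND])
        p_tot = 1.0 - math.exp(-ku * nsteps * params.dt)
        expect = arms * p_tot
        sigma = math.sqrt(arms * p_tot * (1 - p_tot))
        assert abs(events - expect) < 3 * sigma


class TestEngineWalking:
    def test_arm_advances_toward_barbed_end_and_respects_exclusion(self):
        # suppress unbinding (k20 = k10 = 0) so the single arm only walks
        params = quiet_params(kBT=0.0, k20=0.0, k10_M=0.0, k21_M=30.0)
        st = make_fixture("filament_plus_motor", params)
        m = 0
        f = int(st.filament_ids[0])
        for p in st.mot_pts[m]:
            st.anchored[p] = 1  # backbone clamp: pure kinetic walk
        start = int(st.mot_site[m, 0])
        st.advance(60_000, phase=1)
        s = int(st.mot_bound[m, 0])
        site = int(st.mot_site[m, 0])
        assert st.ev[L.EV_MOT_WALK] > 0
        # polarity: the occupied lattice position moved barbed-ward
        pts = st.filament_points(f)
        assert pts.index(s) * 20 + site > start
        # occupancy bookkeeping is consistent
        assert st.occ[s, site] == 3
        assert int(st.widx[s, site]) == m * 8 + 0

    def test_walking_disabled_during_assembly_phase(self):
        params = quiet_params(kBT=0.0)
        st = make_fixture("filament_plus_motor", params)
        for p in st.mot_pts[0]:
            st.anchored[p] = 1
        st.advance(3000, phase=0)
        assert int(st.ev[L.EV_MOT_WALK]) == 0

    def test_relocation_requires_all_arms_free_and_motor_region_actin(self):
        params = quiet_params(kBT=0.0)
        st = SystemState(params, seed=6)
        lx, ly, _ = params.domain_size
        # filament inside the motor region
        iv = st.regions.intervals_um(ly, params.A_FA)
        y_mot = 0.5 * (iv["motor"][0] + iv["motor"][1])
        st.new_filament([[1.0 + 0.14 * i, y_mot, 0.05] for i in range(5)])
        m = st.new_motor([3.0, 2.0, 0.05])  # far away, all arms free
        st.advance(50, phase=1)
        assert int(st.ev[L.EV_MOT_RELOC]) >= 1
        center_y = st.x[st.mot_pts[m], 1].mean() / 1e-6
        assert iv["motor"][0] - 0.05 <= center_y <= iv["motor"][1] + 0.05

    def test_no_actin_in_region_makes_motor_dormant(self):
        params = quiet_params(kBT=0.0)
        st = SystemState(params, seed=6)
        st.new_filament([[1.0 + 0.14 * i, 2.0, 0.05] for i in range(5)])
        m = st.new_motor([3.0, 2.0, 0.05])
        st.advance(50, phase=1)
        assert st.mot_state[m] == 2  # dormant, waiting for rear actin

    def test_bound_arm_holds_when_one_arm_remains(self):
        params = quiet_params(kBT=0.0)
        st = make_fixture("filament_plus_motor", params)
        st.advance(20, phase=0)
        # arm 0 bound => no relocation happened
        assert int(st.ev[L.EV_MOT_RELOC]) == 0
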