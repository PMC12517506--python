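"""Deterministic minimal states used across the test suite and examples."""

from __future__ import annotations

import math

import numpy as np

from . import _layout as L
from .errors import ConfigError
from .params import ParameterSet, build_reference_config
from .state import SystemState
from .substrate import build_mesh

FIXTURE_NAMES = ("single_filament", "filament_plus_motor", "branch_junction",
                 "mesh_patch", "two_filaments_acp")


def make_fixture(name: str, params: ParameterSet | None = None,
                 seed: int = 0) -> SystemState:
    """Build one of the named minimal configurations.

    single_filament     one straight 7-segment filament, nothing else
    filament_plus_motor straight anchored filament + motor, arm 0 bound
    branch_junction     mother + daughter joined at 70 deg by one Arp2/3
    mesh_patch          boundary-pinned substrate patch (no network)
    two_filaments_acp   two parallel filaments bridged by one cross-linker
    """
    if params is None:
        params = build_reference_config()
    if name == "single_filament":
        return _single_filament(params, seed)
    if name == "filament_plus_motor":
        return _filament_plus_motor(params, seed)
    if name == "branch_junction":
        return _branch_junction(params, seed)
    if name == "mesh_patch":
        state = SystemState(params, seed=seed,
                            mesh=build_mesh(1.0, 0.9, params.r0_sub * 1e-3,
                                            periodic_x=False))
        return state
    if name == "two_filaments_acp":
        return _two_filaments_acp(params, seed)
    raise ConfigError(f"unknown fixture {name!r}; "
                      f"choose from {FIXTURE_NAMES}")


def _single_filament(params, seed):
    state = SystemState(params, seed=seed)
    lx, ly, _ = params.domain_size
    r0 = params.r0_A * 1e-3
    n = params.max_segments_per_filament
    y0 = 0.5 * (ly - n * r0)
    coords = [[0.5 * lx, y0 + i * r0, 0.05] for i in range(n + 1)]
    state.new_filament(coords)
    return state


def _filament_plus_motor(params, seed):
    """Straight 7-segment filament along +x, both ends anchored, with a
    motor backbone alongside and arm 0 bound at the pointed-most site."""
    state = SystemState(params, seed=seed)
    lx, ly, _ = params.domain_size
    r0 = params.r0_A * 1e-3
    n = params.max_segments_per_filament
    y0 = 0.5 * ly
    x0 = 0.5 * (lx - n * r0)
    coords = [[x0 + i * r0, y0, 0.05] for i in range(n + 1)]
    f = state.new_filament(coords)
    state.anchored[state.fil_pt[f]] = 1
    state.anchored[state.fil_bb[f]] = 1
    m = state.new_motor([x0 + 0.15, y0 - params.r0_M1 * 1e-3, 0.05])
    state.bind_motor_arm(m, 0, int(state.fil_pt[f]), 0)
    return state


def _branch_junction(params, seed):
    state = SystemState(params, seed=seed)
    lx, ly, _ = params.domain_size
    r0 = params.r0_A * 1e-3
    ra = params.r0_Arp * 1e-3
    y0 = 0.4 * ly
    x0 = 0.5 * lx - r0
    # mother: two segments along +x; branch site mid first segment (site 10)
    f = state.new_filament([[x0 + i * r0, y0, 0.05] for i in range(3)])
    pts = state.filament_points(f)
    s = pts[0]
    site = 10
    sx = x0 + (site / L.SITES_PER_SEG) * r0
    th = math.radians(params.theta0_Arp_f)
    dvec = np.array([math.cos(th), math.sin(th), 0.0])
    # junction body normal to the mother, daughter pointed end at its tip
    c = state._alloc_point(np.array([sx, y0 + ra, 0.05]) * 1e-6,
                           state.P[L.P_ZETA_ARP])
    a1 = state._alloc_point(np.array([sx, y0, 0.05]) * 1e-6,
                            state.P[L.P_ZETA_ARP])
    a2 = state._alloc_point(np.array([sx, y0 + 2 * ra, 0.05]) * 1e-6,
                            state.P[L.P_ZETA_ARP])
    d0 = np.array([sx, y0 + 2 * ra, 0.05])
    g = state.new_filament([d0, d0 + r0 * dvec])
    r = int(np.flatnonzero(state.arp_state == 0)[0])
    state.arp_pts[r] = (c, a1, a2)
    state.arp_state[r] = 2
    state.arp_seg[r] = s
    state.arp_msite[r] = site
    state.arp_dfil[r] = g
    dp = int(state.fil_pt[g])
    state.arp_dpt[r] = dp
    state.pt_arp[dp] = r
    state.fil_parent[g] = r
    state.occ[s, site] = 2
    state.wkind[s, site] = 2
    state.widx[s, site] = r
    return state


def _two_filaments_acp(params, seed):
    state = SystemState(params, seed=seed)
    lx, ly, _ = params.domain_size
    r0 = params.r0_A * 1e-3
    gap = 2 * params.r0_ACP * 1e-3
    y0 = 0.5 * ly
    x0 = 0.5 * (lx - 3 * r0)
    f1 = state.new_filament([[x0 + i * r0, y0, 0.05] for i in range(4)])
    f2 = state.new_filament([[x0 + i * r0, y0 + gap, 0.05] for i in range(4)])
    s1 = state.filament_points(f1)[1]
    s2 = state.filament_points(f2)[1]
    site = 10
    sx = x0 + r0 + (site / L.SITES_PER_SEG) * r0
    a = int(np.flatnonzero(state.acp_state == 0)[0])
    a1 = state._alloc_point(np.array([sx, y0, 0.05]) * 1e-6,
                            state.P[L.P_ZETA_ACP])
    c = state._alloc_point(np.array([sx, y0 + 0.5 * gap, 0.05]) * 1e-6,
                           state.P[L.P_ZETA_ACP])
    a2 = state._alloc_point(np.array([sx, y0 + gap, 0.05]) * 1e-6,
                            state.P[L.P_ZETA_ACP])
    state.acp_pts[a] = (c, a1, a2)
    state.acp_state[a] = 2
    for arm, (s, ap) in enumerate(((s1, a1), (s2, a2))):
        state.acp_seg[a, arm] = s
        state.acp_site[a, arm] = site
        state.occ[s, site] = 1
        state.wkind[s, site] = 1
        state.widx[s, site] = a * 2 + arm
    return state
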