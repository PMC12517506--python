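"""Mechanics: drag, deterministic forces, thermal noise, Euler integration,
and boundary conditions.

The overdamped Langevin equation is integrated with a forward Euler scheme:
``r(t+dt) = r(t) + (F + F_T) dt / zeta`` per endpoint, where the stochastic
force has zero mean and per-component variance ``2 kBT zeta / dt`` (the
fluctuation-dissipation theorem constrains only these moments; a matched
uniform distribution is used for speed).  Segment drag follows the
approximated cylinder form ``zeta = 3 pi mu r_c (3 + 2 r0/rc) / 5``.

The fast path lives in the numba kernels; this module exposes the same
operations on :class:`~lamelliflow.state.SystemState` plus a plain-Python
total-energy reference used to verify every analytic gradient against
central finite differences.
"""

from __future__ import annotations

import math

import numpy as np

from . import _layout as L
from .errors import DomainError
from .state import SystemState


def drag_coefficient(segment_length: float, segment_diameter: float,
                     viscosity: float) -> float:
    """Drag of a cylindrical segment (SI): 3*pi*mu*rc*(3 + 2*r0/rc)/5.

    Motor backbones additionally multiply this by the configured
    ``motor_drag_multiplier`` (handled in parameter packing).
    """
    if segment_length <= 0 or segment_diameter <= 0 or viscosity <= 0:
        raise DomainError("drag_coefficient requires positive inputs")
    return 3.0 * math.pi * viscosity * segment_diameter * \
        (3.0 + 2.0 * segment_length / segment_diameter) / 5.0


def thermal_forces(state: SystemState, rng: np.random.Generator | None = None,
                   ) -> np.ndarray:
    """Sample a stochastic force field (N): independent per mobile endpoint
    and component, zero mean, variance 2*kBT*zeta/dt; anchored and inactive
    endpoints receive none."""
    if rng is None:
        rng = np.random.default_rng(state.seed)
    p = state.params
    n = state.x.shape[0]
    out = np.zeros((n, 3))
    mobile = (state.active == 1) & (state.anchored == 0)
    amp = np.sqrt(2.0 * p.kBT * state.zeta[mobile] / p.dt)
    draws = (rng.random((mobile.sum(), 3)) * 2.0 - 1.0) * math.sqrt(3.0)
    out[mobile] = amp[:, None] * draws
    return out


def euler_step(state: SystemState, forces: np.ndarray, dt: float,
               thermal: np.ndarray | None = None) -> None:
    """One explicit Euler update of the mobile endpoints, then boundaries."""
    mobile = (state.active == 1) & (state.anchored == 0)
    tot = forces if thermal is None else forces + thermal
    disp = tot[mobile] * dt / state.zeta[mobile][:, None]
    r0a = state.P[L.P_R0_A]
    if disp.size and np.max(np.einsum("ij,ij->i", disp, disp)) > (0.5 * r0a) ** 2:
        from .errors import InstabilityError
        raise InstabilityError("displacement exceeded half a segment length")
    state.x[mobile] += disp
    apply_boundaries(state)


def apply_boundaries(state: SystemState) -> None:
    """Periodic wrap in x; sticky anchoring of actin endpoints at the -y
    boundary.  (The repulsive +y and z walls act through forces.)"""
    lx = state.P[L.P_LX]
    act = state.active == 1
    state.x[act, 0] %= lx
    sticky = act & (state.filid >= 0) & (state.x[:, 1] <= 0.0) & \
        (state.anchored == 0)
    state.x[sticky, 1] = 0.0
    state.anchored[sticky] = 1


def potential_forces(state: SystemState) -> np.ndarray:
    """Deterministic internal forces (-grad U, N) on all endpoints: chain
    extension/bending, cross-linker and branch-junction terms (including the
    branch-plane torsion), motor backbone and two-spring arms, volume
    exclusion, and adhesion links.  Wall forces are excluded here."""
    F, _ = state.compute_forces(walls=False)
    return F.copy()


def repulsive_forces(state: SystemState) -> np.ndarray:
    """Brute-force volume-exclusion forces between actin segments (oracle
    implementation; the engine uses a cell/Verlet list)."""
    P = state.P
    rc = P[L.P_RC_A]
    kr = P[L.P_KR_A]
    lx = P[L.P_LX]
    F = np.zeros_like(state.x)
    segs = [p for p in np.flatnonzero(state.actin_point_mask())
            if state.nxt[p] >= 0]
    for i, p in enumerate(segs):
        q = int(state.nxt[p])
        for s2 in segs[i + 1:]:
            q2 = int(state.nxt[s2])
            if s2 == q or q2 == p:
                continue
            d, t, u, nvec = _segseg_py(state.x, p, q, s2, q2, lx)
            if 0.0 < d < rc:
                f = kr * (rc - d)
                F[p] -= f * nvec * (1 - t)
                F[q] -= f * nvec * t
                F[s2] += f * nvec * (1 - u)
                F[q2] += f * nvec * u
    return F


# ---------------------------------------------------------------------------
# plain-Python energy reference (finite-difference oracle target)
# ---------------------------------------------------------------------------

def _mi_vec(d, lx):
    d = d.copy()
    if d[0] > 0.5 * lx:
        d[0] -= lx
    elif d[0] < -0.5 * lx:
        d[0] += lx
    return d


def _vertex_angle(x, i, j, k, lx):
    u = _mi_vec(x[i] - x[j], lx)
    v = _mi_vec(x[k] - x[j], lx)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, max(-1.0, c)))


def _axis_angle(x, i, j, k, l, lx):
    u = _mi_vec(x[j] - x[i], lx)
    v = _mi_vec(x[l] - x[k], lx)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, max(-1.0, c)))


def _dihedral_dev(x, i, j, k, l, lx):
    b1 = _mi_vec(x[j] - x[i], lx)
    b2 = _mi_vec(x[k] - x[j], lx)
    b3 = _mi_vec(x[l] - x[k], lx)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-20 or np.linalg.norm(n2) < 1e-20:
        return 0.0
    phi = math.atan2(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2),
                     np.dot(n1, n2))
    return math.pi - abs(phi)


def _segseg_py(x, p1, p2, q1, q2, lx):
    d1 = _mi_vec(x[p2] - x[p1], lx)
    r = _mi_vec(x[q1] - x[p1], lx)
    d2 = _mi_vec(x[q2] - x[q1], lx)
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    b = float(np.dot(d1, d2))
    c = float(np.dot(d1, r))
    f = float(np.dot(d2, r))
    den = a * e - b * b
    t = (c * e - b * f) / den if den > 1e-30 else 0.0
    t = min(1.0, max(0.0, t))
    u = (b * t - f) / e if e > 1e-30 else 0.0
    u = min(1.0, max(0.0, u))
    if a > 1e-30:
        t = min(1.0, max(0.0, (b * u + c) / a))
    g = r + u * d2 - t * d1
    d = float(np.linalg.norm(g))
    n = g / d if d > 1e-15 else np.zeros(3)
    return d, t, u, n


def _site_pos(x, s, q, site, lx):
    fr = site / float(L.SITES_PER_SEG)
    return x[s] + fr * _mi_vec(x[q] - x[s], lx)


def total_energy(state: SystemState, walls: bool = False,
                 include_mesh: bool = False) -> float:
    """Total potential energy (J) mirroring every force term in the kernels;
    used as the independent target of the finite-difference force check."""
    P = state.P
    lx = P[L.P_LX]
    x = state.x
    E = 0.0
    # actin chains
    for p in np.flatnonzero(state.actin_point_mask()):
        q = int(state.nxt[p])
        if q >= 0:
            r = np.linalg.norm(_mi_vec(x[q] - x[p], lx))
            E += 0.5 * P[L.P_KS_A] * (r - P[L.P_R0_A]) ** 2
        pr = int(state.prv[p])
        if q >= 0 and pr >= 0:
            th = _vertex_angle(x, pr, p, q, lx)
            E += 0.5 * P[L.P_KB_A] * (th - math.pi) ** 2
    # cross-linkers
    for a in np.flatnonzero(state.acp_state == 2):
        c, a1, a2 = (int(v) for v in state.acp_pts[a])
        for arm_pt in (a1, a2):
            r = np.linalg.norm(_mi_vec(x[arm_pt] - x[c], lx))
            E += 0.5 * P[L.P_KS_ACP] * (r - P[L.P_R0_ACP]) ** 2
        E += 0.5 * P[L.P_KB_ACP] * (_vertex_angle(x, a1, c, a2, lx)
                                    - math.pi) ** 2
        for arm in range(2):
            s = int(state.acp_seg[a, arm])
            if s >= 0:
                sp = _site_pos(x, s, int(state.nxt[s]),
                               int(state.acp_site[a, arm]), lx)
                d = np.linalg.norm(_mi_vec(sp - x[(a1, a2)[arm]], lx))
                E += 0.5 * P[L.P_KL_BIND] * d ** 2
    # branch junctions
    for r_ in np.flatnonzero(state.arp_state == 2):
        c, a1, a2 = (int(v) for v in state.arp_pts[r_])
        for arm_pt in (a1, a2):
            rr = np.linalg.norm(_mi_vec(x[arm_pt] - x[c], lx))
            E += 0.5 * P[L.P_KS_ARP] * (rr - P[L.P_R0_ARP]) ** 2
        E += 0.5 * P[L.P_KB_ARP_C] * (_vertex_angle(x, a1, c, a2, lx)
                                      - math.pi) ** 2
        s = int(state.arp_seg[r_])
        dp = int(state.arp_dpt[r_])
        if s >= 0:
            mq = int(state.nxt[s])
            sp = _site_pos(x, s, mq, int(state.arp_msite[r_]), lx)
            E += 0.5 * P[L.P_KL_BIND] * np.linalg.norm(
                _mi_vec(sp - x[a1], lx)) ** 2
            E += 0.5 * P[L.P_KB_ARP_M] * (_axis_angle(x, s, mq, a1, c, lx)
                                          - P[L.P_TH_ARP_M]) ** 2
        if dp >= 0:
            E += 0.5 * P[L.P_KL_BIND] * np.linalg.norm(
                _mi_vec(x[dp] - x[a2], lx)) ** 2
            d1 = int(state.nxt[dp])
            if d1 >= 0:
                E += 0.5 * P[L.P_KB_ARP_D] * (
                    _axis_angle(x, c, a2, dp, d1, lx) - P[L.P_TH_ARP_D]) ** 2
                if s >= 0:
                    mq = int(state.nxt[s])
                    E += 0.5 * P[L.P_KB_ARP_F] * (
                        _axis_angle(x, s, mq, dp, d1, lx)
                        - P[L.P_TH_ARP_F]) ** 2
                    E += 0.5 * P[L.P_KT_ARP] * _dihedral_dev(
                        x, s, mq, dp, d1, lx) ** 2
    # motors
    for m in np.flatnonzero(state.mot_state == 1):
        pts = state.mot_pts[m]
        for i in range(7):
            rr = np.linalg.norm(_mi_vec(x[pts[i + 1]] - x[pts[i]], lx))
            E += 0.5 * P[L.P_KS_MB] * (rr - P[L.P_R0_MB]) ** 2
        for i in range(1, 7):
            E += 0.5 * P[L.P_KB_MB] * (
                _vertex_angle(x, pts[i - 1], pts[i], pts[i + 1], lx)
                - math.pi) ** 2
        for arm in range(8):
            s = int(state.mot_bound[m, arm])
            if s < 0:
                continue
            q = int(state.nxt[s])
            w = _mi_vec(x[q] - x[s], lx)
            t = w / np.linalg.norm(w)
            sp = _site_pos(x, s, q, int(state.mot_site[m, arm]), lx)
            d = _mi_vec(sp - x[pts[arm]], lx)
            dl = float(np.dot(d, t))
            rt = float(np.linalg.norm(d - dl * t))
            E += 0.5 * P[L.P_KS_M2] * dl ** 2
            E += 0.5 * P[L.P_KS_M1] * (rt - P[L.P_R0_M1]) ** 2
    # volume exclusion (brute force)
    segs = [p for p in np.flatnonzero(state.actin_point_mask())
            if state.nxt[p] >= 0]
    rc = P[L.P_RC_A]
    for i, p in enumerate(segs):
        q = int(state.nxt[p])
        for s2 in segs[i + 1:]:
            q2 = int(state.nxt[s2])
            if s2 == q or q2 == p:
                continue
            d, _, _, _ = _segseg_py(x, p, q, s2, q2, lx)
            if d < rc:
                E += 0.5 * P[L.P_KR_A] * (rc - d) ** 2
    # adhesion links
    for n in np.flatnonzero(state.m_link >= 0):
        pt = int(state.m_link[n])
        r = np.linalg.norm(_mi_vec(x[pt] - state.mx[n], lx))
        E += 0.5 * P[L.P_KS_C] * (r - state.m_link_r0[n]) ** 2
    # walls
    if walls:
        ly, lz = P[L.P_LY], P[L.P_LZ]
        kw = P[L.P_K_WALL]
        for p in np.flatnonzero((state.active == 1) & (state.anchored == 0)):
            y, z = x[p, 1], x[p, 2]
            if y > ly:
                E += 0.5 * kw * (y - ly) ** 2
            if y < 0.0 and state.filid[p] < 0:
                E += 0.5 * kw * y ** 2
            if z < 0.0:
                E += 0.5 * kw * z ** 2
            elif z > lz:
                E += 0.5 * kw * (z - lz) ** 2
    if include_mesh:
        E += mesh_energy(state)
    return E


def mesh_energy(state: SystemState) -> float:
    """Elastic energy of the substrate mesh (chains + angles)."""
    P = state.P
    lx = P[L.P_LX]
    mx = state.mx
    E = 0.0
    for e in range(state.m_edges.shape[0]):
        i, j = state.m_edges[e]
        r = np.linalg.norm(_mi_vec(mx[j] - mx[i], lx))
        E += 0.5 * P[L.P_KS_SUB] * (r - P[L.P_R0_SUB]) ** 2
    for t in range(state.m_tri.shape[0]):
        a, b, c = state.m_tri[t]
        for (v, w1, w2) in ((a, b, c), (b, a, c), (c, a, b)):
            th = _vertex_angle(mx, w1, v, w2, lx)
            E += 0.5 * P[L.P_KB_SUB] * (th - P[L.P_TH_SUB]) ** 2
    return E
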