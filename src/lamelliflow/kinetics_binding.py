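"""Cross-linker (ACP) binding and Arp2/3 side-branching.

Cross-linkers bind the 7-nm site lattice on F-actin one arm at a time at
rate ``k_plus_ACP`` (second arm must reach a *different* filament), and the
resulting cross-links are permanent.  Arp2/3 binds a site at ``k_plus_Arp``
and immediately nucleates a daughter filament at the characteristic 70-degree
branch angle with its barbed end biased toward the leading edge (+y);
mother and daughter connections are permanent for as long as the supporting
segments exist.  When a supporting segment depolymerizes or is severed away,
the bound protein loses that one connection and may rebind later.
"""

from __future__ import annotations

import math

import numpy as np

from . import _layout as L
from .state import SystemState


def site_positions_um(state: SystemState, f: int) -> np.ndarray:
    """Binding-site lattice of filament ``f``: positions every 7 nm along
    each 140-nm segment, pointed to barbed (um)."""
    pts = state.filament_points(f)
    lx = state.P[L.P_LX]
    rows = []
    for i in range(len(pts) - 1):
        a = state.x[pts[i]]
        d = state.x[pts[i + 1]] - a
        if d[0] > 0.5 * lx:
            d[0] -= lx
        elif d[0] < -0.5 * lx:
            d[0] += lx
        for s in range(L.SITES_PER_SEG):
            rows.append(a + (s / L.SITES_PER_SEG) * d)
    rows.append(state.x[pts[-1]])  # barbed terminus
    return np.asarray(rows) / 1e-6


def n_crosslinks(state: SystemState) -> int:
    """Number of bridging (two-armed) cross-links."""
    return int(np.sum((state.acp_seg[:, 0] >= 0) &
                      (state.acp_seg[:, 1] >= 0)))


def n_one_armed(state: SystemState) -> int:
    return int(np.sum((state.acp_state == 2) &
                      ((state.acp_seg[:, 0] >= 0) ^
                       (state.acp_seg[:, 1] >= 0))))


def n_branch_junctions(state: SystemState) -> int:
    """Junctions with both a live mother attachment and a daughter."""
    return int(np.sum((state.arp_seg >= 0) & (state.arp_dfil >= 0)))


def branch_angles_deg(state: SystemState) -> np.ndarray:
    """Mother-daughter axis angle (deg) of every complete junction."""
    lx = state.P[L.P_LX]
    out = []
    for r in np.flatnonzero((state.arp_seg >= 0) & (state.arp_dpt >= 0)):
        s = int(state.arp_seg[r])
        mq = int(state.nxt[s])
        dp = int(state.arp_dpt[r])
        d1 = int(state.nxt[dp])
        if mq < 0 or d1 < 0:
            continue
        u = state.x[mq] - state.x[s]
        v = state.x[d1] - state.x[dp]
        for w in (u, v):
            if w[0] > 0.5 * lx:
                w[0] -= lx
            elif w[0] < -0.5 * lx:
                w[0] += lx
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        out.append(math.degrees(math.acos(min(1.0, max(-1.0, c)))))
    return np.asarray(out)


def junction_geometry_deg(state: SystemState, r: int) -> dict:
    """The three restrained angles of junction ``r``: body-vs-mother,
    body-vs-daughter, mother-vs-daughter (deg)."""
    lx = state.P[L.P_LX]

    def ang(u, v):
        for w in (u, v):
            if w[0] > 0.5 * lx:
                w[0] -= lx
            elif w[0] < -0.5 * lx:
                w[0] += lx
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    s = int(state.arp_seg[r])
    mq = int(state.nxt[s])
    c_, a1, a2 = (int(v) for v in state.arp_pts[r])
    dp = int(state.arp_dpt[r])
    d1 = int(state.nxt[dp])
    mother = state.x[mq] - state.x[s]
    body1 = state.x[c_] - state.x[a1]
    daughter = state.x[d1] - state.x[dp]
    body2 = state.x[a2] - state.x[c_]
    return {
        "body_mother": ang(mother.copy(), body1),
        "body_daughter": ang(body2, daughter.copy()),
        "mother_daughter": ang(mother.copy(), daughter.copy()),
    }
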