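"""Numba kernels: force evaluation, stochastic kinetics, and the step loop.

Everything here operates on the flat arrays owned by
:class:`lamelliflow.state.SystemState`.  Geometry is SI (metres); x is
periodic, so every pair difference goes through the minimum-image helper.
The random stream is an explicit xorshift128+ state passed as a 2-element
uint64 array, which makes trajectories bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._layout import (
    C_ERROR, C_NFIL_FREE, C_NMOTSEG, C_NPAIRS, C_NPT_FREE, C_POOL_FREE,
    C_POOL_TOTAL, C_STEP,
    EV_ACP_BIND1, EV_ACP_BIND2, EV_BRANCH, EV_DEPOLY, EV_FA_FORM,
    EV_FA_RUPTURE, EV_MOT_BIND, EV_MOT_RELOC, EV_MOT_UNBIND, EV_MOT_WALK,
    EV_NUCLEATE, EV_POLY, EV_SEVER,
    P_ASM_HI, P_ASM_LO, P_BIND_M, P_CAP_ACP, P_CAP_ARP, P_CAP_C, P_CAP_M,
    P_DIS_HI, P_DIS_LO, P_DT, P_F_STALL, P_FA_HI, P_FA_LO, P_FLOOR,
    P_K0_SEV, P_K0U_C, P_K10, P_K12_0, P_K20, P_K21, P_KB_A, P_KB_ACP,
    P_KB_ARP_C, P_KB_ARP_D, P_KB_ARP_F, P_KB_ARP_M, P_KB_MB, P_KB_SUB,
    P_KBT, P_K_WALL, P_KL_BIND, P_KM_A, P_KN_A, P_KP_A, P_KP_ACP, P_KP_ARP,
    P_KP_C, P_KR_A, P_KS_A, P_KS_ACP, P_KS_ARP, P_KS_C, P_KS_M1, P_KS_M2,
    P_KS_MB, P_KS_SUB, P_KT_ARP, P_LAM_SEV, P_LAMU_C, P_LX, P_LY, P_LZ,
    P_MAX_DISP, P_MAX_NSEG, P_MOT_HI, P_MOT_LO, P_N_KIN, P_N_MESH,
    P_R0_A, P_R0_ACP, P_R0_ARP, P_R0_M1, P_R0_MB, P_R0_SUB, P_RC_A,
    P_REBUILD, P_SKIN, P_TH_ARP_D, P_TH_ARP_F, P_TH_ARP_M,
    P_TH_SUB, P_UM_PER_SEG, P_ZETA_ACP, P_ZETA_ARP,
    P_ZETA_MESH, P_F_SLIP,
    SITES_PER_SEG,
)

NB = {"cache": True, "fastmath": True}
NBI = {"cache": True, "fastmath": True, "inline": "always"}


# ---------------------------------------------------------------------------
# random stream (xorshift128+)
# ---------------------------------------------------------------------------

@njit(**NBI)
def _ru(rs):
    """Uniform double in [0, 1)."""
    s1 = rs[0]
    s0 = rs[1]
    rs[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    rs[1] = s1
    return np.float64((s0 + s1) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(**NBI)
def _rsym(rs):
    """Zero-mean, unit-variance uniform draw (range +-sqrt(3))."""
    return (2.0 * _ru(rs) - 1.0) * 1.7320508075688772


SQRT3 = 1.7320508075688772


def seed_rng_state(seed: int) -> np.ndarray:
    """Two nonzero 64-bit words from splitmix64 of the user seed."""
    out = np.empty(2, dtype=np.uint64)
    z = (int(seed) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    for i in range(2):
        z = (z + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
        w = z
        w = ((w ^ (w >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        w = ((w ^ (w >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        w ^= w >> 31
        out[i] = np.uint64(w if w != 0 else 0x1234567887654321)
    return out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

@njit(inline="always", **NB)
def _mi(dx, Lx):
    if dx > 0.5 * Lx:
        return dx - Lx
    if dx < -0.5 * Lx:
        return dx + Lx
    return dx


@njit(inline="always", **NB)
def _dvec(x, i, j, Lx):
    """x[j] - x[i] with minimum image in x."""
    return (_mi(x[j, 0] - x[i, 0], Lx), x[j, 1] - x[i, 1], x[j, 2] - x[i, 2])


@njit(**NBI)
def _spring(x, F, i, j, ks, r0, Lx):
    dx, dy, dz = _dvec(x, i, j, Lx)
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    if r < 1e-15:
        return
    c = ks * (r - r0) / r
    F[i, 0] += c * dx
    F[i, 1] += c * dy
    F[i, 2] += c * dz
    F[j, 0] -= c * dx
    F[j, 1] -= c * dy
    F[j, 2] -= c * dz


@njit(**NBI)
def _angle4(x, F, i, j, k, l, kb, th0, Lx):
    """Harmonic angle between vectors u = x[j]-x[i] and v = x[l]-x[k];
    returns the angle (rad)."""
    ux, uy, uz = _dvec(x, i, j, Lx)
    vx, vy, vz = _dvec(x, k, l, Lx)
    lu = math.sqrt(ux * ux + uy * uy + uz * uz)
    lv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if lu < 1e-15 or lv < 1e-15:
        return th0
    iu = 1.0 / lu
    iv = 1.0 / lv
    ux *= iu
    uy *= iu
    uz *= iu
    vx *= iv
    vy *= iv
    vz *= iv
    c = ux * vx + uy * vy + uz * vz
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th = math.acos(c)
    s = math.sqrt(max(1.0 - c * c, 1e-24))
    dth = th - th0
    # near-degenerate geometry (sin -> 0) with the restraint far from its
    # minimum would produce a diverging gradient; floor the sine there.
    # Near the minimum dth -> 0 keeps the ratio finite and the force exact.
    if s < 5e-2 and abs(dth) > 0.2:
        s = 5e-2
    coef = kb * dth
    # dtheta/du = (c*uhat - vhat) / (|u| sin)
    gux = (c * ux - vx) * iu / s
    guy = (c * uy - vy) * iu / s
    guz = (c * uz - vz) * iu / s
    gvx = (c * vx - ux) * iv / s
    gvy = (c * vy - uy) * iv / s
    gvz = (c * vz - uz) * iv / s
    # F = -dU/dx; u depends on i (-1) and j (+1), v on k (-1) and l (+1)
    F[i, 0] += coef * gux
    F[i, 1] += coef * guy
    F[i, 2] += coef * guz
    F[j, 0] -= coef * gux
    F[j, 1] -= coef * guy
    F[j, 2] -= coef * guz
    F[k, 0] += coef * gvx
    F[k, 1] += coef * gvy
    F[k, 2] += coef * gvz
    F[l, 0] -= coef * gvx
    F[l, 1] -= coef * gvy
    F[l, 2] -= coef * gvz
    return th


@njit(**NB)
def _angle3(x, F, i, j, k, kb, th0, Lx):
    """Vertex angle at j between (x[i]-x[j]) and (x[k]-x[j])."""
    return _angle4(x, F, j, i, j, k, kb, th0, Lx)


@njit(**NB)
def _dihedral_plane(x, F, i, j, k, l, kt, Lx):
    """Coplanarity restraint for the branch plane: harmonic in the deviation
    of the i-j-k-l dihedral from the straight (+-pi) configuration."""
    b1x, b1y, b1z = _dvec(x, i, j, Lx)
    b2x, b2y, b2z = _dvec(x, j, k, Lx)
    b3x, b3y, b3z = _dvec(x, k, l, Lx)
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    b1sq = b1x * b1x + b1y * b1y + b1z * b1z
    b3sq = b3x * b3x + b3y * b3y + b3z * b3z
    b2sq = b2x * b2x + b2y * b2y + b2z * b2z
    b2n = math.sqrt(b2sq)
    # the torsion is ill-conditioned when either bond pair is nearly
    # collinear (sin < 5%); skip the restraint there
    if b2n < 1e-15 or n1sq < 2.5e-3 * b1sq * b2sq or \
            n2sq < 2.5e-3 * b3sq * b2sq:
        return 0.0
    mx = n1y * n2z - n1z * n2y
    my = n1z * n2x - n1x * n2z
    mz = n1x * n2y - n1y * n2x
    sin_phi = (mx * b2x + my * b2y + mz * b2z) / b2n
    cos_phi = n1x * n2x + n1y * n2y + n1z * n2z
    phi = math.atan2(sin_phi, cos_phi)
    # deviation from the nearest of +-pi, signed so the gradient chain rule
    # picks up d(dev)/d(phi) = -sign(phi)
    dev = math.pi - abs(phi)
    dUdphi = kt * dev * (-1.0 if phi >= 0.0 else 1.0)
    # dphi/dxi = -(|b2|/|n1|^2) n1 ; dphi/dxl = +(|b2|/|n2|^2) n2 ;
    # middle atoms by the chain rule (verified against finite differences)
    ai = -b2n / n1sq
    al = b2n / n2sq
    gix = ai * n1x
    giy = ai * n1y
    giz = ai * n1z
    glx = al * n2x
    gly = al * n2y
    glz = al * n2z
    t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
    t2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
    gjx = (-t1 - 1.0) * gix + t2 * glx
    gjy = (-t1 - 1.0) * giy + t2 * gly
    gjz = (-t1 - 1.0) * giz + t2 * glz
    gkx = t1 * gix - (1.0 + t2) * glx
    gky = t1 * giy - (1.0 + t2) * gly
    gkz = t1 * giz - (1.0 + t2) * glz
    F[i, 0] -= dUdphi * gix
    F[i, 1] -= dUdphi * giy
    F[i, 2] -= dUdphi * giz
    F[j, 0] -= dUdphi * gjx
    F[j, 1] -= dUdphi * gjy
    F[j, 2] -= dUdphi * gjz
    F[k, 0] -= dUdphi * gkx
    F[k, 1] -= dUdphi * gky
    F[k, 2] -= dUdphi * gkz
    F[l, 0] -= dUdphi * glx
    F[l, 1] -= dUdphi * gly
    F[l, 2] -= dUdphi * glz
    return dev


@njit(**NBI)
def _site_frac(site):
    return site / float(SITES_PER_SEG)


@njit(**NBI)
def _site_link_force(x, F, arm, s, q, site, kl, Lx):
    """Zero-rest-length spring between an arm endpoint and the binding-site
    position on segment (s, q); lever-rule distribution to the endpoints."""
    fr = _site_frac(site)
    dx, dy, dz = _dvec(x, s, q, Lx)
    sx = x[s, 0] + fr * dx
    sy = x[s, 1] + fr * dy
    sz = x[s, 2] + fr * dz
    ex = _mi(sx - x[arm, 0], Lx)
    ey = sy - x[arm, 1]
    ez = sz - x[arm, 2]
    # force on arm = +kl * e (toward the site)
    F[arm, 0] += kl * ex
    F[arm, 1] += kl * ey
    F[arm, 2] += kl * ez
    F[s, 0] -= kl * ex * (1.0 - fr)
    F[s, 1] -= kl * ey * (1.0 - fr)
    F[s, 2] -= kl * ez * (1.0 - fr)
    F[q, 0] -= kl * ex * fr
    F[q, 1] -= kl * ey * fr
    F[q, 2] -= kl * ez * fr


@njit(**NB)
def _two_spring_force(x, F, b, s, q, site, k1, r01, k2, Lx):
    """Motor-arm two-spring attachment between backbone point b and the
    binding site on segment (s, q), with the exact gradient (including the
    tangent-rotation terms).  Returns the longitudinal extension d_l (m),
    positive when the site lies barbed-ward of the backbone point."""
    fr = _site_frac(site)
    wx, wy, wz = _dvec(x, s, q, Lx)
    Lw = math.sqrt(wx * wx + wy * wy + wz * wz)
    if Lw < 1e-15:
        return 0.0
    tx = wx / Lw
    ty = wy / Lw
    tz = wz / Lw
    sxp = x[s, 0] + fr * wx
    syp = x[s, 1] + fr * wy
    szp = x[s, 2] + fr * wz
    dx = _mi(sxp - x[b, 0], Lx)
    dy = syp - x[b, 1]
    dz = szp - x[b, 2]
    dl = dx * tx + dy * ty + dz * tz
    px = dx - dl * tx
    py = dy - dl * ty
    pz = dz - dl * tz
    rt = math.sqrt(px * px + py * py + pz * pz)
    # force on backbone point: -dU/db with d(d)/db = -I
    c2 = k2 * dl
    c1 = 0.0
    hx = hy = hz = 0.0
    if rt > 1e-15:
        c1 = k1 * (rt - r01)
        hx = px / rt
        hy = py / rt
        hz = pz / rt
    F[b, 0] += c2 * tx + c1 * hx
    F[b, 1] += c2 * ty + c1 * hy
    F[b, 2] += c2 * tz + c1 * hz
    # gradients wrt segment endpoints (see methods note):
    #   d dl/ds = (1-fr) t - p/L ;  d dl/dq = fr t + p/L
    #   d rt/ds = h ((1-fr) + dl/L) ; d rt/dq = h (fr - dl/L)
    a = dl / Lw
    gsx = c2 * ((1.0 - fr) * tx - px / Lw) + c1 * hx * ((1.0 - fr) + a)
    gsy = c2 * ((1.0 - fr) * ty - py / Lw) + c1 * hy * ((1.0 - fr) + a)
    gsz = c2 * ((1.0 - fr) * tz - pz / Lw) + c1 * hz * ((1.0 - fr) + a)
    gqx = c2 * (fr * tx + px / Lw) + c1 * hx * (fr - a)
    gqy = c2 * (fr * ty + py / Lw) + c1 * hy * (fr - a)
    gqz = c2 * (fr * tz + pz / Lw) + c1 * hz * (fr - a)
    F[s, 0] -= gsx
    F[s, 1] -= gsy
    F[s, 2] -= gsz
    F[q, 0] -= gqx
    F[q, 1] -= gqy
    F[q, 2] -= gqz
    return dl


@njit(**NBI)
def _segseg(x, p1, p2, q1, q2, Lx):
    """Closest approach of segments (p1,p2) and (q1,q2) with min-image x.
    Returns (dist, t, u, nx, ny, nz): parameters on P and Q and the unit
    vector from the closest point on P to the closest point on Q."""
    d1x, d1y, d1z = _dvec(x, p1, p2, Lx)
    # shift Q rigidly by the minimum image of (q1 - p1)
    rx = _mi(x[q1, 0] - x[p1, 0], Lx)
    ry = x[q1, 1] - x[p1, 1]
    rz = x[q1, 2] - x[p1, 2]
    d2x = _mi(x[q2, 0] - x[q1, 0], Lx)
    d2y = x[q2, 1] - x[q1, 1]
    d2z = x[q2, 2] - x[q1, 2]
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    b = d1x * d2x + d1y * d2y + d1z * d2z
    c = d1x * rx + d1y * ry + d1z * rz
    f = d2x * rx + d2y * ry + d2z * rz
    den = a * e - b * b
    if den > 1e-30:
        t = (c * e - b * f) / den
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    if e > 1e-30:
        u = (b * t - f) / e
    else:
        u = 0.0
    if u < 0.0:
        u = 0.0
    elif u > 1.0:
        u = 1.0
    if a > 1e-30:
        t = (b * u + c) / a
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    gx = rx + u * d2x - t * d1x
    gy = ry + u * d2y - t * d1y
    gz = rz + u * d2z - t * d1z
    d = math.sqrt(gx * gx + gy * gy + gz * gz)
    if d > 1e-15:
        return d, t, u, gx / d, gy / d, gz / d
    return d, t, u, 0.0, 0.0, 0.0


# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------

@njit(**NB)
def rebuild_lists(x, active, nxt, filid, P, counts, pairs, motsegs,
                  cl_head, cl_next, ncx, ncy):
    """Cell-list construction over actin segments, then (a) Verlet pair list
    for volume exclusion and (b) the motor-region segment roster."""
    Lx = P[P_LX]
    Ly = P[P_LY]
    csx = Lx / ncx
    csy = Ly / ncy
    cl_head[:] = -1
    NP = x.shape[0]
    for p in range(NP):
        if active[p] == 1 and filid[p] >= 0 and nxt[p] >= 0:
            q = nxt[p]
            mxp = x[p, 0] + 0.5 * _mi(x[q, 0] - x[p, 0], Lx)
            myp = 0.5 * (x[p, 1] + x[q, 1])
            ix = int(mxp / csx) % ncx
            if ix < 0:
                ix += ncx
            iy = int(myp / csy)
            if iy < 0:
                iy = 0
            elif iy >= ncy:
                iy = ncy - 1
            cell = iy * ncx + ix
            cl_next[p] = cl_head[cell]
            cl_head[cell] = p
    cut = P[P_RC_A] + P[P_SKIN]
    # a pair can only approach within `cut` if the midpoints are closer than
    # cut + half the two segment lengths; quick reject on that bound first
    midcut = cut + P[P_R0_A] * 1.2
    midcut2 = midcut * midcut
    npairs = 0
    nmot = 0
    cap = pairs.shape[0]
    mcap = motsegs.shape[0]
    midx = np.empty(NP)
    midy = np.empty(NP)
    midz = np.empty(NP)
    for p in range(NP):
        if not (active[p] == 1 and filid[p] >= 0 and nxt[p] >= 0):
            continue
        q = nxt[p]
        midx[p] = x[p, 0] + 0.5 * _mi(x[q, 0] - x[p, 0], Lx)
        midy[p] = 0.5 * (x[p, 1] + x[q, 1])
        midz[p] = 0.5 * (x[p, 2] + x[q, 2])
        if (x[p, 1] >= P[P_MOT_LO] and x[p, 1] < P[P_MOT_HI]) or \
           (x[q, 1] >= P[P_MOT_LO] and x[q, 1] < P[P_MOT_HI]):
            if nmot < mcap:
                motsegs[nmot] = p
                nmot += 1
    for p in range(NP):
        if not (active[p] == 1 and filid[p] >= 0 and nxt[p] >= 0):
            continue
        q = nxt[p]
        ix = int(midx[p] / csx) % ncx
        if ix < 0:
            ix += ncx
        iy = int(midy[p] / csy)
        if iy < 0:
            iy = 0
        elif iy >= ncy:
            iy = ncy - 1
        for dy in range(-1, 2):
            jy = iy + dy
            if jy < 0 or jy >= ncy:
                continue
            for dxc in range(-1, 2):
                jx = (ix + dxc) % ncx
                s2 = cl_head[jy * ncx + jx]
                while s2 >= 0:
                    if s2 > p:
                        q2 = nxt[s2]
                        # exclude segments sharing a point (chain neighbors)
                        if not (q2 == p or q == s2):
                            ddx = _mi(midx[s2] - midx[p], Lx)
                            ddy = midy[s2] - midy[p]
                            ddz = midz[s2] - midz[p]
                            if ddx * ddx + ddy * ddy + ddz * ddz < midcut2:
                                d, t, u, nx_, ny_, nz_ = _segseg(
                                    x, p, q, s2, q2, Lx)
                                if d < cut and npairs < cap:
                                    pairs[npairs, 0] = p
                                    pairs[npairs, 1] = s2
                                    npairs += 1
                    s2 = cl_next[s2]
    counts[C_NPAIRS] = npairs
    counts[C_NMOTSEG] = nmot


@njit(**NB)
def _cell_of(px, py, Lx, Ly, ncx, ncy):
    csx = Lx / ncx
    csy = Ly / ncy
    ix = int(px / csx) % ncx
    if ix < 0:
        ix += ncx
    iy = int(py / csy)
    if iy < 0:
        iy = 0
    elif iy >= ncy:
        iy = ncy - 1
    return ix, iy


@njit(**NB)
def _nearest_site(x, p, q, qx, qy, qz, occ, cap, Lx):
    """Nearest unoccupied binding site on segment (p,q) to query point
    (qx,qy,qz) within capture distance ``cap``; returns site index or -1."""
    wx, wy, wz = _dvec(x, p, q, Lx)
    L2 = wx * wx + wy * wy + wz * wz
    if L2 < 1e-30:
        return -1
    ex = _mi(qx - x[p, 0], Lx)
    ey = qy - x[p, 1]
    ez = qz - x[p, 2]
    t = (ex * wx + ey * wy + ez * wz) / L2
    s0 = int(round(t * SITES_PER_SEG))
    best = -1
    bestd = cap
    for ds in range(-1, 2):
        s = s0 + ds
        if s < 0 or s >= SITES_PER_SEG:
            continue
        if occ[p, s] != 0:
            continue
        fr = _site_frac(s)
        dx = _mi(x[p, 0] + fr * wx - qx, Lx)
        dy = x[p, 1] + fr * wy - qy
        dz = x[p, 2] + fr * wz - qz
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d < bestd:
            bestd = d
            best = s
    return best


# ---------------------------------------------------------------------------
# topology mutation helpers
# ---------------------------------------------------------------------------

@njit(**NB)
def _free_pt(p, active, anchored, nxt, prv, filid, pt_arp, occ, wkind, widx,
             pt_free, counts, m_link):
    active[p] = 0
    anchored[p] = 0
    nxt[p] = -1
    prv[p] = -1
    filid[p] = -1
    pt_arp[p] = -1
    for s in range(SITES_PER_SEG):
        occ[p, s] = 0
        wkind[p, s] = 0
        widx[p, s] = -1
    for n in range(m_link.shape[0]):
        if m_link[n] == p:
            m_link[n] = -1
    pt_free[counts[C_NPT_FREE]] = p
    counts[C_NPT_FREE] += 1


@njit(**NB)
def _alloc_pt(pt_free, counts, active, gen):
    counts[C_NPT_FREE] -= 1
    p = pt_free[counts[C_NPT_FREE]]
    active[p] = 1
    gen[p] += 1
    return p


@njit(**NB)
def _collapse_acp(a, acp_state, acp_pts, x, active, anchored, nxt, prv,
                  filid, pt_arp, occ, wkind, widx, pt_free, counts, m_link):
    """Fold an expanded, fully unbound cross-linker back to a compact point."""
    _free_pt(acp_pts[a, 1], active, anchored, nxt, prv, filid, pt_arp, occ,
             wkind, widx, pt_free, counts, m_link)
    _free_pt(acp_pts[a, 2], active, anchored, nxt, prv, filid, pt_arp, occ,
             wkind, widx, pt_free, counts, m_link)
    acp_pts[a, 1] = -1
    acp_pts[a, 2] = -1
    acp_state[a] = 1


@njit(**NB)
def _collapse_arp(r, arp_state, arp_pts, x, active, anchored, nxt, prv,
                  filid, pt_arp, occ, wkind, widx, pt_free, counts, m_link):
    _free_pt(arp_pts[r, 1], active, anchored, nxt, prv, filid, pt_arp, occ,
             wkind, widx, pt_free, counts, m_link)
    _free_pt(arp_pts[r, 2], active, anchored, nxt, prv, filid, pt_arp, occ,
             wkind, widx, pt_free, counts, m_link)
    arp_pts[r, 1] = -1
    arp_pts[r, 2] = -1
    arp_state[r] = 1


@njit(**NB)
def _release_seg_sites(s, x, active, anchored, nxt, prv, filid, pt_arp, occ,
                       wkind, widx, pt_free, counts, m_link,
                       acp_state, acp_pts, acp_seg, acp_site,
                       arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                       arp_dpt, fil_parent, mot_bound, mot_site):
    """Every bound protein on segment keyed by point ``s`` loses that
    connection (the segment is about to disappear)."""
    for site in range(SITES_PER_SEG):
        k = wkind[s, site]
        if k == 0:
            continue
        idx = widx[s, site]
        if k == 1:  # cross-linker arm
            a = idx >> 1
            arm = idx & 1
            acp_seg[a, arm] = -1
            acp_site[a, arm] = -1
            if acp_state[a] == 2 and acp_seg[a, 0] < 0 and acp_seg[a, 1] < 0:
                _collapse_acp(a, acp_state, acp_pts, x, active, anchored, nxt,
                              prv, filid, pt_arp, occ, wkind, widx, pt_free,
                              counts, m_link)
        elif k == 2:  # Arp2/3 mother arm
            r = idx
            arp_seg[r] = -1
            arp_msite[r] = -1
            if arp_state[r] == 2 and arp_dpt[r] < 0:
                _collapse_arp(r, arp_state, arp_pts, x, active, anchored, nxt,
                              prv, filid, pt_arp, occ, wkind, widx, pt_free,
                              counts, m_link)
        elif k == 3:  # motor arm
            m = idx >> 3
            arm = idx & 7
            mot_bound[m, arm] = -1
            mot_site[m, arm] = -1
        occ[s, site] = 0
        wkind[s, site] = 0
        widx[s, site] = -1


@njit(**NB)
def _release_daughter_pt(p, x, active, anchored, nxt, prv, filid, pt_arp,
                         occ, wkind, widx, pt_free, counts, m_link,
                         arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                         arp_dpt, fil_parent):
    """Point ``p`` (a daughter pointed end) is about to disappear: detach
    its Arp2/3 junction."""
    r = pt_arp[p]
    if r < 0:
        return
    f = arp_dfil[r]
    if f >= 0:
        fil_parent[f] = -1
    arp_dfil[r] = -1
    arp_dpt[r] = -1
    pt_arp[p] = -1
    if arp_state[r] == 2 and arp_seg[r] < 0:
        _collapse_arp(r, arp_state, arp_pts, x, active, anchored, nxt, prv,
                      filid, pt_arp, occ, wkind, widx, pt_free, counts, m_link)


@njit(**NB)
def _remove_pointed(f, x, active, anchored, nxt, prv, filid, pt_arp, occ,
                    wkind, widx, pt_free, counts, m_link,
                    fil_pt, fil_bb, fil_n, fil_parent, fil_active, fil_free,
                    acp_state, acp_pts, acp_seg, acp_site,
                    arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                    arp_dpt, mot_bound, mot_site):
    """Depolymerize one segment from the pointed end of filament ``f``."""
    p0 = fil_pt[f]
    _release_seg_sites(p0, x, active, anchored, nxt, prv, filid, pt_arp, occ,
                       wkind, widx, pt_free, counts, m_link,
                       acp_state, acp_pts, acp_seg, acp_site,
                       arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                       arp_dpt, fil_parent, mot_bound, mot_site)
    _release_daughter_pt(p0, x, active, anchored, nxt, prv, filid, pt_arp,
                         occ, wkind, widx, pt_free, counts, m_link,
                         arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                         arp_dpt, fil_parent)
    p1 = nxt[p0]
    if fil_n[f] == 1:
        _free_pt(p0, active, anchored, nxt, prv, filid, pt_arp, occ, wkind,
                 widx, pt_free, counts, m_link)
        _free_pt(p1, active, anchored, nxt, prv, filid, pt_arp, occ, wkind,
                 widx, pt_free, counts, m_link)
        fil_active[f] = 0
        fil_parent[f] = -1
        fil_pt[f] = -1
        fil_bb[f] = -1
        fil_n[f] = 0
        fil_free[counts[C_NFIL_FREE]] = f
        counts[C_NFIL_FREE] += 1
    else:
        _free_pt(p0, active, anchored, nxt, prv, filid, pt_arp, occ, wkind,
                 widx, pt_free, counts, m_link)
        prv[p1] = -1
        fil_pt[f] = p1
        fil_n[f] -= 1
    counts[C_POOL_FREE] += 1


@njit(**NB)
def _sever_at(j, x, active, anchored, nxt, prv, filid, pt_arp, occ, wkind,
              widx, pt_free, counts, m_link,
              fil_pt, fil_bb, fil_n, fil_parent, fil_active, fil_free,
              acp_state, acp_pts, acp_seg, acp_site,
              arp_state, arp_pts, arp_seg, arp_msite, arp_dfil, arp_dpt,
              mot_bound, mot_site):
    """Remove the barbed-side segment at interior joint ``j`` and split the
    filament into two (or truncate it when the removed segment is terminal)."""
    f = filid[j]
    q = nxt[j]
    _release_seg_sites(j, x, active, anchored, nxt, prv, filid, pt_arp, occ,
                       wkind, widx, pt_free, counts, m_link,
                       acp_state, acp_pts, acp_seg, acp_site,
                       arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                       arp_dpt, fil_parent, mot_bound, mot_site)
    # count segments pointed..j  (j becomes the new barbed end of fragment A)
    n_a = 0
    p = fil_pt[f]
    while p != j:
        n_a += 1
        p = nxt[p]
    n_total = fil_n[f]
    n_b = n_total - n_a - 1
    nxt[j] = -1
    fil_bb[f] = j
    fil_n[f] = n_a
    counts[C_POOL_FREE] += 1
    if n_b == 0:
        # removed segment was terminal: q is a bare point
        _free_pt(q, active, anchored, nxt, prv, filid, pt_arp, occ, wkind,
                 widx, pt_free, counts, m_link)
        return -1
    # fragment B becomes a new filament with pointed end q
    counts[C_NFIL_FREE] -= 1
    g = fil_free[counts[C_NFIL_FREE]]
    fil_active[g] = 1
    fil_parent[g] = -1
    prv[q] = -1
    fil_pt[g] = q
    p = q
    while p >= 0:
        filid[p] = g
        if nxt[p] < 0:
            fil_bb[g] = p
        p = nxt[p]
    fil_n[g] = n_b
    return g


@njit(**NB)
def _polymerize(f, x, active, gen, nxt, prv, filid, occ, wkind, widx,
                pt_free, counts, fil_bb, fil_n, zeta, sig, za, sa, P):
    """Append one segment at the barbed end, collinear with the terminal
    segment."""
    b = fil_bb[f]
    pr = prv[b]
    Lx = P[P_LX]
    dx, dy, dz = _dvec(x, pr, b, Lx)
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    if r < 1e-15:
        return
    p = _alloc_pt(pt_free, counts, active, gen)
    s = P[P_R0_A] / r
    x[p, 0] = x[b, 0] + dx * s
    x[p, 1] = x[b, 1] + dy * s
    x[p, 2] = x[b, 2] + dz * s
    if x[p, 0] >= Lx:
        x[p, 0] -= Lx
    elif x[p, 0] < 0.0:
        x[p, 0] += Lx
    zeta[p] = za
    sig[p] = sa
    nxt[b] = p
    prv[p] = b
    nxt[p] = -1
    filid[p] = f
    fil_bb[f] = p
    fil_n[f] += 1
    for site in range(SITES_PER_SEG):
        occ[b, site] = 0
        wkind[b, site] = 0
        widx[b, site] = -1
    counts[C_POOL_FREE] -= 1


@njit(**NB)
def _nucleate_seg(px, py, pz, dirx, diry, x, active, gen, nxt, prv, filid,
                  pt_free, counts, fil_pt, fil_bb, fil_n, fil_parent,
                  fil_active, fil_free, zeta, sig, za, sa, P):
    """New single-segment filament in the xy plane at height pz."""
    counts[C_NFIL_FREE] -= 1
    f = fil_free[counts[C_NFIL_FREE]]
    fil_active[f] = 1
    fil_parent[f] = -1
    p0 = _alloc_pt(pt_free, counts, active, gen)
    p1 = _alloc_pt(pt_free, counts, active, gen)
    Lx = P[P_LX]
    x[p0, 0] = px % Lx
    x[p0, 1] = py
    x[p0, 2] = pz
    x[p1, 0] = (px + dirx * P[P_R0_A]) % Lx
    x[p1, 1] = py + diry * P[P_R0_A]
    x[p1, 2] = pz
    zeta[p0] = za
    zeta[p1] = za
    sig[p0] = sa
    sig[p1] = sa
    nxt[p0] = p1
    prv[p1] = p0
    nxt[p1] = -1
    prv[p0] = -1
    filid[p0] = f
    filid[p1] = f
    fil_pt[f] = p0
    fil_bb[f] = p1
    fil_n[f] = 1
    counts[C_POOL_FREE] -= 1
    return f


@njit(**NB)
def _branch_dir(rs, tx, ty, tz, th_f):
    """Daughter axis at the characteristic branch angle from mother tangent
    (tx,ty,tz), azimuth biased toward +y (the leading edge)."""
    # orthonormal frame around the tangent: e1 = normalize(t x a)
    ax, ay, az = 0.0, 0.0, 1.0
    if abs(tz) > 0.9:
        ax, ay, az = 0.0, 1.0, 0.0
    e1x = ty * az - tz * ay
    e1y = tz * ax - tx * az
    e1z = tx * ay - ty * ax
    n = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= n
    e1y /= n
    e1z /= n
    e2x = ty * e1z - tz * e1y
    e2y = tz * e1x - tx * e1z
    e2z = tx * e1y - ty * e1x
    ct = math.cos(th_f)
    st = math.sin(th_f)
    bestx, besty, bestz = 0.0, -2.0, 0.0
    for _ in range(16):
        psi = 2.0 * math.pi * _ru(rs)
        dx = ct * tx + st * (math.cos(psi) * e1x + math.sin(psi) * e2x)
        dy = ct * ty + st * (math.cos(psi) * e1y + math.sin(psi) * e2y)
        dz = ct * tz + st * (math.cos(psi) * e1z + math.sin(psi) * e2z)
        if dy > 0.0:
            return dx, dy, dz
        if dy > besty:
            bestx, besty, bestz = dx, dy, dz
    return bestx, besty, bestz


@njit(**NBI)
def _arm_load(x, b, s, q, site, k2, Lx):
    """Longitudinal spring force opposing barbed-ward stepping (N, >= 0)."""
    fr = _site_frac(site)
    wx, wy, wz = _dvec(x, s, q, Lx)
    Lw = math.sqrt(wx * wx + wy * wy + wz * wz)
    if Lw < 1e-15:
        return 0.0
    dx = _mi(x[s, 0] + fr * wx - x[b, 0], Lx)
    dy = x[s, 1] + fr * wy - x[b, 1]
    dz = x[s, 2] + fr * wz - x[b, 2]
    dl = (dx * wx + dy * wy + dz * wz) / Lw
    f = k2 * dl
    return f if f > 0.0 else 0.0


@njit(**NBI)
def motor_rate_pair(load, P):
    """(k_w, k_u) of a bound arm at the given opposing load (N): catch
    bond up to stall, slip beyond it."""
    gate = 1.0 - load / P[P_F_STALL]
    if gate < 0.0:
        gate = 0.0
    k12 = P[P_K12_0] * gate
    a = P[P_K20] + P[P_K21]
    denom = k12 + a
    kw = k12 * a / denom
    ku = (P[P_K10] * a + P[P_K20] * k12) / denom
    over = load - P[P_F_STALL]
    if over > 0.0:
        ex = over / P[P_F_SLIP]
        if ex > 30.0:
            ex = 30.0
        ku *= math.exp(ex)
    return kw, ku


# ---------------------------------------------------------------------------
# force assembly
# ---------------------------------------------------------------------------

@njit(**NB)
def compute_forces(x, F, active, anchored, nxt, prv, filid,
                   acp_state, acp_pts, acp_seg, acp_site,
                   arp_state, arp_pts, arp_seg, arp_msite, arp_dpt,
                   mot_state, mot_pts, mot_bound, mot_site,
                   mx, m_link, m_link_r0, mF,
                   pairs, counts, P, walls, sevj, sevr, sevn):
    """All deterministic internal forces on network points (into F) and the
    adhesion-link reactions on mesh nodes (into mF).  As a side product the
    actin bending pass records severing candidates (joint id, rate) whose
    angle-dependent rate is non-negligible."""
    F[:, :] = 0.0
    mF[:, :] = 0.0
    sevn[0] = 0
    Lx = P[P_LX]
    NP = x.shape[0]
    ks_a = P[P_KS_A]
    r0_a = P[P_R0_A]
    kb_a = P[P_KB_A]
    # severing prefilter: only joints with k_sev*dt > 1e-16 are candidates
    k0s = P[P_K0_SEV]
    lam = P[P_LAM_SEV]
    if k0s > 0.0 and lam > 0.0:
        thc_deg = (math.log(1e-16) - math.log(k0s * P[P_DT])) / lam
    else:
        thc_deg = 1e30
    cap_sev = sevj.shape[0]
    # --- actin chains ---
    for p in range(NP):
        if active[p] == 0 or filid[p] < 0:
            continue
        q = nxt[p]
        if q >= 0:
            _spring(x, F, p, q, ks_a, r0_a, Lx)
        pr = prv[p]
        if q >= 0 and pr >= 0:
            th = _angle3(x, F, pr, p, q, kb_a, math.pi, Lx)
            bend_deg = (math.pi - th) * 57.29577951308232
            if bend_deg > thc_deg and sevn[0] < cap_sev:
                sevj[sevn[0]] = p
                sevr[sevn[0]] = k0s * math.exp(lam * bend_deg)
                sevn[0] += 1
    # --- cross-linkers ---
    kl = P[P_KL_BIND]
    for a in range(acp_state.shape[0]):
        if acp_state[a] != 2:
            continue
        c = acp_pts[a, 0]
        a1 = acp_pts[a, 1]
        a2 = acp_pts[a, 2]
        _spring(x, F, c, a1, P[P_KS_ACP], P[P_R0_ACP], Lx)
        _spring(x, F, c, a2, P[P_KS_ACP], P[P_R0_ACP], Lx)
        _angle3(x, F, a1, c, a2, P[P_KB_ACP], math.pi, Lx)
        for arm in range(2):
            s = acp_seg[a, arm]
            if s >= 0:
                _site_link_force(x, F, acp_pts[a, 1 + arm], s, nxt[s],
                                 acp_site[a, arm], kl, Lx)
    # --- branch junctions ---
    for r in range(arp_state.shape[0]):
        if arp_state[r] != 2:
            continue
        c = arp_pts[r, 0]
        a1 = arp_pts[r, 1]
        a2 = arp_pts[r, 2]
        _spring(x, F, c, a1, P[P_KS_ARP], P[P_R0_ARP], Lx)
        _spring(x, F, c, a2, P[P_KS_ARP], P[P_R0_ARP], Lx)
        _angle3(x, F, a1, c, a2, P[P_KB_ARP_C], math.pi, Lx)
        s = arp_seg[r]
        dp = arp_dpt[r]
        if s >= 0:
            mq = nxt[s]
            _site_link_force(x, F, a1, s, mq, arp_msite[r], kl, Lx)
            _angle4(x, F, s, mq, a1, c, P[P_KB_ARP_M], P[P_TH_ARP_M], Lx)
        if dp >= 0:
            _spring(x, F, a2, dp, kl, 0.0, Lx)
            d1 = nxt[dp]
            if d1 >= 0:
                _angle4(x, F, c, a2, dp, d1, P[P_KB_ARP_D], P[P_TH_ARP_D], Lx)
                if s >= 0:
                    mq = nxt[s]
                    _angle4(x, F, s, mq, dp, d1, P[P_KB_ARP_F],
                            P[P_TH_ARP_F], Lx)
                    _dihedral_plane(x, F, s, mq, dp, d1, P[P_KT_ARP], Lx)
    # --- motors ---
    for m in range(mot_state.shape[0]):
        if mot_state[m] != 1:
            continue
        for i in range(7):
            _spring(x, F, mot_pts[m, i], mot_pts[m, i + 1], P[P_KS_MB],
                    P[P_R0_MB], Lx)
        for i in range(1, 7):
            _angle3(x, F, mot_pts[m, i - 1], mot_pts[m, i],
                    mot_pts[m, i + 1], P[P_KB_MB], math.pi, Lx)
        for arm in range(8):
            s = mot_bound[m, arm]
            if s >= 0:
                _two_spring_force(x, F, mot_pts[m, arm], s, nxt[s],
                                  mot_site[m, arm], P[P_KS_M1], P[P_R0_M1],
                                  P[P_KS_M2], Lx)
    # --- volume exclusion between actin segments ---
    rc = P[P_RC_A]
    kr = P[P_KR_A]
    for ip in range(counts[C_NPAIRS]):
        p = pairs[ip, 0]
        s2 = pairs[ip, 1]
        if active[p] == 0 or active[s2] == 0:
            continue
        q = nxt[p]
        q2 = nxt[s2]
        if q < 0 or q2 < 0 or filid[p] < 0 or filid[s2] < 0:
            continue
        d, t, u, nx_, ny_, nz_ = _segseg(x, p, q, s2, q2, Lx)
        if d < rc and d > 1e-15:
            f = kr * (rc - d)
            F[p, 0] -= f * nx_ * (1.0 - t)
            F[p, 1] -= f * ny_ * (1.0 - t)
            F[p, 2] -= f * nz_ * (1.0 - t)
            F[q, 0] -= f * nx_ * t
            F[q, 1] -= f * ny_ * t
            F[q, 2] -= f * nz_ * t
            F[s2, 0] += f * nx_ * (1.0 - u)
            F[s2, 1] += f * ny_ * (1.0 - u)
            F[s2, 2] += f * nz_ * (1.0 - u)
            F[q2, 0] += f * nx_ * u
            F[q2, 1] += f * ny_ * u
            F[q2, 2] += f * nz_ * u
    # --- adhesion links (network <-> substrate) ---
    ks_c = P[P_KS_C]
    for n in range(m_link.shape[0]):
        pt = m_link[n]
        if pt < 0:
            continue
        ex = _mi(x[pt, 0] - mx[n, 0], Lx)
        ey = x[pt, 1] - mx[n, 1]
        ez = x[pt, 2] - mx[n, 2]
        r = math.sqrt(ex * ex + ey * ey + ez * ez)
        if r < 1e-15:
            continue
        coef = ks_c * (r - m_link_r0[n]) / r
        F[pt, 0] -= coef * ex
        F[pt, 1] -= coef * ey
        F[pt, 2] -= coef * ez
        mF[n, 0] += coef * ex
        mF[n, 1] += coef * ey
        mF[n, 2] += coef * ez
    # --- repulsive walls (+y, z) ---
    if walls == 1:
        kw = P[P_K_WALL]
        Ly = P[P_LY]
        Lz = P[P_LZ]
        for p in range(NP):
            if active[p] == 0 or anchored[p] == 1:
                continue
            y = x[p, 1]
            z = x[p, 2]
            if y > Ly:
                F[p, 1] -= kw * (y - Ly)
            if y < 0.0 and filid[p] < 0:
                F[p, 1] += kw * (0.0 - y)
            if z < 0.0:
                F[p, 2] += kw * (0.0 - z)
            elif z > Lz:
                F[p, 2] -= kw * (z - Lz)


@njit(**NB)
def mesh_internal_forces(mx, mF, m_edges, m_tri, P):
    """Elastic forces of the substrate mesh (chains + 60-degree angles)."""
    Lx = P[P_LX]
    for e in range(m_edges.shape[0]):
        _spring(mx, mF, m_edges[e, 0], m_edges[e, 1], P[P_KS_SUB],
                P[P_R0_SUB], Lx)
    th0 = P[P_TH_SUB]
    kb = P[P_KB_SUB]
    for t in range(m_tri.shape[0]):
        a = m_tri[t, 0]
        b = m_tri[t, 1]
        c = m_tri[t, 2]
        _angle3(mx, mF, b, a, c, kb, th0, Lx)
        _angle3(mx, mF, a, b, c, kb, th0, Lx)
        _angle3(mx, mF, a, c, b, kb, th0, Lx)


@njit(**NB)
def _find_site(x, qx, qy, qz, cap, exclude_fil, active, nxt, filid, occ,
               cl_head, cl_next, ncx, ncy, P, radius):
    """Nearest unoccupied binding site within ``cap`` of the query position,
    searched over the segment cell list; returns (seg, site) or (-1, -1)."""
    Lx = P[P_LX]
    Ly = P[P_LY]
    ix, iy = _cell_of(qx, qy, Lx, Ly, ncx, ncy)
    best_s = -1
    best_site = -1
    best_d = cap
    for dy in range(-radius, radius + 1):
        jy = iy + dy
        if jy < 0 or jy >= ncy:
            continue
        for dxc in range(-radius, radius + 1):
            jx = (ix + dxc) % ncx
            s = cl_head[jy * ncx + jx]
            while s >= 0:
                if active[s] == 1 and filid[s] >= 0 and nxt[s] >= 0 and \
                        filid[s] != exclude_fil:
                    q = nxt[s]
                    wx, wy, wz = _dvec(x, s, q, Lx)
                    L2 = wx * wx + wy * wy + wz * wz
                    if L2 > 1e-30:
                        ex = _mi(qx - x[s, 0], Lx)
                        ey = qy - x[s, 1]
                        ez = qz - x[s, 2]
                        tpar = (ex * wx + ey * wy + ez * wz) / L2
                        s0 = int(round(tpar * SITES_PER_SEG))
                        for ds in range(-1, 2):
                            st = s0 + ds
                            if st < 0 or st >= SITES_PER_SEG or occ[s, st] != 0:
                                continue
                            fr = _site_frac(st)
                            dx = _mi(x[s, 0] + fr * wx - qx, Lx)
                            dyy = x[s, 1] + fr * wy - qy
                            dz = x[s, 2] + fr * wz - qz
                            d = math.sqrt(dx * dx + dyy * dyy + dz * dz)
                            if d < best_d:
                                best_d = d
                                best_s = s
                                best_site = st
                s = cl_next[s]
    return best_s, best_site


@njit(**NB)
def _place_backbone(m, s, site, x, nxt, mot_pts, rs, P):
    """Assemble a motor backbone adjacent to binding site (s, site)."""
    Lx = P[P_LX]
    fr = _site_frac(site)
    wx, wy, wz = _dvec(x, s, nxt[s], Lx)
    sx = x[s, 0] + fr * wx
    sy = x[s, 1] + fr * wy
    sz = x[s, 2] + fr * wz
    phi = 2.0 * math.pi * _ru(rs)
    cx = sx + P[P_R0_M1] * math.cos(phi)
    cy = sy + P[P_R0_M1] * math.sin(phi)
    cz = sz
    Ly = P[P_LY]
    Lz = P[P_LZ]
    if cy < 0.0:
        cy = 0.0
    elif cy > Ly:
        cy = Ly
    if cz < 0.0:
        cz = 0.0
    elif cz > Lz:
        cz = Lz
    for i in range(8):
        px = cx + (i - 3.5) * P[P_R0_MB]
        px = px % Lx
        x[mot_pts[m, i], 0] = px
        x[mot_pts[m, i], 1] = cy
        x[mot_pts[m, i], 2] = cz


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@njit(**NB)
def advance(x, zeta, sig, anchored, active, gen,
            nxt, prv, filid, pt_arp,
            occ, wkind, widx,
            fil_pt, fil_bb, fil_n, fil_parent, fil_active, fil_free,
            pt_free, counts,
            acp_state, acp_pts, acp_seg, acp_site,
            arp_state, arp_pts, arp_seg, arp_msite, arp_dfil, arp_dpt,
            mot_state, mot_pts, mot_bound, mot_site,
            mx, m_pinned, m_link, m_link_r0, m_edges, m_tri, mF,
            F, pairs, motsegs, cl_head, cl_next, ncx, ncy,
            sevj, sevr, sevn,
            ev, rs, P, phase, nsteps, za, sa):
    """Run ``nsteps`` fixed-dt steps; returns 0 on success, 1 on integration
    instability.  ``phase`` 0 = assembly (no motor walking, no region gates
    on polymerization/depolymerization), 1 = steady state."""
    dt = P[P_DT]
    Lx = P[P_LX]
    Ly = P[P_LY]
    Lz = P[P_LZ]
    n_kin = int(P[P_N_KIN])
    n_mesh = int(P[P_N_MESH])
    rebuild = int(P[P_REBUILD])
    dtk = n_kin * dt
    dtm = n_mesh * dt
    maxd2 = P[P_MAX_DISP] * P[P_MAX_DISP]
    NF = fil_pt.shape[0]
    sig_mesh = 0.0
    if P[P_ZETA_MESH] > 0.0:
        sig_mesh = math.sqrt(2.0 * P[P_KBT] * dtm / P[P_ZETA_MESH])
    for _istep in range(nsteps):
        step = counts[C_STEP]
        if step % rebuild == 0:
            rebuild_lists(x, active, nxt, filid, P, counts, pairs, motsegs,
                          cl_head, cl_next, ncx, ncy)
        # ---------------- (1) kinetics ----------------
        # depolymerization (pointed end, disassembly region in steady phase)
        p_dep = -math.expm1(-P[P_KM_A] * dt)
        if P[P_KM_A] > 0.0:
            for f in range(NF):
                if fil_active[f] == 0:
                    continue
                y = x[fil_pt[f], 1]
                if phase == 1 and not (y >= P[P_DIS_LO] and y < P[P_DIS_HI]):
                    continue
                if _ru(rs) < p_dep:
                    _remove_pointed(f, x, active, anchored, nxt, prv, filid,
                                    pt_arp, occ, wkind, widx, pt_free, counts,
                                    m_link, fil_pt, fil_bb, fil_n, fil_parent,
                                    fil_active, fil_free,
                                    acp_state, acp_pts, acp_seg, acp_site,
                                    arp_state, arp_pts, arp_seg, arp_msite,
                                    arp_dfil, arp_dpt, mot_bound, mot_site)
                    ev[EV_DEPOLY] += 1
        # severing (buffered candidates from the previous force pass)
        for i in range(sevn[0]):
            j = sevj[i]
            if active[j] == 0 or filid[j] < 0 or prv[j] < 0 or nxt[j] < 0:
                continue
            if fil_n[filid[j]] < 3:
                continue
            if _ru(rs) < -math.expm1(-sevr[i] * dt):
                _sever_at(j, x, active, anchored, nxt, prv, filid, pt_arp,
                          occ, wkind, widx, pt_free, counts, m_link,
                          fil_pt, fil_bb, fil_n, fil_parent, fil_active,
                          fil_free, acp_state, acp_pts, acp_seg, acp_site,
                          arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                          arp_dpt, mot_bound, mot_site)
                ev[EV_SEVER] += 1
        sevn[0] = 0
        # polymerization (barbed end, assembly region in steady phase)
        floor_segs = P[P_FLOOR] * counts[C_POOL_TOTAL]
        if P[P_KP_A] > 0.0:
            rate_pol = P[P_KP_A] * P[P_UM_PER_SEG] * counts[C_POOL_FREE]
            p_pol = -math.expm1(-rate_pol * dt)
            for f in range(NF):
                if fil_active[f] == 0 or fil_n[f] >= int(P[P_MAX_NSEG]):
                    continue
                if counts[C_POOL_FREE] - 1 < floor_segs:
                    break
                if counts[C_NPT_FREE] < 1:
                    break
                y = x[fil_bb[f], 1]
                if phase == 1:
                    if not (y >= P[P_ASM_LO] and
                            (y < P[P_ASM_HI] or
                             (P[P_ASM_HI] >= Ly and y <= P[P_ASM_HI]))):
                        continue
                if _ru(rs) < p_pol:
                    _polymerize(f, x, active, gen, nxt, prv, filid, occ,
                                wkind, widx, pt_free, counts, fil_bb, fil_n,
                                zeta, sig, za, sa, P)
                    ev[EV_POLY] += 1
        # de novo nucleation
        if P[P_KN_A] > 0.0 and counts[C_POOL_FREE] - 1 >= floor_segs and \
                counts[C_NPT_FREE] >= 2 and counts[C_NFIL_FREE] >= 1:
            if _ru(rs) < -math.expm1(-P[P_KN_A] * dt):
                if phase == 0:
                    _nucleate_seg(_ru(rs) * Lx, 0.0, 0.0, 0.0, 1.0,
                                  x, active, gen, nxt, prv, filid, pt_free,
                                  counts,
                                  fil_pt, fil_bb, fil_n, fil_parent,
                                  fil_active, fil_free, zeta, sig, za, sa, P)
                else:
                    ang = 2.0 * math.pi * _ru(rs)
                    _nucleate_seg(_ru(rs) * Lx, _ru(rs) * Ly, 0.0,
                                  math.cos(ang), math.sin(ang),
                                  x, active, gen, nxt, prv, filid, pt_free,
                                  counts,
                                  fil_pt, fil_bb, fil_n, fil_parent,
                                  fil_active, fil_free, zeta, sig, za, sa, P)
                ev[EV_NUCLEATE] += 1
        # binding / motor / adhesion kinetics at the coarser cadence
        if step % n_kin == 0:
            _binding_kinetics(x, zeta, sig, anchored, active, gen, nxt,
                              prv, filid, pt_arp, occ, wkind, widx,
                              fil_pt, fil_bb, fil_n, fil_parent, fil_active,
                              fil_free, pt_free, counts,
                              acp_state, acp_pts, acp_seg, acp_site,
                              arp_state, arp_pts, arp_seg, arp_msite,
                              arp_dfil, arp_dpt,
                              mot_state, mot_pts, mot_bound, mot_site,
                              mx, m_link, m_link_r0,
                              motsegs, cl_head, cl_next, ncx, ncy,
                              ev, rs, P, phase, dtk, za, sa)
        # ---------------- (2) forces ----------------
        compute_forces(x, F, active, anchored, nxt, prv, filid,
                       acp_state, acp_pts, acp_seg, acp_site,
                       arp_state, arp_pts, arp_seg, arp_msite, arp_dpt,
                       mot_state, mot_pts, mot_bound, mot_site,
                       mx, m_link, m_link_r0, mF,
                       pairs, counts, P, 1, sevj, sevr, sevn)
        # ---------------- (3) Euler update + (4) boundaries ----------------
        bad = 0
        clip = 0.25 * P[P_R0_A]
        clip2 = clip * clip
        for p in range(x.shape[0]):
            if active[p] == 0 or anchored[p] == 1:
                continue
            iz = dt / zeta[p]
            fx = F[p, 0] * iz
            fy = F[p, 1] * iz
            fz = F[p, 2] * iz
            d2 = fx * fx + fy * fy + fz * fz
            if d2 > clip2:
                # displacement limiter: rare force spikes (e.g. an extreme
                # buckle that severing would normally relieve) may not move
                # an endpoint more than a quarter segment per step
                sc = clip / math.sqrt(d2)
                fx *= sc
                fy *= sc
                fz *= sc
            ddx = fx + sig[p] * _rsym(rs)
            ddy = fy + sig[p] * _rsym(rs)
            ddz = fz + sig[p] * _rsym(rs)
            if ddx * ddx + ddy * ddy + ddz * ddz > maxd2:
                bad = 1
            xn = x[p, 0] + ddx
            if xn >= Lx:
                xn -= Lx
            elif xn < 0.0:
                xn += Lx
            x[p, 0] = xn
            x[p, 1] += ddy
            x[p, 2] += ddz
            if filid[p] >= 0 and x[p, 1] <= 0.0:
                x[p, 1] = 0.0
                anchored[p] = 1  # sticky -y boundary
        if bad == 1:
            counts[C_ERROR] = 1
            return 1
        # ---------------- substrate substep ----------------
        if step % n_mesh == 0:
            mesh_internal_forces(mx, mF, m_edges, m_tri, P)
            izm = dtm / P[P_ZETA_MESH]
            for n in range(mx.shape[0]):
                if m_pinned[n] == 1:
                    continue
                xn = mx[n, 0] + mF[n, 0] * izm + sig_mesh * _rsym(rs)
                if xn >= Lx:
                    xn -= Lx
                elif xn < 0.0:
                    xn += Lx
                mx[n, 0] = xn
                mx[n, 1] += mF[n, 1] * izm + sig_mesh * _rsym(rs)
                # z is constrained to the substrate plane
        counts[C_STEP] += 1
    return 0


@njit(**NB)
def _spawn_daughter(r, s, d0x, d0y, d0z, x, active, gen, nxt, prv, filid,
                    pt_arp, pt_free, counts, fil_pt, fil_bb, fil_n,
                    fil_parent, fil_active, fil_free, arp_dfil, arp_dpt,
                    zeta, sig, rs, P, za, sa):
    """Nucleate a daughter filament for Arp2/3 ``r`` bound to mother segment
    ``s``: one actin segment whose pointed end sits at the junction arm and
    whose axis makes the characteristic 70-degree angle with the mother,
    biased toward +y.  Returns the new filament id or -1."""
    if counts[C_POOL_FREE] - 1 < P[P_FLOOR] * counts[C_POOL_TOTAL]:
        return -1
    if counts[C_NPT_FREE] < 2 or counts[C_NFIL_FREE] < 1:
        return -1
    Lx = P[P_LX]
    wx, wy, wz = _dvec(x, s, nxt[s], Lx)
    Lw = math.sqrt(wx * wx + wy * wy + wz * wz)
    if Lw < 1e-15:
        return -1
    tx = wx / Lw
    ty = wy / Lw
    tz = wz / Lw
    dx, dy, dz = _branch_dir(rs, tx, ty, tz, P[P_TH_ARP_F])
    counts[C_NFIL_FREE] -= 1
    g = fil_free[counts[C_NFIL_FREE]]
    fil_active[g] = 1
    d0 = _alloc_pt(pt_free, counts, active, gen)
    d1 = _alloc_pt(pt_free, counts, active, gen)
    x[d0, 0] = d0x % Lx
    x[d0, 1] = d0y
    x[d0, 2] = d0z
    r0a = P[P_R0_A]
    x[d1, 0] = (d0x + dx * r0a) % Lx
    x[d1, 1] = d0y + dy * r0a
    x[d1, 2] = d0z + dz * r0a
    zeta[d0] = za
    zeta[d1] = za
    sig[d0] = sa
    sig[d1] = sa
    nxt[d0] = d1
    prv[d1] = d0
    nxt[d1] = -1
    prv[d0] = -1
    filid[d0] = g
    filid[d1] = g
    fil_pt[g] = d0
    fil_bb[g] = d1
    fil_n[g] = 1
    fil_parent[g] = r
    arp_dfil[r] = g
    arp_dpt[r] = d0
    pt_arp[d0] = r
    counts[C_POOL_FREE] -= 1
    return g


@njit(**NB)
def _binding_kinetics(x, zeta, sig, anchored, active, gen, nxt, prv, filid,
                      pt_arp, occ, wkind, widx,
                      fil_pt, fil_bb, fil_n, fil_parent, fil_active,
                      fil_free, pt_free, counts,
                      acp_state, acp_pts, acp_seg, acp_site,
                      arp_state, arp_pts, arp_seg, arp_msite, arp_dfil,
                      arp_dpt,
                      mot_state, mot_pts, mot_bound, mot_site,
                      mx, m_link, m_link_r0,
                      motsegs, cl_head, cl_next, ncx, ncy,
                      ev, rs, P, phase, dtk, za, sa):
    Lx = P[P_LX]
    kbt = P[P_KBT]
    z_acp = P[P_ZETA_ACP]
    z_arp = P[P_ZETA_ARP]
    s_acp = math.sqrt(2.0 * kbt * P[P_DT] / z_acp) if z_acp > 0 else 0.0
    s_arp = math.sqrt(2.0 * kbt * P[P_DT] / z_arp) if z_arp > 0 else 0.0
    # ---- cross-linker binding ----
    p_acp = -math.expm1(-P[P_KP_ACP] * dtk)
    for a in range(acp_state.shape[0]):
        st = acp_state[a]
        if st == 1:
            if counts[C_NPT_FREE] < 2 or _ru(rs) >= p_acp:
                continue
            c = acp_pts[a, 0]
            s, site = _find_site(x, x[c, 0], x[c, 1], x[c, 2], P[P_CAP_ACP],
                                 -1, active, nxt, filid, occ, cl_head,
                                 cl_next, ncx, ncy, P, 1)
            if s < 0:
                continue
            # expand: arm 0 at the site, body extended along a random normal
            fr = _site_frac(site)
            wx, wy, wz = _dvec(x, s, nxt[s], Lx)
            sx = x[s, 0] + fr * wx
            sy = x[s, 1] + fr * wy
            sz = x[s, 2] + fr * wz
            phiang = 2.0 * math.pi * _ru(rs)
            nxr = math.cos(phiang)
            nyr = math.sin(phiang)
            a1 = _alloc_pt(pt_free, counts, active, gen)
            a2 = _alloc_pt(pt_free, counts, active, gen)
            r0c = P[P_R0_ACP]
            x[a1, 0] = sx % Lx
            x[a1, 1] = sy
            x[a1, 2] = sz
            x[c, 0] = (sx + r0c * nxr) % Lx
            x[c, 1] = sy + r0c * nyr
            x[c, 2] = sz
            x[a2, 0] = (sx + 2.0 * r0c * nxr) % Lx
            x[a2, 1] = sy + 2.0 * r0c * nyr
            x[a2, 2] = sz
            zeta[a1] = z_acp
            zeta[a2] = z_acp
            sig[a1] = s_acp
            sig[a2] = s_acp
            acp_pts[a, 1] = a1
            acp_pts[a, 2] = a2
            acp_seg[a, 0] = s
            acp_site[a, 0] = site
            occ[s, site] = 1
            wkind[s, site] = 1
            widx[s, site] = a * 2
            acp_state[a] = 2
            ev[EV_ACP_BIND1] += 1
        elif st == 2:
            for arm in range(2):
                if acp_seg[a, arm] >= 0:
                    continue
                other = acp_seg[a, 1 - arm]
                if other < 0:
                    continue
                if _ru(rs) >= p_acp:
                    continue
                ap = acp_pts[a, 1 + arm]
                s, site = _find_site(x, x[ap, 0], x[ap, 1], x[ap, 2],
                                     P[P_CAP_ACP], filid[other], active, nxt,
                                     filid, occ, cl_head, cl_next, ncx, ncy,
                                     P, 1)
                if s < 0:
                    continue
                acp_seg[a, arm] = s
                acp_site[a, arm] = site
                occ[s, site] = 1
                wkind[s, site] = 1
                widx[s, site] = a * 2 + arm
                ev[EV_ACP_BIND2] += 1
    # ---- Arp2/3 binding and branching ----
    p_arp = -math.expm1(-P[P_KP_ARP] * dtk)
    r0r = P[P_R0_ARP]
    for r in range(arp_state.shape[0]):
        st = arp_state[r]
        if st == 1:
            if counts[C_NPT_FREE] < 4 or counts[C_NFIL_FREE] < 1:
                continue
            if _ru(rs) >= p_arp:
                continue
            c = arp_pts[r, 0]
            s, site = _find_site(x, x[c, 0], x[c, 1], x[c, 2], P[P_CAP_ARP],
                                 -1, active, nxt, filid, occ, cl_head,
                                 cl_next, ncx, ncy, P, 1)
            if s < 0:
                continue
            if counts[C_POOL_FREE] - 1 < P[P_FLOOR] * counts[C_POOL_TOTAL]:
                continue
            fr = _site_frac(site)
            wx, wy, wz = _dvec(x, s, nxt[s], Lx)
            Lw = math.sqrt(wx * wx + wy * wy + wz * wz)
            if Lw < 1e-15:
                continue
            tx = wx / Lw
            ty = wy / Lw
            tz = wz / Lw
            sx = x[s, 0] + fr * wx
            sy = x[s, 1] + fr * wy
            sz = x[s, 2] + fr * wz
            dxb, dyb, dzb = _branch_dir(rs, tx, ty, tz, P[P_TH_ARP_F])
            # body normal: daughter direction minus its tangential component
            dpar = dxb * tx + dyb * ty + dzb * tz
            mxn = dxb - dpar * tx
            myn = dyb - dpar * ty
            mzn = dzb - dpar * tz
            nm = math.sqrt(mxn * mxn + myn * myn + mzn * mzn)
            if nm < 1e-12:
                continue
            mxn /= nm
            myn /= nm
            mzn /= nm
            a1 = _alloc_pt(pt_free, counts, active, gen)
            a2 = _alloc_pt(pt_free, counts, active, gen)
            x[a1, 0] = sx % Lx
            x[a1, 1] = sy
            x[a1, 2] = sz
            x[c, 0] = (sx + r0r * mxn) % Lx
            x[c, 1] = sy + r0r * myn
            x[c, 2] = sz + r0r * mzn
            x[a2, 0] = (sx + 2.0 * r0r * mxn) % Lx
            x[a2, 1] = sy + 2.0 * r0r * myn
            x[a2, 2] = sz + 2.0 * r0r * mzn
            zeta[a1] = z_arp
            zeta[a2] = z_arp
            sig[a1] = s_arp
            sig[a2] = s_arp
            arp_pts[r, 1] = a1
            arp_pts[r, 2] = a2
            arp_state[r] = 2
            arp_seg[r] = s
            arp_msite[r] = site
            occ[s, site] = 2
            wkind[s, site] = 2
            widx[s, site] = r
            g = _spawn_daughter(r, s, x[a2, 0], x[a2, 1], x[a2, 2], x,
                                active, gen, nxt, prv, filid, pt_arp,
                                pt_free, counts, fil_pt, fil_bb, fil_n,
                                fil_parent, fil_active, fil_free, arp_dfil,
                                arp_dpt, zeta, sig, rs, P, za, sa)
            if g >= 0:
                ev[EV_BRANCH] += 1
        elif st == 2:
            if arp_seg[r] < 0 and arp_dpt[r] >= 0:
                # daughter-only: free arm may rebind a new mother site
                if _ru(rs) >= p_arp:
                    continue
                a1 = arp_pts[r, 1]
                s, site = _find_site(x, x[a1, 0], x[a1, 1], x[a1, 2],
                                     P[P_CAP_ARP], arp_dfil[r], active, nxt,
                                     filid, occ, cl_head, cl_next, ncx, ncy,
                                     P, 1)
                if s < 0:
                    continue
                arp_seg[r] = s
                arp_msite[r] = site
                occ[s, site] = 2
                wkind[s, site] = 2
                widx[s, site] = r
            elif arp_seg[r] >= 0 and arp_dpt[r] < 0:
                # mother-only: re-nucleates a daughter
                if _ru(rs) >= p_arp:
                    continue
                a2 = arp_pts[r, 2]
                g = _spawn_daughter(r, arp_seg[r], x[a2, 0], x[a2, 1],
                                    x[a2, 2], x, active, gen, nxt, prv,
                                    filid, pt_arp, pt_free, counts, fil_pt,
                                    fil_bb, fil_n, fil_parent, fil_active,
                                    fil_free, arp_dfil, arp_dpt, zeta, sig,
                                    rs, P, za, sa)
                if g >= 0:
                    ev[EV_BRANCH] += 1
    # ---- motors ----
    p_bind = -math.expm1(-P[P_BIND_M] * dtk)
    for m in range(mot_state.shape[0]):
        st = mot_state[m]
        if st == 0:
            continue
        all_unbound = True
        for arm in range(8):
            if mot_bound[m, arm] >= 0:
                all_unbound = False
                break
        if all_unbound:
            # instantaneous backbone relocation onto F-actin in the motor
            # region; dormant if none is available
            nmot = counts[C_NMOTSEG]
            placed = False
            if nmot > 0:
                idx = int(_ru(rs) * nmot)
                if idx >= nmot:
                    idx = nmot - 1
                s = motsegs[idx]
                if active[s] == 1 and filid[s] >= 0 and nxt[s] >= 0:
                    site = int(_ru(rs) * SITES_PER_SEG)
                    if site >= SITES_PER_SEG:
                        site = SITES_PER_SEG - 1
                    _place_backbone(m, s, site, x, nxt, mot_pts, rs, P)
                    placed = True
                    mot_state[m] = 1
                    ev[EV_MOT_RELOC] += 1
            if not placed:
                mot_state[m] = 2
                continue
        if mot_state[m] != 1:
            continue
        for arm in range(8):
            s = mot_bound[m, arm]
            b = mot_pts[m, arm]
            if s >= 0:
                if active[s] == 0 or nxt[s] < 0:
                    mot_bound[m, arm] = -1
                    continue
                load = _arm_load(x, b, s, nxt[s], mot_site[m, arm],
                                 P[P_KS_M2], Lx)
                kw, ku = motor_rate_pair(load, P)
                walked = False
                if phase == 1 and kw > 0.0 and \
                        _ru(rs) < -math.expm1(-kw * dtk):
                    site = mot_site[m, arm]
                    if site + 1 < SITES_PER_SEG:
                        if occ[s, site + 1] == 0:
                            occ[s, site] = 0
                            wkind[s, site] = 0
                            widx[s, site] = -1
                            mot_site[m, arm] = site + 1
                            occ[s, site + 1] = 3
                            wkind[s, site + 1] = 3
                            widx[s, site + 1] = m * 8 + arm
                            walked = True
                            ev[EV_MOT_WALK] += 1
                    else:
                        q = nxt[s]
                        if nxt[q] >= 0 and occ[q, 0] == 0:
                            occ[s, site] = 0
                            wkind[s, site] = 0
                            widx[s, site] = -1
                            mot_bound[m, arm] = q
                            mot_site[m, arm] = 0
                            occ[q, 0] = 3
                            wkind[q, 0] = 3
                            widx[q, 0] = m * 8 + arm
                            walked = True
                            ev[EV_MOT_WALK] += 1
                if not walked and _ru(rs) < -math.expm1(-ku * dtk):
                    site = mot_site[m, arm]
                    occ[s, site] = 0
                    wkind[s, site] = 0
                    widx[s, site] = -1
                    mot_bound[m, arm] = -1
                    mot_site[m, arm] = -1
                    ev[EV_MOT_UNBIND] += 1
            else:
                # motors stay near the rear via relocation + 1000x drag;
                # a placed backbone binds wherever its arms reach
                if _ru(rs) >= p_bind:
                    continue
                s, site = _find_site(x, x[b, 0], x[b, 1], x[b, 2], P[P_CAP_M],
                                     -1, active, nxt, filid, occ, cl_head,
                                     cl_next, ncx, ncy, P, 1)
                if s < 0:
                    continue
                mot_bound[m, arm] = s
                mot_site[m, arm] = site
                occ[s, site] = 3
                wkind[s, site] = 3
                widx[s, site] = m * 8 + arm
                ev[EV_MOT_BIND] += 1
    # ---- nascent focal adhesions ----
    p_fa = -math.expm1(-P[P_KP_C] * dtk)
    ks_c = P[P_KS_C]
    fa_lo = P[P_FA_LO]
    fa_hi = P[P_FA_HI]
    cap_c = P[P_CAP_C]
    for n in range(m_link.shape[0]):
        pt = m_link[n]
        if pt >= 0:
            # force-dependent rupture (slip bond above the rest length)
            ex = _mi(x[pt, 0] - mx[n, 0], Lx)
            ey = x[pt, 1] - mx[n, 1]
            ez = x[pt, 2] - mx[n, 2]
            rr = math.sqrt(ex * ex + ey * ey + ez * ez)
            fmag = ks_c * abs(rr - m_link_r0[n])
            if rr >= m_link_r0[n] and fmag > 0.0:
                # clamp the exponent (and its zero-temperature limit)
                arg = 50.0
                if kbt > 0.0:
                    arg = min(P[P_LAMU_C] * fmag / kbt, 50.0)
                rate = P[P_K0U_C] * math.exp(arg)
            else:
                rate = P[P_K0U_C]
            if _ru(rs) < -math.expm1(-rate * dtk):
                m_link[n] = -1
                ev[EV_FA_RUPTURE] += 1
        else:
            ny = mx[n, 1]
            if fa_hi <= fa_lo or ny < fa_lo or ny >= fa_hi:
                continue
            if _ru(rs) >= p_fa:
                continue
            # nearest actin endpoint inside the FA region within 200 nm
            ix, iy = _cell_of(mx[n, 0], ny, Lx, P[P_LY], ncx, ncy)
            best = -1
            best_d = cap_c
            for dy in range(-2, 3):
                jy = iy + dy
                if jy < 0 or jy >= ncy:
                    continue
                for dxc in range(-2, 3):
                    jx = (ix + dxc) % ncx
                    s = cl_head[jy * ncx + jx]
                    while s >= 0:
                        if active[s] == 1 and filid[s] >= 0:
                            q = nxt[s]
                            cand = s
                            for rep in range(2):
                                if rep == 1:
                                    # barbed terminal endpoint only (interior
                                    # endpoints are another segment's key)
                                    if q < 0 or nxt[q] >= 0:
                                        break
                                    cand = q
                                cy = x[cand, 1]
                                if cy >= fa_lo and cy < fa_hi:
                                    ex = _mi(x[cand, 0] - mx[n, 0], Lx)
                                    ey = cy - mx[n, 1]
                                    ez = x[cand, 2] - mx[n, 2]
                                    d = math.sqrt(ex * ex + ey * ey + ez * ez)
                                    if d < best_d:
                                        best_d = d
                                        best = cand
                        s = cl_next[s]
            if best >= 0:
                m_link[n] = best
                m_link_r0[n] = best_d
                ev[EV_FA_FORM] += 1
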