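"""Elastic substrate mesh and nascent focal-adhesion kinetics.

The substrate is a two-dimensional equilateral triangulated mesh at z = 0:
chains of rest length ``r0_sub`` (50 nm) with extensional stiffness
``kappa_s_sub`` and interior angles restrained to 60 degrees by
``kappa_b_sub``.  Mesh nodes never move in z.  Nascent adhesions are single
elastic links between a mesh node and an actin endpoint; a link forms at rate
``k_plus_C`` when the pair is within 200 nm (both inside the FA region), is
born force-free (rest length = formation length), and ruptures as a slip
bond: ``k_u = k0_u_C exp(lambda_u_C |F| / kBT)`` when extended, ``k0_u_C``
when compressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from . import _layout as L
from .errors import ConvergenceError, DomainError
from .params import ParameterSet
from .state import SystemState

UM = 1e-6


@dataclass
class SubstrateMesh:
    """Triangulated elastic substrate at z = 0 (SI coordinates)."""

    nodes: np.ndarray          # (N, 3), z == 0
    pinned: np.ndarray         # (N,) uint8
    edges: np.ndarray          # (E, 2) int64
    triangles: np.ndarray      # (T, 3) int64
    r0: float                  # chain rest length (m)
    periodic_x: bool
    extent: tuple              # (lx, ly) in m

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


def build_mesh(lx_um: float, ly_um: float, r0_um: float = 0.05,
               periodic_x: bool = True, pin_boundary: bool = True,
               ) -> SubstrateMesh:
    """Equilateral triangulation spanning ``lx x ly`` (um) at z = 0.

    Periodic meshes wrap in x (column count rounds to fit the box) and pin
    the two extreme rows; patches pin the full boundary ring.
    """
    lx, ly, r0 = lx_um * UM, ly_um * UM, r0_um * UM
    dy = r0 * math.sqrt(3.0) / 2.0
    nrows = int(round(ly / dy)) + 1
    if periodic_x:
        ncols = max(3, int(round(lx / r0)))
        r0x = lx / ncols
    else:
        ncols = max(2, int(round(lx / r0)) + 1)
        r0x = r0
    if nrows < 2 or ncols < 2:
        raise DomainError("domain smaller than one triangle")

    def nid(r, c):
        return r * ncols + (c % ncols if periodic_x else c)

    nodes = np.zeros((nrows * ncols, 3))
    for r in range(nrows):
        off = 0.5 * (r % 2)
        for c in range(ncols):
            xx = (c + off) * r0x
            nodes[nid(r, c), 0] = xx % lx if periodic_x else xx
            nodes[nid(r, c), 1] = r * dy
    tris = []
    for r in range(nrows - 1):
        cmax = ncols if periodic_x else ncols - 1
        for c in range(cmax):
            if r % 2 == 0:
                tris.append((nid(r, c), nid(r, c + 1), nid(r + 1, c)))
                tris.append((nid(r + 1, c), nid(r + 1, c + 1), nid(r, c + 1)))
            else:
                tris.append((nid(r, c), nid(r, c + 1), nid(r + 1, c + 1)))
                tris.append((nid(r + 1, c), nid(r + 1, c + 1), nid(r, c)))
    triangles = np.array(sorted(set(tuple(t) for t in tris)), dtype=np.int64)
    eset = set()
    for a, b, c in triangles:
        for i, j in ((a, b), (b, c), (a, c)):
            eset.add((min(i, j), max(i, j)))
    edges = np.array(sorted(eset), dtype=np.int64)
    pinned = np.zeros(nrows * ncols, dtype=np.uint8)
    if pin_boundary:
        pinned[:ncols] = 1
        pinned[-ncols:] = 1
        if not periodic_x:
            for r in range(nrows):
                pinned[nid(r, 0)] = 1
                pinned[nid(r, ncols - 1)] = 1
    return SubstrateMesh(nodes, pinned, edges, triangles, r0, periodic_x,
                         (lx, ly))


def domain_mesh(params: ParameterSet) -> SubstrateMesh:
    """The engine's substrate: periodic in x, spanning the full domain."""
    lx, ly, _ = params.domain_size
    return build_mesh(lx, ly, params.r0_sub * 1e-3, periodic_x=True)


# Probe-patch extent (um).  The printed effective stiffness (~2.4e-4 N/m)
# refers to a prior-work probe protocol whose geometry is not reproduced in
# the text; this patch size is the package's calibrated default for it.
PROBE_PATCH_UM = (0.25, 0.22)


def _mesh_P(params: ParameterSet, lx_m: float) -> np.ndarray:
    P = np.zeros(L.NPARAMS)
    P[L.P_LX] = lx_m
    P[L.P_KS_SUB] = params.kappa_s_sub
    P[L.P_KB_SUB] = params.kappa_b_sub
    P[L.P_R0_SUB] = params.r0_sub * 1e-9
    P[L.P_TH_SUB] = math.radians(params.theta0_sub)
    return P


def probe_effective_stiffness(mesh: SubstrateMesh,
                              params: ParameterSet | None = None,
                              probe_force: float = 1e-12,
                              tol: float = 1e-6,
                              max_iter: int = 200_000) -> float:
    """Effective in-plane stiffness kappa_eff = |F| / |u| from a static point
    force on a central node of a relaxed, boundary-pinned mesh.

    Relaxation uses damped dynamics (FIRE) on the in-plane coordinates until
    the residual force on every free node is below ``tol`` times the applied
    load.
    """
    if params is None:
        params = ParameterSet()
    if mesh.periodic_x:
        raise DomainError("stiffness probe expects a non-periodic patch")
    P = _mesh_P(params, 1e3)  # huge Lx disables the minimum-image wrap
    nodes = mesh.nodes.copy()
    free = mesh.pinned == 0
    if not free.any():
        raise DomainError("mesh has no free nodes")
    centroid = nodes[:, :2].mean(axis=0)
    d2 = ((nodes[:, :2] - centroid) ** 2).sum(axis=1)
    d2[~free] = np.inf
    center = int(np.argmin(d2))
    x0 = nodes[center].copy()
    fvec = np.array([probe_force, 0.0, 0.0])
    F = np.zeros_like(nodes)
    v = np.zeros_like(nodes)
    # FIRE parameters
    keff_scale = params.kappa_s_sub * 4 + params.kappa_b_sub / mesh.r0 ** 2 * 6
    dt = 0.2 / math.sqrt(keff_scale)
    dt_max = 10 * dt
    alpha = 0.1
    n_pos = 0
    for it in range(max_iter):
        F[:, :] = 0.0
        K.mesh_internal_forces(nodes, F, mesh.edges, mesh.triangles, P)
        F[center] += fvec
        F[~free] = 0.0
        F[:, 2] = 0.0  # substrate plane constraint
        res = np.max(np.abs(F[free][:, :2]))
        if res <= tol * probe_force and it > 0:
            disp = np.linalg.norm(nodes[center] - x0)
            if disp <= 0:
                raise ConvergenceError("probe produced zero displacement")
            return probe_force / disp
        p = float((F * v).sum())
        if p > 0:
            n_pos += 1
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(F)
            if fn > 0:
                v = (1 - alpha) * v + alpha * vn * F / fn
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:, :] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        v += F * dt
        nodes += v * dt
        nodes[~free] = mesh.nodes[~free]
        nodes[:, 2] = 0.0
    raise ConvergenceError(
        f"stiffness probe did not converge (residual {res:.3e} N "
        f"vs target {tol * probe_force:.3e} N)")


def reference_effective_stiffness(params: ParameterSet | None = None) -> float:
    """kappa_eff of the reference substrate parameters on the default
    calibrated probe patch."""
    if params is None:
        params = ParameterSet()
    mesh = build_mesh(*PROBE_PATCH_UM, params.r0_sub * 1e-3,
                      periodic_x=False)
    return probe_effective_stiffness(mesh, params)


# ---------------------------------------------------------------------------
# adhesion-link kinetics and measurement helpers
# ---------------------------------------------------------------------------

def fa_unbind_rate(link_force_pN: float, link_length_um: float,
                   rest_length_um: float, params: ParameterSet) -> float:
    """Slip-bond rupture rate (1/s) of a nascent adhesion link."""
    k0 = params.k0_u_C
    if link_length_um < rest_length_um:
        return k0
    lam = params.lambda_u_C * 1e-9
    return k0 * math.exp(lam * abs(link_force_pN) * 1e-12 / params.kBT)


def link_forces_pN(state: SystemState) -> np.ndarray:
    """|spring force| (pN) of every live adhesion link."""
    ns = np.flatnonzero(state.m_link >= 0)
    lx = state.P[L.P_LX]
    out = np.empty(ns.size)
    for i, n in enumerate(ns):
        pt = int(state.m_link[n])
        d = state.x[pt] - state.mx[n]
        if d[0] > 0.5 * lx:
            d[0] -= lx
        elif d[0] < -0.5 * lx:
            d[0] += lx
        r = np.linalg.norm(d)
        out[i] = abs(state.P[L.P_KS_C] * (r - state.m_link_r0[n])) / 1e-12
    return out


def total_substrate_force(state: SystemState) -> float:
    """Sum of |spring force| over all live adhesion links (pN)."""
    return float(link_forces_pN(state).sum())


def adhesion_snapshot(state: SystemState) -> list[dict]:
    """Per-link records (time, node, endpoint, length um, force pN)."""
    rows = []
    lx = state.P[L.P_LX]
    for n in np.flatnonzero(state.m_link >= 0):
        pt = int(state.m_link[n])
        d = state.x[pt] - state.mx[n]
        if d[0] > 0.5 * lx:
            d[0] -= lx
        elif d[0] < -0.5 * lx:
            d[0] += lx
        r = float(np.linalg.norm(d))
        rows.append({
            "time_s": state.clock, "node": int(n), "endpoint": pt,
            "length_um": r / UM,
            "force_pN": abs(state.P[L.P_KS_C] * (r - state.m_link_r0[n]))
            / 1e-12,
        })
    return rows
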