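"""Mutable world state: points, filaments, binding agents, motors, substrate.

The state is a structure-of-arrays with fixed capacities and explicit free
stacks so the numba kernels can create and destroy segments without Python.
Positions are SI metres internally; ``*_um`` helpers convert at the API
boundary.  All randomness flows through a single xorshift128+ stream stored
in the state, which makes trajectories bit-reproducible per seed.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np

from . import _kernels as K
from . import _layout as L
from .errors import InstabilityError
from .params import ParameterSet, RegionSet, pack_kernel_params

UM = 1e-6


class SystemState:
    """Full simulation state (parameters, regions, network, substrate, RNG)."""

    def __init__(self, params: ParameterSet, regions: RegionSet | None = None,
                 seed: int = 0, mesh=None, point_capacity: int | None = None):
        self.params = params
        self.regions = regions if regions is not None else RegionSet()
        self.P = pack_kernel_params(params, self.regions)
        nt = params.n_segments_total
        npc = point_capacity or (
            2 * nt + 3 * (params.n_acp + params.n_arp)
            + 8 * params.n_motors + 256)
        nf = nt + 8
        self.x = np.zeros((npc, 3))
        self.zeta = np.ones(npc)
        self.sig = np.zeros(npc)
        self.anchored = np.zeros(npc, dtype=np.uint8)
        self.active = np.zeros(npc, dtype=np.uint8)
        self.gen = np.zeros(npc, dtype=np.int64)
        self.nxt = np.full(npc, -1, dtype=np.int64)
        self.prv = np.full(npc, -1, dtype=np.int64)
        self.filid = np.full(npc, -1, dtype=np.int64)
        self.pt_arp = np.full(npc, -1, dtype=np.int64)
        self.occ = np.zeros((npc, L.SITES_PER_SEG), dtype=np.int8)
        self.wkind = np.zeros((npc, L.SITES_PER_SEG), dtype=np.int8)
        self.widx = np.full((npc, L.SITES_PER_SEG), -1, dtype=np.int64)
        self.fil_pt = np.full(nf, -1, dtype=np.int64)
        self.fil_bb = np.full(nf, -1, dtype=np.int64)
        self.fil_n = np.zeros(nf, dtype=np.int64)
        self.fil_parent = np.full(nf, -1, dtype=np.int64)
        self.fil_active = np.zeros(nf, dtype=np.uint8)
        self.fil_free = np.arange(nf - 1, -1, -1, dtype=np.int64)
        self.pt_free = np.arange(npc - 1, -1, -1, dtype=np.int64)
        self.counts = np.zeros(L.NCOUNTS, dtype=np.int64)
        self.counts[L.C_NPT_FREE] = npc
        self.counts[L.C_NFIL_FREE] = nf
        self.counts[L.C_POOL_TOTAL] = nt
        self.counts[L.C_POOL_FREE] = nt
        na, nr, nm = max(params.n_acp, 1), max(params.n_arp, 1), \
            max(params.n_motors, 1)
        self.acp_state = np.zeros(na, dtype=np.int8)
        self.acp_pts = np.full((na, 3), -1, dtype=np.int64)
        self.acp_seg = np.full((na, 2), -1, dtype=np.int64)
        self.acp_site = np.full((na, 2), -1, dtype=np.int64)
        self.arp_state = np.zeros(nr, dtype=np.int8)
        self.arp_pts = np.full((nr, 3), -1, dtype=np.int64)
        self.arp_seg = np.full(nr, -1, dtype=np.int64)
        self.arp_msite = np.full(nr, -1, dtype=np.int64)
        self.arp_dfil = np.full(nr, -1, dtype=np.int64)
        self.arp_dpt = np.full(nr, -1, dtype=np.int64)
        self.mot_state = np.zeros(nm, dtype=np.int8)
        self.mot_pts = np.full((nm, 8), -1, dtype=np.int64)
        self.mot_bound = np.full((nm, 8), -1, dtype=np.int64)
        self.mot_site = np.full((nm, 8), -1, dtype=np.int64)
        self.set_mesh(mesh)
        self.F = np.zeros((npc, 3))
        self.pairs = np.zeros((50 * nt + 1024, 2), dtype=np.int64)
        self.motsegs = np.zeros(nt + 8, dtype=np.int64)
        cutoff = (params.r0_A + params.r_c_A + params.verlet_skin) * 1e-9
        lx, ly, _ = (d * UM for d in params.domain_size)
        self.ncx = max(1, int(lx / cutoff))
        self.ncy = max(1, int(ly / cutoff))
        self.cl_head = np.full(self.ncx * self.ncy, -1, dtype=np.int64)
        self.cl_next = np.full(npc, -1, dtype=np.int64)
        self.sevj = np.zeros(2048, dtype=np.int64)
        self.sevr = np.zeros(2048)
        self.sevn = np.zeros(1, dtype=np.int64)
        self.ev = np.zeros(L.NEVENTS, dtype=np.int64)
        self.rs = K.seed_rng_state(seed)
        self.seed = seed

    # ------------------------------------------------------------------
    def set_mesh(self, mesh) -> None:
        """Attach a substrate mesh (``substrate.SubstrateMesh``) or none."""
        self.mesh = mesh
        if mesh is None:
            self.mx = np.zeros((0, 3))
            self.m_pinned = np.zeros(0, dtype=np.uint8)
            self.m_edges = np.zeros((0, 2), dtype=np.int64)
            self.m_tri = np.zeros((0, 3), dtype=np.int64)
        else:
            self.mx = mesh.nodes
            self.m_pinned = mesh.pinned
            self.m_edges = mesh.edges
            self.m_tri = mesh.triangles
        n = self.mx.shape[0]
        self.m_link = np.full(n, -1, dtype=np.int64)
        self.m_link_r0 = np.zeros(n)
        self.mF = np.zeros((n, 3))

    # --- unit helpers --------------------------------------------------
    @property
    def clock(self) -> float:
        """Simulation time (s)."""
        return self.counts[L.C_STEP] * self.params.dt

    @property
    def x_um(self) -> np.ndarray:
        return self.x / UM

    # --- python-side builders (fixtures & initialization) --------------
    def _alloc_point(self, pos_si, zeta: float) -> int:
        self.counts[L.C_NPT_FREE] -= 1
        p = int(self.pt_free[self.counts[L.C_NPT_FREE]])
        self.active[p] = 1
        self.gen[p] += 1
        self.x[p] = pos_si
        self.zeta[p] = zeta
        kbt, dt = self.params.kBT, self.params.dt
        self.sig[p] = math.sqrt(2.0 * kbt * dt / zeta) if zeta > 0 else 0.0
        return p

    def new_filament(self, coords_um) -> int:
        """Create a filament from ordered pointed-to-barbed endpoint
        coordinates (um, shape (n_seg+1, 3)); consumes pool segments."""
        coords = np.asarray(coords_um, dtype=float) * UM
        nseg = coords.shape[0] - 1
        self.counts[L.C_NFIL_FREE] -= 1
        f = int(self.fil_free[self.counts[L.C_NFIL_FREE]])
        za = self.P[L.P_ZETA_A]
        pts = [self._alloc_point(c, za) for c in coords]
        for i, p in enumerate(pts):
            self.filid[p] = f
            if i + 1 < len(pts):
                self.nxt[p] = pts[i + 1]
                self.prv[pts[i + 1]] = p
        self.fil_active[f] = 1
        self.fil_pt[f] = pts[0]
        self.fil_bb[f] = pts[-1]
        self.fil_n[f] = nseg
        self.counts[L.C_POOL_FREE] -= nseg
        return f

    def new_acp(self, pos_um) -> int:
        a = int(np.flatnonzero(self.acp_state == 0)[0])
        p = self._alloc_point(np.asarray(pos_um, float) * UM,
                              self.P[L.P_ZETA_ACP])
        self.acp_pts[a] = (p, -1, -1)
        self.acp_state[a] = 1
        return a

    def new_arp(self, pos_um) -> int:
        r = int(np.flatnonzero(self.arp_state == 0)[0])
        p = self._alloc_point(np.asarray(pos_um, float) * UM,
                              self.P[L.P_ZETA_ARP])
        self.arp_pts[r] = (p, -1, -1)
        self.arp_state[r] = 1
        return r

    def new_motor(self, center_um, axis=(1.0, 0.0, 0.0)) -> int:
        m = int(np.flatnonzero(self.mot_state == 0)[0])
        c = np.asarray(center_um, float) * UM
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
        r0 = self.P[L.P_R0_MB]
        zb = self.P[L.P_ZETA_MB]
        lx = self.P[L.P_LX]
        for i in range(8):
            pos = c + (i - 3.5) * r0 * ax
            pos[0] %= lx
            self.mot_pts[m, i] = self._alloc_point(pos, zb)
        self.mot_state[m] = 1
        return m

    def bind_motor_arm(self, m: int, arm: int, seg_pt: int, site: int) -> None:
        self.mot_bound[m, arm] = seg_pt
        self.mot_site[m, arm] = site
        self.occ[seg_pt, site] = 3
        self.wkind[seg_pt, site] = 3
        self.widx[seg_pt, site] = m * 8 + arm

    # --- kernel plumbing -----------------------------------------------
    def _advance_args(self, phase: int, nsteps: int):
        za = self.P[L.P_ZETA_A]
        kbt, dt = self.params.kBT, self.params.dt
        sa = math.sqrt(2.0 * kbt * dt / za) if za > 0 else 0.0
        return (self.x, self.zeta, self.sig, self.anchored, self.active,
                self.gen,
                self.nxt, self.prv, self.filid, self.pt_arp,
                self.occ, self.wkind, self.widx,
                self.fil_pt, self.fil_bb, self.fil_n, self.fil_parent,
                self.fil_active, self.fil_free,
                self.pt_free, self.counts,
                self.acp_state, self.acp_pts, self.acp_seg, self.acp_site,
                self.arp_state, self.arp_pts, self.arp_seg, self.arp_msite,
                self.arp_dfil, self.arp_dpt,
                self.mot_state, self.mot_pts, self.mot_bound, self.mot_site,
                self.mx, self.m_pinned, self.m_link, self.m_link_r0,
                self.m_edges, self.m_tri, self.mF,
                self.F, self.pairs, self.motsegs, self.cl_head, self.cl_next,
                self.ncx, self.ncy,
                self.sevj, self.sevr, self.sevn,
                self.ev, self.rs, self.P, phase, nsteps, za, sa)

    def advance(self, nsteps: int, phase: int = 1) -> None:
        """Run ``nsteps`` integration steps (phase 0 = assembly, 1 = steady)."""
        ret = K.advance(*self._advance_args(phase, nsteps))
        if ret != 0:
            raise InstabilityError(
                "per-step displacement exceeded half a segment length; "
                "reduce dt or soften stiffnesses "
                f"(t = {self.clock:.4g} s)")

    def rebuild_neighbor_lists(self) -> None:
        K.rebuild_lists(self.x, self.active, self.nxt, self.filid, self.P,
                        self.counts, self.pairs, self.motsegs, self.cl_head,
                        self.cl_next, self.ncx, self.ncy)

    def compute_forces(self, walls: bool = True):
        """Deterministic forces on points (N) and mesh nodes; returns
        (F, mF) views (do not mutate)."""
        self.rebuild_neighbor_lists()
        K.compute_forces(self.x, self.F, self.active, self.anchored,
                         self.nxt, self.prv, self.filid,
                         self.acp_state, self.acp_pts, self.acp_seg,
                         self.acp_site,
                         self.arp_state, self.arp_pts, self.arp_seg,
                         self.arp_msite, self.arp_dpt,
                         self.mot_state, self.mot_pts, self.mot_bound,
                         self.mot_site,
                         self.mx, self.m_link, self.m_link_r0, self.mF,
                         self.pairs, self.counts, self.P,
                         1 if walls else 0, self.sevj, self.sevr, self.sevn)
        return self.F, self.mF

    # --- bookkeeping / diagnostics --------------------------------------
    @property
    def filament_ids(self) -> np.ndarray:
        return np.flatnonzero(self.fil_active == 1)

    def filament_points(self, f: int) -> list[int]:
        pts = []
        p = int(self.fil_pt[f])
        while p >= 0:
            pts.append(p)
            p = int(self.nxt[p])
        return pts

    @property
    def n_segments_in_filaments(self) -> int:
        return int(self.fil_n[self.fil_active == 1].sum())

    @property
    def pool_free(self) -> int:
        return int(self.counts[L.C_POOL_FREE])

    @property
    def pool_total(self) -> int:
        return int(self.counts[L.C_POOL_TOTAL])

    @property
    def incorporated_fraction(self) -> float:
        return self.n_segments_in_filaments / self.pool_total

    def actin_conserved(self) -> bool:
        return self.pool_free + self.n_segments_in_filaments == self.pool_total

    def actin_point_mask(self) -> np.ndarray:
        return (self.active == 1) & (self.filid >= 0)

    def segment_midpoints_um(self) -> np.ndarray:
        """Midpoints of all live actin segments (um); x minimum-imaged."""
        mask = self.actin_point_mask() & (self.nxt >= 0)
        ps = np.flatnonzero(mask)
        lx = self.P[L.P_LX]
        out = np.empty((ps.size, 3))
        for i, p in enumerate(ps):
            q = self.nxt[p]
            d = self.x[q] - self.x[p]
            if d[0] > 0.5 * lx:
                d[0] -= lx
            elif d[0] < -0.5 * lx:
                d[0] += lx
            out[i] = self.x[p] + 0.5 * d
        out[:, 0] %= lx
        return out / UM

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.x, self.active, self.nxt, self.prv, self.filid,
                    self.fil_pt, self.fil_n, self.counts, self.acp_state,
                    self.arp_state, self.mot_bound, self.m_link, self.mx):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()
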