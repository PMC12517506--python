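"""Model parameters, provenance, and region geometry.

The simulator describes a thin slab of lamellipodium (default 5 x 2.5 x 0.1 um)
containing a branched actin network (F-actin, Arp2/3, cross-linkers, myosin
minifilaments) on top of an elastic substrate mesh.  Every tunable constant of
the model lives in :class:`ParameterSet`; each field carries a provenance tag:

* ``"paper"`` -- the value is printed in the source study (rates, geometry,
  reference densities, calibration anchors);
* ``"default-decision"`` -- the value is this package's documented choice
  (stiffnesses, binding rate constants, numerical cadences), selected for
  physical realism and stable Euler integration at the reference time step.

User-facing units follow the field's ``units`` metadata (micrometres, seconds,
piconewtons where noted); :func:`pack_kernel_params` converts everything to SI
for the integration kernels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from typing import Iterator

import numpy as np

from . import _layout as L
from .errors import ConfigError, DomainError

AVOGADRO = 6.02214076e23


def _f(default, units: str, provenance: str, doc: str = ""):
    return field(default=default, metadata={
        "units": units, "provenance": provenance, "doc": doc})


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter ledger of the lamellipodium model."""

    # --- integration & environment ---
    dt: float = _f(1.15e-5, "s", "paper", "Brownian-dynamics time step")
    kBT: float = _f(4.142e-21, "J", "default-decision", "thermal energy (300 K)")
    mu: float = _f(0.86, "Pa*s", "default-decision", "medium viscosity")
    domain_size: tuple = _f((5.0, 2.5, 0.1), "um", "paper", "(Lx, Ly, Lz)")

    # --- composition ---
    C_A: float = _f(250.0, "uM", "paper", "actin concentration")
    R_ACP: float = _f(0.04, "-", "paper", "cross-linker : actin molar ratio")
    R_Arp: float = _f(0.01, "-", "paper", "Arp2/3 : actin molar ratio")
    R_M: float = _f(0.004, "-", "paper", "myosin : actin molar ratio")
    acp_cluster_size: int = _f(4, "-", "default-decision",
                               "alpha-actinins represented by one "
                               "cross-linker agent")
    heads_per_motor: int = _f(32, "-", "default-decision",
                              "8 arms x 4 heads: myosins per minifilament "
                              "agent")
    monomers_per_segment: int = _f(52, "-", "default-decision",
                                   "370 monomers/um over a 140-nm segment")

    # --- actin turnover ---
    k_n_A: float = _f(60.0, "1/s", "default-decision",
                      "whole-domain de novo nucleation rate; high enough "
                      "that assembly keeps the network rooted at the rear")
    k_plus_A: float = _f(12.0, "1/(uM*s)", "paper", "polymerization rate constant")
    k_minus_A: float = _f(6.0, "1/s", "paper", "depolymerization rate")
    k0_sev: float = _f(1e-45, "1/s", "paper", "zero-angle severing rate constant")
    lambda_sev: float = _f(1.0, "1/deg", "paper", "severing angle sensitivity")
    L_cap: float = _f(0.98, "um", "paper", "maximum filament length (capping)")
    monomer_floor_fraction: float = _f(0.10, "-", "paper",
                                       "free pool never drops below this")
    assembly_actin_fraction: float = _f(0.90, "-", "paper",
                                        "target incorporated fraction at assembly")
    seed_spacing: float = _f(0.25, "um", "default-decision",
                             "target x spacing of seed filaments")
    assembly_time_cap: float = _f(20.0, "s", "default-decision",
                                  "hard cap on the assembly phase")

    # --- filament geometry & mechanics ---
    r0_A: float = _f(140.0, "nm", "paper", "actin segment rest length")
    r_c_A: float = _f(7.0, "nm", "default-decision", "actin segment diameter")
    site_spacing: float = _f(7.0, "nm", "paper", "binding-site lattice spacing")
    kappa_s_A: float = _f(2e-3, "N/m", "default-decision",
                          "bond-length fluctuation sqrt(kBT/ks) ~ 1.4 nm")
    kappa_b_A: float = _f(2.7e-19, "N*m", "default-decision",
                          "persistence length ~9 um at 300 K")
    kappa_r_A: float = _f(1.7e-3, "N/m", "default-decision", "volume exclusion")

    # --- cross-linker (ACP) ---
    k_plus_ACP: float = _f(30.0, "1/s", "default-decision")
    r0_ACP: float = _f(20.0, "nm", "paper")
    kappa_s_ACP: float = _f(5e-4, "N/m", "default-decision")
    kappa_b_ACP: float = _f(4.7e-20, "N*m", "default-decision")

    # --- Arp2/3 branching ---
    k_plus_Arp: float = _f(30.0, "1/s", "default-decision")
    r0_Arp: float = _f(35.0, "nm", "paper")
    kappa_s_Arp: float = _f(5e-4, "N/m", "default-decision")
    kappa_b_Arp_c: float = _f(1e-19, "N*m", "default-decision")
    kappa_b_Arp_m: float = _f(1e-19, "N*m", "default-decision")
    kappa_b_Arp_d: float = _f(1e-19, "N*m", "default-decision")
    kappa_b_Arp_f: float = _f(1e-19, "N*m", "default-decision")
    kappa_t_Arp: float = _f(1e-19, "N*m", "default-decision")
    theta0_Arp_c: float = _f(0.0, "deg", "paper", "between the two body segments")
    theta0_Arp_m: float = _f(90.0, "deg", "paper", "body vs mother axis")
    theta0_Arp_d: float = _f(20.0, "deg", "paper", "body vs daughter axis")
    theta0_Arp_f: float = _f(70.0, "deg", "paper", "mother vs daughter axis")

    # --- motors ---
    N_h: int = _f(4, "-", "paper", "myosin heads per motor arm")
    n_arms: int = _f(8, "-", "paper", "arms per motor backbone")
    motor_bind_per_head: float = _f(40.0, "1/s", "paper",
                                    "arm binding propensity is 40*N_h")
    k20: float = _f(17.0, "1/s", "paper", "ATP-dependent head unbinding rate")
    k10_M: float = _f(2.0, "1/s", "default-decision",
                      "pre-stroke detachment rate of the arm cycle")
    k21_M: float = _f(5.0, "1/s", "default-decision", "reverse power-stroke rate")
    F_slip_M: float = _f(4.0, "pN", "default-decision",
                         "arm unbinding e-fold scale beyond stall "
                         "(catch-to-slip transition)")
    v_unloaded: float = _f(120.0, "nm/s", "paper", "unloaded arm speed anchor")
    F_stall: float = _f(5.33, "pN", "paper", "arm stall force anchor")
    r0_MB: float = _f(42.0, "nm", "paper", "backbone segment rest length")
    kappa_s_MB: float = _f(2e-3, "N/m", "default-decision", "equals kappa_s_A")
    kappa_b_MB: float = _f(5e-18, "N*m", "default-decision", "stiff backbone")
    kappa_s_M1: float = _f(2e-4, "N/m", "default-decision", "arm transverse spring")
    r0_M1: float = _f(10.0, "nm", "paper")
    kappa_s_M2: float = _f(2e-4, "N/m", "default-decision", "arm longitudinal spring")
    r0_M2: float = _f(0.0, "nm", "paper")
    motor_drag_multiplier: float = _f(1000.0, "-", "paper")
    motor_capture: float = _f(50.0, "nm", "default-decision",
                              "backbone-to-site capture distance")

    # --- substrate & adhesions ---
    kappa_s_sub: float = _f(1.0e-4, "N/m", "paper")
    kappa_b_sub: float = _f(2.4e-20, "N*m", "paper")
    r0_sub: float = _f(50.0, "nm", "paper", "mesh chain rest length")
    theta0_sub: float = _f(60.0, "deg", "paper")
    mesh_chain_diameter: float = _f(10.0, "nm", "default-decision", "for drag")
    mesh_drag_multiplier: float = _f(100.0, "-", "default-decision",
                                     "effective friction of coarse-grained "
                                     "substrate nodes; keeps the mesh "
                                     "substep stable")
    A_FA: float = _f(0.35, "-", "paper", "FA-region fraction of Ly")
    k_plus_C: float = _f(3.0, "1/s", "default-decision", "adhesion formation")
    r_capture_C: float = _f(200.0, "nm", "paper", "adhesion capture distance")
    kappa_s_C: float = _f(1e-4, "N/m", "default-decision", "adhesion link spring")
    k0_u_C: float = _f(1.0, "1/s", "default-decision",
                       "zero-force rupture rate; nascent adhesions are transient")
    lambda_u_C: float = _f(8.0, "nm", "default-decision",
                           "rupture force sensitivity length (e-fold per "
                           "~0.5 pN)")

    # --- numerics ---
    kappa_wall: float = _f(2e-3, "N/m", "default-decision",
                           "repulsive wall stiffness (equals kappa_s_A)")
    kappa_link: float = _f(5e-4, "N/m", "default-decision",
                           "ACP/Arp arm-to-site attachment spring")
    capture_margin: float = _f(1.5, "-", "default-decision",
                               "capture distance = margin * arm rest length")
    n_kin: int = _f(10, "steps", "default-decision",
                    "binding/adhesion kinetics cadence")
    n_mesh: int = _f(40, "steps", "default-decision", "mesh substep cadence")
    rebuild_every: int = _f(40, "steps", "default-decision",
                            "neighbor-list rebuild cadence; diffusive drift "
                            "over one interval stays well inside the skin")
    verlet_skin: float = _f(14.0, "nm", "default-decision")

    # ------------------------------------------------------------------
    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for fl in fields(self):
            v = getattr(self, fl.name)
            if fl.name == "domain_size":
                if len(v) != 3 or any(d <= 0 for d in v):
                    raise ConfigError("domain_size must be three positive extents")
                continue
            if isinstance(v, (int, float)) and v < 0:
                raise ConfigError(f"{fl.name} must be non-negative, got {v}")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        for name in ("A_FA", "monomer_floor_fraction", "assembly_actin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    def with_overrides(self, **overrides) -> "ParameterSet":
        """Return a copy with the given fields replaced; other fields unchanged."""
        known = {fl.name for fl in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        if "domain_size" in overrides:
            overrides["domain_size"] = tuple(overrides["domain_size"])
        return dataclasses.replace(self, **overrides)

    def provenance(self, name: str) -> str:
        (fl,) = [fl for fl in fields(self) if fl.name == name]
        return fl.metadata["provenance"]

    def items(self) -> Iterator[tuple[str, object]]:
        for fl in fields(self):
            yield fl.name, getattr(self, fl.name)

    # --- derived quantities -------------------------------------------
    @property
    def volume_litres(self) -> float:
        lx, ly, lz = self.domain_size
        return lx * ly * lz * 1e-15  # um^3 -> L

    @property
    def n_segments_total(self) -> int:
        """Total actin segment count from C_A, the domain volume and the
        monomers-per-segment convention."""
        monomers = self.C_A * 1e-6 * self.volume_litres * AVOGADRO
        return max(1, int(round(monomers / self.monomers_per_segment)))

    @property
    def uM_per_segment(self) -> float:
        return self.monomers_per_segment / (self.volume_litres * AVOGADRO) * 1e6

    @property
    def n_monomers(self) -> int:
        return self.n_segments_total * self.monomers_per_segment

    @property
    def n_acp(self) -> int:
        return int(round(self.R_ACP * self.n_monomers /
                         self.acp_cluster_size))

    @property
    def n_arp(self) -> int:
        return int(round(self.R_Arp * self.n_monomers))

    @property
    def n_motors(self) -> int:
        # R_M counts myosin molecules (two heads each); one agent lumps
        # heads_per_motor heads (8 arms x 4 heads)
        return int(round(self.R_M * self.n_monomers * 2 /
                         self.heads_per_motor))

    @property
    def n_seeds(self) -> int:
        return max(1, int(round(self.domain_size[0] / self.seed_spacing)))

    @property
    def max_segments_per_filament(self) -> int:
        # tolerance guards the exact-ratio case (0.98 / 0.14 = 7)
        return int(math.floor(self.L_cap / (self.r0_A * 1e-3) + 1e-9))


def build_reference_config(**overrides) -> ParameterSet:
    """The reference condition of the study: k_plus_A = 12 uM^-1 s^-1,
    R_ACP = 0.04, R_Arp2/3 = 0.01, k_minus_A = 6 s^-1, k0_sev = 1e-45 s^-1,
    lambda_sev = 1 deg^-1, R_M = 0.004, k20 = 17 s^-1, A_FA = 0.35, with
    C_A = 250 uM in a 5 x 2.5 x 0.1 um domain.

    Keyword overrides replace single fields; unknown names raise
    :class:`ConfigError`.
    """
    return ParameterSet().with_overrides(**overrides)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSet:
    """y-interval zones for localized dynamics, stored as fractions of Ly so
    reduced-scale domains keep the reference geometry proportions.

    Defaults reproduce the printed absolute intervals at Ly = 2.5 um:
    assembly 2.125-2.5, disassembly 0-0.375, motor 0-0.1875 um; the FA band
    has height A_FA*Ly around a configurable center (default mid-domain) and
    the flow-measurement band defaults to the assembly band.
    """

    assembly: tuple = (0.85, 1.0)
    disassembly: tuple = (0.0, 0.15)
    motor: tuple = (0.0, 0.075)
    fa_center: float = 0.5
    flow_measure: tuple = (0.85, 1.0)

    def __post_init__(self):
        for name in ("assembly", "disassembly", "motor", "flow_measure"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"region {name} must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.fa_center <= 1.0:
            raise ConfigError("fa_center must lie in [0, 1]")

    def intervals_um(self, Ly: float, A_FA: float) -> dict:
        """Absolute y-intervals in micrometres for a domain of height Ly."""
        half = 0.5 * A_FA
        fa_lo = max(0.0, self.fa_center - half) * Ly
        fa_hi = min(1.0, self.fa_center + half) * Ly
        if A_FA == 0.0:
            fa_lo = fa_hi = 0.0  # empty band
        return {
            "assembly": (self.assembly[0] * Ly, self.assembly[1] * Ly),
            "disassembly": (self.disassembly[0] * Ly, self.disassembly[1] * Ly),
            "motor": (self.motor[0] * Ly, self.motor[1] * Ly),
            "fa": (fa_lo, fa_hi),
            "flow_measure": (self.flow_measure[0] * Ly, self.flow_measure[1] * Ly),
        }


def _in_interval(y: float, lo: float, hi: float, Ly: float) -> bool:
    # half-open [lo, hi); the top interval additionally includes y == Ly
    if hi >= Ly:
        return lo <= y <= hi
    return lo <= y < hi


def region_membership(position, regions: RegionSet, params: ParameterSet) -> dict:
    """Which zones contain ``position`` (um, 3-vector)?  x is wrapped
    periodically; y/z outside the domain raise :class:`DomainError`."""
    lx, ly, lz = params.domain_size
    x, y, z = (float(c) for c in position)
    if not (0.0 <= y <= ly) or not (0.0 <= z <= lz):
        raise DomainError(f"position y/z ({y}, {z}) outside domain")
    iv = regions.intervals_um(ly, params.A_FA)
    out = {}
    for name, (lo, hi) in iv.items():
        if name == "fa" and params.A_FA == 0.0:
            out[name] = False
        else:
            out[name] = _in_interval(y, lo, hi, ly)
    return out


# ---------------------------------------------------------------------------
# Kernel packing
# ---------------------------------------------------------------------------

def pack_kernel_params(params: ParameterSet, regions: RegionSet | None = None,
                       ) -> np.ndarray:
    """Convert a :class:`ParameterSet` (+ regions) into the flat SI float64
    vector consumed by the integration kernels."""
    from .mechanics import drag_coefficient
    from .motors import calibrate_power_stroke_rate

    if regions is None:
        regions = RegionSet()
    nm, um, pN = 1e-9, 1e-6, 1e-12
    deg = math.pi / 180.0
    lx, ly, lz = (d * um for d in params.domain_size)

    P = np.zeros(L.NPARAMS, dtype=np.float64)
    P[L.P_DT] = params.dt
    P[L.P_KBT] = params.kBT
    P[L.P_LX], P[L.P_LY], P[L.P_LZ] = lx, ly, lz
    P[L.P_KS_A] = params.kappa_s_A
    P[L.P_KB_A] = params.kappa_b_A
    P[L.P_R0_A] = params.r0_A * nm
    P[L.P_RC_A] = params.r_c_A * nm
    P[L.P_KR_A] = params.kappa_r_A
    P[L.P_KS_ACP] = params.kappa_s_ACP
    P[L.P_KB_ACP] = params.kappa_b_ACP
    P[L.P_R0_ACP] = params.r0_ACP * nm
    P[L.P_KS_ARP] = params.kappa_s_Arp
    P[L.P_KB_ARP_C] = params.kappa_b_Arp_c
    P[L.P_KB_ARP_M] = params.kappa_b_Arp_m
    P[L.P_KB_ARP_D] = params.kappa_b_Arp_d
    P[L.P_KB_ARP_F] = params.kappa_b_Arp_f
    P[L.P_KT_ARP] = params.kappa_t_Arp
    P[L.P_R0_ARP] = params.r0_Arp * nm
    P[L.P_TH_ARP_M] = params.theta0_Arp_m * deg
    P[L.P_TH_ARP_D] = params.theta0_Arp_d * deg
    P[L.P_TH_ARP_F] = params.theta0_Arp_f * deg
    P[L.P_KS_MB] = params.kappa_s_MB
    P[L.P_KB_MB] = params.kappa_b_MB
    P[L.P_R0_MB] = params.r0_MB * nm
    P[L.P_KS_M1] = params.kappa_s_M1
    P[L.P_R0_M1] = params.r0_M1 * nm
    P[L.P_KS_M2] = params.kappa_s_M2
    P[L.P_KS_SUB] = params.kappa_s_sub
    P[L.P_KB_SUB] = params.kappa_b_sub
    P[L.P_R0_SUB] = params.r0_sub * nm
    P[L.P_TH_SUB] = params.theta0_sub * deg
    P[L.P_KS_C] = params.kappa_s_C
    P[L.P_K_WALL] = params.kappa_wall
    P[L.P_KP_A] = params.k_plus_A
    P[L.P_UM_PER_SEG] = params.uM_per_segment
    P[L.P_KM_A] = params.k_minus_A
    P[L.P_K0_SEV] = params.k0_sev
    P[L.P_LAM_SEV] = params.lambda_sev
    P[L.P_KN_A] = params.k_n_A
    P[L.P_KP_ACP] = params.k_plus_ACP
    P[L.P_KP_ARP] = params.k_plus_Arp
    P[L.P_KP_C] = params.k_plus_C
    P[L.P_K0U_C] = params.k0_u_C
    P[L.P_LAMU_C] = params.lambda_u_C * nm
    P[L.P_CAP_ACP] = params.capture_margin * params.r0_ACP * nm
    P[L.P_CAP_ARP] = params.capture_margin * params.r0_Arp * nm
    P[L.P_CAP_M] = params.motor_capture * nm
    P[L.P_CAP_C] = params.r_capture_C * nm
    P[L.P_BIND_M] = params.motor_bind_per_head * params.N_h
    P[L.P_K12_0] = calibrate_power_stroke_rate(params)
    P[L.P_K20] = params.k20
    P[L.P_K21] = params.k21_M
    P[L.P_K10] = params.k10_M
    P[L.P_F_STALL] = params.F_stall * pN
    P[L.P_SITE_SP] = params.site_spacing * nm
    P[L.P_FLOOR] = params.monomer_floor_fraction
    P[L.P_MAX_NSEG] = params.max_segments_per_filament
    iv = regions.intervals_um(params.domain_size[1], params.A_FA)
    P[L.P_ASM_LO], P[L.P_ASM_HI] = (v * um for v in iv["assembly"])
    P[L.P_DIS_LO], P[L.P_DIS_HI] = (v * um for v in iv["disassembly"])
    P[L.P_MOT_LO], P[L.P_MOT_HI] = (v * um for v in iv["motor"])
    P[L.P_FA_LO], P[L.P_FA_HI] = (v * um for v in iv["fa"])
    P[L.P_FLOW_LO], P[L.P_FLOW_HI] = (v * um for v in iv["flow_measure"])
    P[L.P_ZETA_A] = drag_coefficient(params.r0_A * nm, params.r_c_A * nm, params.mu)
    P[L.P_ZETA_ACP] = drag_coefficient(params.r0_ACP * nm, params.r_c_A * nm, params.mu)
    P[L.P_ZETA_ARP] = drag_coefficient(params.r0_Arp * nm, params.r_c_A * nm, params.mu)
    P[L.P_ZETA_MB] = params.motor_drag_multiplier * drag_coefficient(
        params.r0_MB * nm, params.mesh_chain_diameter * nm, params.mu)
    P[L.P_ZETA_MESH] = params.mesh_drag_multiplier * drag_coefficient(
        params.r0_sub * nm, params.mesh_chain_diameter * nm, params.mu)
    P[L.P_N_KIN] = params.n_kin
    P[L.P_N_MESH] = params.n_mesh
    P[L.P_REBUILD] = params.rebuild_every
    P[L.P_SKIN] = params.verlet_skin * nm
    P[L.P_MAX_DISP] = 0.5 * params.r0_A * nm
    P[L.P_KL_BIND] = params.kappa_link
    P[L.P_F_SLIP] = params.F_slip_M * pN
    return P
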