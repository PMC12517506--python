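"""Index layout shared between the Python state containers and the numba kernels.

Scalar model parameters are packed into a flat float64 vector ``P`` so the
hot loop receives one array instead of dozens of scalars.  Every index below
is a compile-time constant inside the kernels; keep this module free of any
heavyweight imports.
"""

# --- packed parameter vector indices ---------------------------------------
P_DT = 0            # time step (s)
P_KBT = 1           # thermal energy (J)
P_LX = 2            # domain extents (m)
P_LY = 3
P_LZ = 4
P_KS_A = 5          # actin extensional stiffness (N/m)
P_KB_A = 6          # actin bending stiffness (J/rad^2)
P_R0_A = 7          # actin segment rest length (m)
P_RC_A = 8          # actin segment diameter (m)
P_KR_A = 9          # actin-actin repulsion strength (N/m)
P_KS_ACP = 10
P_KB_ACP = 11
P_R0_ACP = 12
P_KS_ARP = 13
P_KB_ARP_C = 14     # between the two Arp2/3 body segments (straight)
P_KB_ARP_M = 15     # Arp2/3 body vs mother axis (90 deg)
P_KB_ARP_D = 16     # Arp2/3 body vs daughter axis (20 deg)
P_KB_ARP_F = 17     # mother axis vs daughter axis (70 deg)
P_KT_ARP = 18       # branch-plane torsional stiffness (J/rad^2)
P_R0_ARP = 19
P_TH_ARP_M = 20     # radians
P_TH_ARP_D = 21
P_TH_ARP_F = 22
P_KS_MB = 23        # motor backbone
P_KB_MB = 24
P_R0_MB = 25
P_KS_M1 = 26        # motor arm transverse spring (N/m)
P_R0_M1 = 27
P_KS_M2 = 28        # motor arm longitudinal spring (N/m), rest length 0
P_KS_SUB = 29       # substrate chain stiffness (N/m)
P_KB_SUB = 30       # substrate angle stiffness (N*m)
P_R0_SUB = 31
P_TH_SUB = 32       # radians (60 deg)
P_KS_C = 33         # adhesion link stiffness (N/m)
P_K_WALL = 34       # repulsive wall stiffness (N/m)
P_KP_A = 35         # polymerization rate constant (uM^-1 s^-1)
P_UM_PER_SEG = 36   # free-monomer concentration (uM) per free segment
P_KM_A = 37         # depolymerization rate (s^-1)
P_K0_SEV = 38       # zero-angle severing rate (s^-1)
P_LAM_SEV = 39      # severing angle sensitivity (deg^-1)
P_KN_A = 40         # whole-domain de novo nucleation rate (s^-1)
P_KP_ACP = 41
P_KP_ARP = 42
P_KP_C = 43         # adhesion formation rate (s^-1 per eligible node)
P_K0U_C = 44        # adhesion zero-force unbinding rate (s^-1)
P_LAMU_C = 45       # adhesion force sensitivity length (m)
P_CAP_ACP = 46      # capture distances (m)
P_CAP_ARP = 47
P_CAP_M = 48
P_CAP_C = 49
P_BIND_M = 50       # motor arm binding propensity 40*N_h (s^-1)
P_K12_0 = 51        # calibrated power-stroke rate (s^-1)
P_K20 = 52          # ATP-dependent head unbinding rate (s^-1)
P_K21 = 53
P_K10 = 54
P_F_STALL = 55      # N
P_SITE_SP = 56      # binding-site spacing (m)
P_FLOOR = 57        # monomer pool floor fraction
P_MAX_NSEG = 58     # filament cap in segments
P_ASM_LO = 59       # region y-intervals (m)
P_ASM_HI = 60
P_DIS_LO = 61
P_DIS_HI = 62
P_MOT_LO = 63
P_MOT_HI = 64
P_FA_LO = 65
P_FA_HI = 66
P_FLOW_LO = 67
P_FLOW_HI = 68
P_ZETA_A = 69       # per-endpoint drag coefficients (N s/m)
P_ZETA_ACP = 70
P_ZETA_ARP = 71
P_ZETA_MB = 72      # includes the 1000x motor drag multiplier
P_ZETA_MESH = 73
P_N_KIN = 74        # binding-kinetics sampling cadence (steps)
P_N_MESH = 75       # mesh substep cadence (steps)
P_REBUILD = 76      # neighbor-list rebuild cadence (steps)
P_SKIN = 77         # Verlet skin (m)
P_MAX_DISP = 78     # instability threshold per step (m)
P_KL_BIND = 79      # attachment-link stiffness for ACP/Arp arms (N/m)
P_F_SLIP = 80       # slip-bond force scale of arm unbinding beyond stall (N)
NPARAMS = 81

# --- event counter indices ---------------------------------------------------
EV_NUCLEATE = 0
EV_POLY = 1
EV_DEPOLY = 2
EV_SEVER = 3
EV_ACP_BIND1 = 4
EV_ACP_BIND2 = 5
EV_BRANCH = 6
EV_MOT_BIND = 7
EV_MOT_WALK = 8
EV_MOT_UNBIND = 9
EV_MOT_RELOC = 10
EV_FA_FORM = 11
EV_FA_RUPTURE = 12
NEVENTS = 13

# --- shared counters (state.counts) -----------------------------------------
C_NPT_FREE = 0      # free-point stack size
C_NFIL_FREE = 1     # free-filament stack size
C_POOL_FREE = 2     # free actin segments (monomer pool)
C_POOL_TOTAL = 3    # conserved total actin segments
C_ERROR = 4         # nonzero -> integration instability
C_NPAIRS = 5        # repulsion pair count
C_NMOTSEG = 6       # segments available in the motor region
C_STEP = 7          # steps taken since state creation
NCOUNTS = 8

SITES_PER_SEG = 20  # 140 nm / 7 nm
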