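"""Stochastic filament turnover: nucleation, polymerization,
depolymerization, angle-dependent severing, and monomer recycling.

The engine samples every event as a Bernoulli trial per candidate and time
step with p = 1 - exp(-k dt) (rates times dt are small at the reference
condition), executed in a fixed order: depolymerize -> sever -> polymerize ->
nucleate.  Rules:

* de novo nucleation drops a single segment in the xy plane at z = 0 at a
  constant whole-domain rate (during assembly, seeds appear at the -y
  boundary with +y polarity);
* polymerization adds one collinear segment at the barbed end, only inside
  the assembly region once the steady-state phase starts, never beyond the
  capping length (0.98 um = 7 segments), and never if it would push the free
  monomer pool below its 10% floor;
* depolymerization removes the pointed segment (disassembly region only in
  the steady phase); bound proteins on the removed segment lose that
  connection and may rebind;
* severing is evaluated per interior joint at the instantaneous bending
  angle with k_sev = k0_sev * exp(lambda_sev * theta); an accepted event
  removes the barbed-side segment at the triggering joint and splits the
  filament, so severing localizes where motor-driven buckling bends the
  network.

This module exposes the pure-rate functions and bookkeeping helpers; the
sampling loop itself lives in the engine kernels.
"""

from __future__ import annotations

import math

import numpy as np

from . import _layout as L
from .errors import DomainError
from .params import ParameterSet
from .state import SystemState


def severing_rate(bend_angle_deg: float, params: ParameterSet) -> float:
    """k_sev = k0_sev * exp(lambda_sev * theta), theta in degrees."""
    if not 0.0 <= bend_angle_deg <= 180.0:
        raise DomainError("bend angle must lie in [0, 180] degrees")
    return params.k0_sev * math.exp(params.lambda_sev * bend_angle_deg)


def polymerization_propensity(state: SystemState) -> float:
    """Per-barbed-end polymerization rate (1/s): k_plus_A times the free
    monomer concentration in uM."""
    return state.params.k_plus_A * state.params.uM_per_segment * \
        state.pool_free


def free_fraction(state: SystemState) -> float:
    return state.pool_free / state.pool_total


def pool_allows_consumption(state: SystemState) -> bool:
    """True if consuming one segment keeps the pool at or above its floor."""
    return state.pool_free - 1 >= \
        state.params.monomer_floor_fraction * state.pool_total


def bend_angles_deg(state: SystemState, f: int) -> np.ndarray:
    """Bending angle (deg, 0 = straight) at each interior joint of
    filament ``f``."""
    pts = state.filament_points(f)
    lx = state.P[L.P_LX]
    out = []
    for i in range(1, len(pts) - 1):
        u = state.x[pts[i]] - state.x[pts[i - 1]]
        v = state.x[pts[i + 1]] - state.x[pts[i]]
        for w in (u, v):
            if w[0] > 0.5 * lx:
                w[0] -= lx
            elif w[0] < -0.5 * lx:
                w[0] += lx
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        out.append(math.degrees(math.acos(min(1.0, max(-1.0, c)))))
    return np.asarray(out)


def filament_lengths_um(state: SystemState) -> np.ndarray:
    """Contour length (um) of every live filament."""
    r0 = state.params.r0_A * 1e-3
    return state.fil_n[state.fil_active == 1] * r0
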