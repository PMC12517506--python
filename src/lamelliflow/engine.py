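"""Scenario runner: network self-assembly, the steady-state phase, and
measurement scheduling.

A run has two phases.  During *assembly* the network self-organizes from
seed filaments rooted at the -y boundary: nucleation, polymerization (no
region gate), depolymerization, severing, cross-linking, branching, motor
and adhesion binding are all active, but motor walking is off; assembly ends
when ~90% of actin is incorporated (or at a time cap).  In the *steady*
phase walking turns on, polymerization is confined to the assembly band at
the leading edge and depolymerization to the disassembly band at the rear,
and recycled monomers feed leading-edge growth, producing the retrograde
flow.  Measurements follow the reference cadences: flow speed every 2 s,
density/CV and substrate force every 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InitializationError
from .measurement import FlowTracker, MeasurementRecord, density_profile
from .params import ParameterSet, RegionSet, build_reference_config
from .state import SystemState
from .substrate import domain_mesh, total_substrate_force


def initialize_network(params: ParameterSet, rng_seed: int = 0,
                       regions: RegionSet | None = None,
                       with_mesh: bool = True) -> SystemState:
    """Self-assemble the branched network (assembly phase, walking off).

    Seeds are evenly spaced single segments at the -y boundary with barbed
    ends toward +y; motors start inside the motor band; cross-linkers and
    Arp2/3 start uniformly distributed.  Assembly runs until the
    incorporated actin fraction reaches ``assembly_actin_fraction`` (within
    two segments) or the configured time cap.
    """
    mesh = domain_mesh(params) if with_mesh else None
    state = SystemState(params, regions, rng_seed, mesh=mesh)
    rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 0x5EED])
    lx, ly, lz = params.domain_size
    r0 = params.r0_A * 1e-3  # um
    n = params.n_seeds
    for i in range(n):
        x0 = ((i + 0.5) / n + 0.02 * (rng.random() - 0.5)) * lx % lx
        f = state.new_filament([[x0, 0.0, 0.0], [x0, r0, 0.0]])
        state.anchored[state.fil_pt[f]] = 1  # rooted at the sticky boundary
    for _ in range(params.n_acp):
        state.new_acp([rng.random() * lx, rng.random() * ly,
                       rng.random() * lz])
    for _ in range(params.n_arp):
        state.new_arp([rng.random() * lx, rng.random() * ly,
                       rng.random() * lz])
    mot_lo, mot_hi = state.regions.intervals_um(ly, params.A_FA)["motor"]
    for _ in range(params.n_motors):
        state.new_motor([rng.random() * lx,
                         mot_lo + rng.random() * max(mot_hi - mot_lo, 1e-9),
                         rng.random() * lz])
    target = params.assembly_actin_fraction - 2.0 / state.pool_total
    chunk = max(1, int(round(0.05 / params.dt)))
    max_steps = int(round(params.assembly_time_cap / params.dt))
    done = 0
    while done < max_steps:
        state.advance(min(chunk, max_steps - done), phase=0)
        done += chunk
        if state.incorporated_fraction >= target:
            break
    if state.filament_ids.size == 0:
        raise InitializationError("no filaments after assembly phase")
    return state


def step(state: SystemState, phase: int = 1) -> SystemState:
    """Advance one time step (kinetics -> forces -> Euler -> boundaries)."""
    state.advance(1, phase=phase)
    return state


@dataclass
class Scenario:
    """A configured run: parameter overrides + schedule + seed."""

    overrides: dict = field(default_factory=dict)
    duration: float = 20.0            # steady-phase duration (s)
    seed: int = 0
    flow_every: float = 2.0
    density_every: float = 1.0
    frame_every: float | None = None
    label: str = "scenario"
    base: ParameterSet | None = None
    regions: RegionSet | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def params(self) -> ParameterSet:
        base = self.base if self.base is not None else \
            build_reference_config()
        return base.with_overrides(**self.overrides)


@dataclass
class RunResult:
    state: SystemState
    record: MeasurementRecord
    frames: list


def run(scenario: Scenario) -> RunResult:
    """Assembly phase, then the steady phase with scheduled measurements."""
    params = scenario.params()
    state = initialize_network(params, scenario.seed,
                               regions=scenario.regions)
    record = MeasurementRecord()
    frames: list = []
    tracker = FlowTracker(state)
    t0 = state.clock
    dt = params.dt
    n_chunks = int(round(scenario.duration / scenario.density_every))
    steps_per_chunk = int(round(scenario.density_every / dt))
    flow_stride = max(1, int(round(scenario.flow_every /
                                   scenario.density_every)))
    frame_stride = None
    if scenario.frame_every is not None:
        frame_stride = max(1, int(round(scenario.frame_every /
                                        scenario.density_every)))
        frames.append(_frame(state, 0.0))
    for i in range(1, n_chunks + 1):
        state.advance(steps_per_chunk, phase=1)
        t = state.clock - t0
        record.add_density(t, density_profile(state))
        record.add_force(t, total_substrate_force(state),
                         int(np.sum(state.m_link >= 0)))
        if i % flow_stride == 0:
            speed, prof = tracker.finish(state)
            record.add_flow(t, speed, prof)
        if frame_stride is not None and i % frame_stride == 0:
            frames.append(_frame(state, t))
    return RunResult(state, record, frames)


def _frame(state: SystemState, t: float) -> dict:
    return {"time": t, "x_um": state.x_um.copy(),
            "active": state.active.copy(), "filid": state.filid.copy()}


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def reference_scenario(seed: int = 0, duration: float = 300.0) -> Scenario:
    """The full-scale reference condition (5 x 2.5 x 0.1 um, 300 s).
    Long-running; intended for production runs, not the test suite."""
    return Scenario(duration=duration, seed=seed, label="reference")


def reduced_scenario(seed: int = 0, duration: float = 20.0,
                     **overrides) -> Scenario:
    """Desk-scale regression preset: a 2.5 x 1.25 x 0.1 um domain at the
    reference actin density, with a 2x time step (stability margins at the
    default stiffnesses exceed 5x).  Used for qualitative regime
    comparisons (flow/CV orderings), not quantitative values."""
    base = build_reference_config(domain_size=(2.5, 1.25, 0.1),
                                  dt=4.6e-5)
    return Scenario(overrides=overrides, duration=duration, seed=seed,
                    base=base, label="reduced")
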