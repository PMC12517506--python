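"""Observables of the dynamic steady state: retrograde flow speed, 40-bin
density profiles, heterogeneity (CV), substrate force, kymographs.

Flow speed is the mean of -dy/dt over actin endpoints inside the
flow-measurement band near the +y boundary, finite-differenced across a 2-s
window (retrograde motion, toward -y, is reported positive, in nm/s).
Density is sampled every 1 s on 40 y-subdomains: the count in each bin is
normalized by N_A/40, so a uniform network gives 1 in every bin.  Network
heterogeneity is the coefficient of variation of that profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _layout as L
from .state import SystemState

N_BINS = 40


def density_profile(state: SystemState) -> np.ndarray:
    """Normalized 40-bin actin density along y (NaN profile if no actin)."""
    mids = state.segment_midpoints_um()
    ly = state.params.domain_size[1]
    if mids.shape[0] == 0:
        return np.full(N_BINS, np.nan)
    idx = np.clip((mids[:, 1] / ly * N_BINS).astype(int), 0, N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS).astype(float)
    return counts / (mids.shape[0] / N_BINS)


def heterogeneity_cv(profile: np.ndarray) -> float:
    """Standard deviation over mean of the 40-bin profile (NaN if the mean
    vanishes or the profile is missing)."""
    profile = np.asarray(profile, dtype=float)
    if np.any(np.isnan(profile)):
        return float("nan")
    m = profile.mean()
    if m == 0:
        return float("nan")
    return float(profile.std() / m)


class FlowTracker:
    """Finite-difference velocity estimation across a measurement window,
    robust to segment birth/death via per-point generation counters."""

    def __init__(self, state: SystemState):
        self.begin(state)

    def begin(self, state: SystemState) -> None:
        self.t0 = state.clock
        self.gen0 = state.gen.copy()
        self.y0 = state.x[:, 1].copy()
        self.mask0 = state.actin_point_mask()

    def finish(self, state: SystemState) -> tuple[float, np.ndarray]:
        """(mean retrograde speed in the flow band [nm/s], 40-bin profile of
        -dy/dt over all actin).  NaN where no endpoint qualifies."""
        dt = state.clock - self.t0
        valid = self.mask0 & state.actin_point_mask() & \
            (state.gen == self.gen0)
        ly = state.params.domain_size[1]
        lo = state.P[L.P_FLOW_LO] / 1e-6
        hi = state.P[L.P_FLOW_HI] / 1e-6
        y1 = state.x[:, 1] / 1e-6
        retro = -(state.x[:, 1] - self.y0) / dt / 1e-9  # nm/s, +y loss
        in_band = valid & (y1 >= lo) & \
            ((y1 < hi) | (hi >= ly) & (y1 <= hi))
        speed = float(np.mean(retro[in_band])) if in_band.any() else \
            float("nan")
        prof = np.full(N_BINS, np.nan)
        if valid.any():
            bins = np.clip((y1[valid] / ly * N_BINS).astype(int), 0,
                           N_BINS - 1)
            v = retro[valid]
            for b in range(N_BINS):
                sel = bins == b
                if sel.any():
                    prof[b] = v[sel].mean()
        self.begin(state)
        return speed, prof


@dataclass
class MeasurementRecord:
    """Time series of the paper-style observables."""

    flow_times: list = field(default_factory=list)
    flow_nm_s: list = field(default_factory=list)          # NaN = missing
    flow_profiles: list = field(default_factory=list)      # 40-bin -dy/dt
    density_times: list = field(default_factory=list)
    density_profiles: list = field(default_factory=list)   # 40-bin normalized
    cv: list = field(default_factory=list)
    force_times: list = field(default_factory=list)
    force_pN: list = field(default_factory=list)
    n_links: list = field(default_factory=list)

    def add_density(self, t: float, profile: np.ndarray) -> None:
        self.density_times.append(t)
        self.density_profiles.append(np.asarray(profile))
        self.cv.append(heterogeneity_cv(profile))

    def add_flow(self, t: float, speed: float, profile: np.ndarray) -> None:
        self.flow_times.append(t)
        self.flow_nm_s.append(speed)
        self.flow_profiles.append(np.asarray(profile))

    def add_force(self, t: float, force: float, n_links: int) -> None:
        self.force_times.append(t)
        self.force_pN.append(force)
        self.n_links.append(n_links)

    def mean_flow(self, t_min: float = 0.0) -> float:
        """Mean flow speed over windows ending at or after ``t_min``."""
        vals = [v for t, v in zip(self.flow_times, self.flow_nm_s)
                if t >= t_min and np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_cv(self, t_min: float = 0.0) -> float:
        vals = [v for t, v in zip(self.density_times, self.cv)
                if t >= t_min and np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def kymograph(record: MeasurementRecord, field_name: str = "density",
              ) -> np.ndarray:
    """Stacked profiles as a (time x 40) matrix: actin density or the
    per-bin retrograde flow."""
    src = record.density_profiles if field_name == "density" else \
        record.flow_profiles
    if not src:
        raise ValueError("record holds no profiles")
    return np.vstack(src)
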