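"""Motor-arm mechanochemistry: a three-state cycle with closed-form
walking and unbinding rates, calibrated to the printed anchors.

Each motor arm lumps ``N_h`` myosin heads into one mechanochemical unit that
cycles through three states: unbound (U), bound pre-power-stroke (B) and bound
post-power-stroke (P).  Five transition rates connect them::

    U -> B : k01   (binding; handled by the engine's arm-binding kinetics)
    B -> U : k10   (pre-stroke detachment)
    B -> P : k12(F) = k12_0 * max(0, 1 - F/F_stall)   (power stroke, load-gated)
    P -> B : k21   (reverse stroke)
    P -> U : k20   (ATP-dependent unbinding; the paper's tuning knob)

A power stroke advances the arm one 7-nm binding site toward the barbed end.
In the quasi-steady state of the bound sub-chain (re-entry after unbinding
occurs in B), the conditional occupancies obey q_P/q_B = k12/(k20 + k21),
giving closed forms for the effective per-arm rates::

    k_w(F) = k12(F) (k20 + k21) / (k12(F) + k20 + k21)
    k_u(F) = (k10 (k20 + k21) + k20 k12(F)) / (k12(F) + k20 + k21)

Because the power stroke is the only load-dependent step, walking stalls
exactly at F_stall, and under load the occupancy shifts toward B: with
k10 < k20 the mean unbinding rate *drops* with load (catch bond), and both
rates grow with k20, matching the reported trends.  The single free constant
k12_0 is calibrated in closed form so that the unloaded velocity at the
reference k20 equals the printed 120 nm/s.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, fields

import numpy as np

from .errors import ConfigError, DomainError
from .params import ParameterSet


def _reference_k20(params: ParameterSet) -> float:
    # The printed anchors (120 nm/s, 5.33 pN) hold at the *reference* k20;
    # runs that vary k20 keep the same calibrated k12_0 so speed scales with it.
    (fl,) = [f for f in fields(ParameterSet) if f.name == "k20"]
    return float(fl.default)


def calibrate_power_stroke_rate(params: ParameterSet) -> float:
    """Closed-form k12_0 such that k_w(0) * site_spacing = v_unloaded at the
    reference k20."""
    a = _reference_k20(params) + params.k21_M
    w0 = params.v_unloaded / params.site_spacing  # sites/s
    if a <= w0:
        raise ConfigError(
            "k20 + k21 must exceed the unloaded stepping rate "
            f"({w0:.2f}/s) for the arm cycle to be calibratable")
    return a * w0 / (a - w0)


def motor_rates(load_pN: float, k20: float, params: ParameterSet,
                ) -> tuple[float, float]:
    """Effective walking and unbinding rates (1/s) of a bound arm.

    ``load_pN`` is the spring-force component opposing barbed-end motion
    (positive = opposing); assisting loads are treated as zero load.
    """
    if k20 < 0:
        raise DomainError("k20 must be non-negative")
    k12_0 = calibrate_power_stroke_rate(params)
    gate = max(0.0, 1.0 - max(0.0, load_pN) / params.F_stall)
    k12 = k12_0 * gate
    a = k20 + params.k21_M
    denom = k12 + a
    k_w = k12 * a / denom
    k_u = (params.k10_M * a + k20 * k12) / denom
    over = max(0.0, load_pN) - params.F_stall
    if over > 0.0:
        k_u *= math.exp(min(over / params.F_slip_M, 30.0))
    return k_w, k_u


@dataclass(frozen=True)
class MotorRateCurve:
    """Tabulated force dependence of the arm rates at a fixed k20."""

    load_pN: np.ndarray
    k_w: np.ndarray       # steps/s
    k_u: np.ndarray       # 1/s
    k20: float
    site_spacing_nm: float

    @property
    def velocity_nm_s(self) -> np.ndarray:
        return self.k_w * self.site_spacing_nm

    def stall_force_pN(self) -> float:
        """Smallest tabulated load with zero walking rate."""
        idx = np.flatnonzero(self.k_w <= 0.0)
        if idx.size == 0:
            raise ValueError("grid does not reach stall; extend load range")
        return float(self.load_pN[idx[0]])


def rate_curve(params: ParameterSet, k20: float | None = None,
               n: int = 534, f_max_pN: float | None = None) -> MotorRateCurve:
    """Evaluate the calibrated rate curve on a uniform load grid.

    The default grid spacing (0.01 pN up to just past stall) resolves the
    stall force to the precision it is printed with.
    """
    if k20 is None:
        k20 = params.k20
    if f_max_pN is None:
        f_max_pN = params.F_stall
    loads = np.linspace(0.0, f_max_pN, n)
    kw = np.empty(n)
    ku = np.empty(n)
    for i, f in enumerate(loads):
        kw[i], ku[i] = motor_rates(float(f), k20, params)
    return MotorRateCurve(loads, kw, ku, k20, params.site_spacing)


def simulate_arm_walk(params: ParameterSet, duration: float = 10.0,
                      seed: int = 0, load_pN: float = 0.0,
                      k20: float | None = None) -> float:
    """Stochastic fixed-step walk of a single bound arm along a long straight
    filament at constant load; returns the mean velocity in nm/s.

    Stepping is a Bernoulli trial per time step with p = 1 - exp(-k_w dt),
    exactly as the engine samples it.
    """
    if k20 is None:
        k20 = params.k20
    k_w, _ = motor_rates(load_pN, k20, params)
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / params.dt))
    p = -np.expm1(-k_w * params.dt)
    hops = int(rng.binomial(n_steps, p))
    return hops * params.site_spacing / duration  # nm/s
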