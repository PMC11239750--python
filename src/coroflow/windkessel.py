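"""Coronary-bed Windkessel boundary conditions and the pulsatile hyperemic solve.

Each tree outlet is loaded by a five-element lumped model: an arterial path
(resistance Ra, compliance Ca, microcirculatory resistance Ra_micro) and a
venous path (distal resistance Rd), joined by the myocardial compliance Cmyo
whose reference pressure is the time-varying left-ventricular pressure P_LV.
The LV pressure squeezes the intramyocardial compartment in systole,
reproducing the diastolic-dominant coronary flow pattern.

State variables per outlet are the two capacitor node pressures (p1 across
Ca, p2 across Cmyo):

    q_in            = (p_out - p1) / Ra
    Ca  dp1/dt      = q_in - (p1 - p2) / Ra_micro
    Cmyo d(p2-P_LV)/dt = (p1 - p2) / Ra_micro - (p2 - p_v) / Rd

Time stepping is semi-implicit: at each step the (small, nonlinear) tree
network is solved with the capacitor pressures frozen, then the linear
two-state system is advanced with backward Euler, which is unconditionally
stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hemodynamics import DEFAULT_KT, FluidParams, OutletResistances, TreeNetwork
from .synthetic import CoronaryTree

DEFAULT_R_FRACTIONS = (0.01, 0.84, 0.15)  # Ra, Ra_micro, Rd shares of R_hyp
DEFAULT_C_FRACTIONS = (0.025, 0.975)  # Ca, Cmyo shares of C_out
TOTAL_ARTERIAL_COMPLIANCE_ML_MMHG = 1.7
DEFAULT_CORONARY_COMPLIANCE_FRACTION = 0.045


@dataclass
class WindkesselParams:
    """Per-outlet five-element coronary-bed parameters (arrays over outlets)."""

    ra: np.ndarray  # mmHg s/mL
    ca: np.ndarray  # mL/mmHg
    ra_micro: np.ndarray
    cmyo: np.ndarray
    rd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ra", "ca", "ra_micro", "cmyo", "rd"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr <= 0):
                raise ValueError(f"Windkessel parameter {name} must be positive")
            setattr(self, name, arr)

    @property
    def r_total(self) -> np.ndarray:
        return self.ra + self.ra_micro + self.rd


def split_windkessel(
    r_hyp: Sequence[float] | float,
    c_out: Sequence[float] | float,
    r_fractions: tuple[float, float, float] = DEFAULT_R_FRACTIONS,
    c_fractions: tuple[float, float] = DEFAULT_C_FRACTIONS,
) -> WindkesselParams:
    """Distribute each outlet's hyperemic resistance and compliance among the
    five Windkessel elements.  The last element takes the remainder so the
    totals are conserved exactly."""
    if len(r_fractions) != 3 or abs(sum(r_fractions) - 1.0) > 1e-12:
        raise ValueError("resistance fractions must be three values summing to 1")
    if len(c_fractions) != 2 or abs(sum(c_fractions) - 1.0) > 1e-12:
        raise ValueError("compliance fractions must be two values summing to 1")
    r = np.atleast_1d(np.asarray(r_hyp, dtype=float))
    c = np.atleast_1d(np.asarray(c_out, dtype=float))
    ra = r_fractions[0] * r
    ra_micro = r_fractions[1] * r
    rd = r - ra - ra_micro
    ca = c_fractions[0] * c
    cmyo = c - ca
    return WindkesselParams(ra=ra, ca=ca, ra_micro=ra_micro, cmyo=cmyo, rd=rd)


def distribute_compliance(
    murray_weights: Sequence[float],
    total_arterial_compliance: float = TOTAL_ARTERIAL_COMPLIANCE_ML_MMHG,
    coronary_fraction: float = DEFAULT_CORONARY_COMPLIANCE_FRACTION,
) -> np.ndarray:
    """Per-outlet compliance: a coronary portion of the total arterial
    compliance (1.7 mL/mmHg), split among outlets by Murray weights —
    peripheral compliance is taken proportional to flow."""
    w = np.asarray(murray_weights, dtype=float)
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("murray weights must be positive and sum to 1")
    return coronary_fraction * total_arterial_compliance * (w / w.sum())


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """Periodic pressure waveform sampled on a uniform phase grid in [0, 1]
    (endpoint included; first and last samples equal)."""

    phase: np.ndarray
    samples: np.ndarray
    period_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.phase.shape != self.samples.shape:
            raise ValueError("phase and samples must have the same shape")
        if abs(self.samples[0] - self.samples[-1]) > 1e-9 * max(1.0, abs(self.samples[0])):
            raise ValueError("waveform must be periodic (first and last samples equal)")

    @property
    def cycle_mean(self) -> float:
        return float(np.mean(self.samples[:-1]))

    @property
    def pulse(self) -> float:
        return float(self.samples.max() - self.samples.min())

    def at_phase(self, phi: np.ndarray | float) -> np.ndarray | float:
        return np.interp(np.mod(phi, 1.0), self.phase, self.samples)


def normalized_aortic_waveform(n: int = 801, systolic_peak: float = 0.18, notch: float = 0.42) -> Waveform:
    """Analytic normalized aortic pressure shape: a broad systolic bump with
    a smaller dicrotic wave, built from two Gaussian harmonics on a constant
    base.  Dimensionless; intended to be affinely rescaled to a patient's
    MAP and pulse pressure."""
    phi = np.linspace(0.0, 1.0, n)
    w = (
        0.35
        + 0.55 * np.exp(-(((phi - systolic_peak) / 0.11) ** 2))
        + 0.18 * np.exp(-(((phi - notch) / 0.07) ** 2))
    )
    w[-1] = w[0]
    return Waveform(phase=phi, samples=w)


def normalized_lv_waveform(n: int = 801, systolic_fraction: float = 0.35) -> Waveform:
    """Analytic normalized left-ventricular pressure: a smooth squared-sine
    systolic pulse rising from ~0 to 1, zero in diastole."""
    phi = np.linspace(0.0, 1.0, n)
    w = np.where(phi < systolic_fraction, np.sin(np.pi * phi / systolic_fraction) ** 2, 0.0)
    w[-1] = w[0]
    return Waveform(phase=phi, samples=w)


def scale_waveform(normalized: Waveform, mean_target_mmHg: float, pulse_mmHg: float, period_s: float) -> Waveform:
    """Affine rescale a normalized waveform to a prescribed cycle mean and
    pulse amplitude (max - min), attaching the cardiac period."""
    if pulse_mmHg <= 0:
        raise ValueError("pulse pressure must be positive")
    if period_s <= 0:
        raise ValueError("period must be positive")
    rng = normalized.pulse
    if rng <= 0:
        raise ValueError("cannot scale a constant waveform to a nonzero pulse")
    a = pulse_mmHg / rng
    b = mean_target_mmHg - a * normalized.cycle_mean
    return Waveform(phase=normalized.phase.copy(), samples=a * normalized.samples + b, period_s=period_s)


def scale_lv_waveform(normalized: Waveform, peak_mmHg: float, period_s: float) -> Waveform:
    """Multiplicative rescale of the LV shape so its systolic peak reaches
    ``peak_mmHg`` (diastolic value stays at the shape's baseline, ~0)."""
    if peak_mmHg <= 0 or period_s <= 0:
        raise ValueError("peak pressure and period must be positive")
    top = normalized.samples.max()
    if top <= 0:
        raise ValueError("cannot scale a non-positive waveform by its peak")
    return Waveform(phase=normalized.phase.copy(), samples=normalized.samples * (peak_mmHg / top), period_s=period_s)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def step_windkessel(
    state: tuple[np.ndarray, np.ndarray],
    p_out_mmHg: np.ndarray,
    p_lv_mmHg: np.ndarray | float,
    params: WindkesselParams,
    fluid: FluidParams,
    dt_s: float,
    dp_lv_dt: np.ndarray | float = 0.0,
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Advance the two capacitor pressures one backward-Euler step.

    ``dp_lv_dt`` is the time derivative of the LV pressure over the step (the
    myocardial capacitor rides on P_LV, so its squeeze enters as a source
    term).  Returns the new state and the inflow q_in = (p_out - p1')/Ra.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    p1, p2 = (np.atleast_1d(np.asarray(s, dtype=float)) for s in state)
    p_out = np.atleast_1d(np.asarray(p_out_mmHg, dtype=float))
    p_v = fluid.venous_pressure_mmHg
    a11 = params.ca / dt_s + 1.0 / params.ra + 1.0 / params.ra_micro
    a12 = -1.0 / params.ra_micro
    a21 = -1.0 / params.ra_micro
    a22 = params.cmyo / dt_s + 1.0 / params.ra_micro + 1.0 / params.rd
    b1 = params.ca / dt_s * p1 + p_out / params.ra
    b2 = params.cmyo / dt_s * p2 + params.cmyo * dp_lv_dt + p_v / params.rd
    det = a11 * a22 - a12 * a21
    p1_new = (b1 * a22 - a12 * b2) / det
    p2_new = (a11 * b2 - a21 * b1) / det
    q_in = (p_out - p1_new) / params.ra
    return (p1_new, p2_new), q_in


@dataclass
class SimResult:
    """Time series of a pulsatile hyperemic simulation plus bookkeeping.

    ``p_d_mmHg`` is the pressure at the distal measurement point,
    ``delta_p_mmHg`` the instantaneous trans-stenotic (lesion-segment) drop.
    The final ``steps_per_cycle`` entries form the last simulated cycle.
    """

    time_s: np.ndarray
    p_a_mmHg: np.ndarray
    p_d_mmHg: np.ndarray
    q_in_ml_s: np.ndarray
    delta_p_mmHg: np.ndarray
    outlet_flows_ml_s: np.ndarray  # (n_steps, n_outlets)
    steps_per_cycle: int
    n_cycles: int
    converged: bool
    dt_s: float

    def _last_cycle(self, arr: np.ndarray) -> np.ndarray:
        return arr[-self.steps_per_cycle:]

    @property
    def mean_p_a(self) -> float:
        return float(np.mean(self._last_cycle(self.p_a_mmHg)))

    @property
    def mean_p_d(self) -> float:
        return float(np.mean(self._last_cycle(self.p_d_mmHg)))

    @property
    def mean_q_in(self) -> float:
        return float(np.mean(self._last_cycle(self.q_in_ml_s)))

    @property
    def mean_delta_p(self) -> float:
        return float(np.mean(self._last_cycle(self.delta_p_mmHg)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "p_a_mmHg": self.p_a_mmHg,
                "p_d_mmHg": self.p_d_mmHg,
                "q_in_ml_s": self.q_in_ml_s,
            }
        )


def compute_ffr(sim: SimResult) -> float:
    """FFR = cycle-mean distal pressure over cycle-mean aortic pressure,
    both averaged over the final simulated cardiac cycle."""
    if not sim.converged:
        warnings.warn("simulation did not reach cycle periodicity; FFR may be off", stacklevel=2)
    mean_pa = sim.mean_p_a
    if mean_pa == 0:
        raise ValueError("cycle-mean aortic pressure is zero")
    return sim.mean_p_d / mean_pa


def _steady_outlet_state(
    net: TreeNetwork, wk: WindkesselParams, p_in_mmHg: float, fluid: FluidParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady network solution with full series Windkessel resistances; used
    to initialize the transient capacitor states."""
    q = net.solve_outlet_flows(p_in_mmHg, wk.r_total, np.full(len(net.outlet_ids), fluid.venous_pressure_mmHg))
    p_out = fluid.venous_pressure_mmHg + wk.r_total * q
    p1 = p_out - wk.ra * q
    p2 = p1 - wk.ra_micro * q
    return q, p1, p2


def run_hyperemic_transient(
    tree: CoronaryTree,
    wk: WindkesselParams,
    aortic_wf: Waveform,
    lv_wf: Waveform,
    fluid: FluidParams = FluidParams(),
    kt: float = DEFAULT_KT,
    dt_s: float = 0.001,
    max_cycles: int = 10,
    periodicity_tol: float = 1e-3,
    min_cycles: int = 2,
) -> SimResult:
    """Pulsatile hyperemic simulation (Scenario II).

    The scaled aortic waveform drives the inlet; each outlet is coupled to
    its five-element coronary bed.  Cycles repeat until the cycle-mean distal
    pressure changes by less than ``periodicity_tol`` (relative) or
    ``max_cycles`` is reached; non-convergence is reported on the result, not
    raised.
    """
    if aortic_wf.period_s is None or lv_wf.period_s is None:
        raise ValueError("waveforms must be scaled (period attached) before simulation")
    if abs(aortic_wf.period_s - lv_wf.period_s) > 1e-12:
        raise ValueError("aortic and LV waveforms must share the cardiac period")
    period = aortic_wf.period_s
    n_steps = int(round(period / dt_s))
    if n_steps < 8:
        raise ValueError("time step too coarse for the cardiac period")

    net = TreeNetwork(tree, fluid, kt)
    n_out = len(net.outlet_ids)
    if wk.ra.shape[0] != n_out:
        raise ValueError("Windkessel parameter count does not match tree outlets")
    if tree.measurement is None or tree.measurement.segment_id is None:
        raise ValueError("tree has no resolved measurement point")
    meas_mask = net.path_mask(tree.measurement.segment_id)
    lesion_idx = net.index_of(tree.measurement.lesion_segment_id)

    # pre-tabulate inlet and LV pressures at the (implicit) step end times
    phi = (np.arange(1, n_steps + 1) * dt_s) / period
    p_a_cycle = np.asarray(aortic_wf.at_phase(phi))
    p_lv_cycle = np.asarray(lv_wf.at_phase(phi))
    p_lv_prev_cycle = np.asarray(lv_wf.at_phase(phi - dt_s / period))
    dp_lv_cycle = (p_lv_cycle - p_lv_prev_cycle) / dt_s

    q, p1, p2 = _steady_outlet_state(net, wk, float(np.mean(p_a_cycle)), fluid)

    rec_pa, rec_pd, rec_qin, rec_dp, rec_qout = [], [], [], [], []
    prev_mean_pd = None
    converged = False
    n_cycles = 0
    for _cycle in range(max_cycles):
        n_cycles += 1
        for i in range(n_steps):
            p_in = p_a_cycle[i]
            q = net.solve_outlet_flows(p_in, wk.ra, p1, q0=q)
            p_out = p1 + wk.ra * q
            q_seg = net.M @ q
            drops = net.segment_drops(q_seg)
            p_d = p_in - float(drops[meas_mask].sum())
            rec_pa.append(p_in)
            rec_pd.append(p_d)
            rec_qin.append(float(q.sum()))
            rec_dp.append(float(drops[lesion_idx]))
            rec_qout.append(q.copy())
            (p1, p2), _ = step_windkessel((p1, p2), p_out, p_lv_cycle[i], wk, fluid, dt_s, dp_lv_cycle[i])
        mean_pd = float(np.mean(rec_pd[-n_steps:]))
        if prev_mean_pd is not None and n_cycles >= min_cycles:
            if abs(mean_pd - prev_mean_pd) <= periodicity_tol * abs(prev_mean_pd):
                converged = True
                break
        prev_mean_pd = mean_pd
    if not converged:
        warnings.warn(
            f"hyperemic transient did not reach cycle periodicity in {max_cycles} cycles",
            stacklevel=2,
        )
    time = np.arange(1, len(rec_pa) + 1) * dt_s
    return SimResult(
        time_s=time,
        p_a_mmHg=np.array(rec_pa),
        p_d_mmHg=np.array(rec_pd),
        q_in_ml_s=np.array(rec_qin),
        delta_p_mmHg=np.array(rec_dp),
        outlet_flows_ml_s=np.array(rec_qout),
        steps_per_cycle=n_steps,
        n_cycles=n_cycles,
        converged=converged,
        dt_s=dt_s,
    )


@dataclass
class SteadyResult:
    """Steady hyperemic solution (compliances open, series resistances)."""

    p_a_mmHg: float
    p_d_mmHg: float
    q_in_ml_s: float
    delta_p_mmHg: float
    outlet_flows_ml_s: np.ndarray

    @property
    def ffr(self) -> float:
        return self.p_d_mmHg / self.p_a_mmHg


def run_hyperemic_steady(
    tree: CoronaryTree,
    wk: WindkesselParams,
    map_mmHg: float,
    fluid: FluidParams = FluidParams(),
    kt: float = DEFAULT_KT,
) -> SteadyResult:
    """Steady hyperemic solve: each outlet loaded by Ra + Ra_micro + Rd to
    venous pressure.  The fast path for calibration and testing; steady FFR
    tracks the transient cycle-mean FFR closely because FFR is a ratio of
    cycle-averaged pressures."""
    net = TreeNetwork(tree, fluid, kt)
    q = net.solve_outlet_flows(
        map_mmHg, wk.r_total, np.full(len(net.outlet_ids), fluid.venous_pressure_mmHg)
    )
    q_seg = net.M @ q
    drops = net.segment_drops(q_seg)
    if tree.measurement is None or tree.measurement.segment_id is None:
        raise ValueError("tree has no resolved measurement point")
    meas_mask = net.path_mask(tree.measurement.segment_id)
    lesion_idx = net.index_of(tree.measurement.lesion_segment_id)
    p_d = map_mmHg - float(drops[meas_mask].sum())
    return SteadyResult(
        p_a_mmHg=map_mmHg,
        p_d_mmHg=p_d,
        q_in_ml_s=float(q.sum()),
        delta_p_mmHg=float(drops[lesion_idx]),
        outlet_flows_ml_s=q,
    )
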