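"""Reduced-order pressure/flow solver for coronary trees.

Replaces a 3D Navier-Stokes solution with a 0D network: each segment carries
a linear viscous resistance (Poiseuille for a plain lumen, annular Poiseuille
where the guidewire is present) plus, for stenotic segments, a Young-Tsai
style quadratic loss

    dP = R_v * q + K_t * rho / (2 A_0^2) * (A_0/A_s - 1)^2 * q * |q|

with A_0 / A_s the healthy / throat cross-sections (both reduced by the wire
cross-section when the wire runs through the segment) and K_t an empirical
turbulent-expansion coefficient (default 1.52).  Computation is in CGS;
pressures are exposed in mmHg and flows in mL/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .synthetic import CoronaryTree, StenosisSpec, WireFitError

MMHG_TO_DYN_CM2 = 1333.22  # 1 mmHg in dyn/cm^2
DEFAULT_KT = 1.52


@dataclass(frozen=True)
class FluidParams:
    """Blood rheology and reference venous pressure."""

    density: float = 1.05  # g/cm^3
    viscosity: float = 0.035  # g/(cm s) == poise
    venous_pressure_mmHg: float = 5.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0 or self.venous_pressure_mmHg <= 0:
            raise ValueError("fluid parameters must be positive")


def poiseuille_resistance(radius_cm: float, length_cm: float, fluid: FluidParams = FluidParams()) -> float:
    """Hagen-Poiseuille resistance of a straight tube, mmHg s/mL."""
    if radius_cm <= 0 or length_cm <= 0:
        raise ValueError("radius and length must be positive")
    r_cgs = 8.0 * fluid.viscosity * length_cm / (math.pi * radius_cm**4)
    return r_cgs / MMHG_TO_DYN_CM2


def annular_resistance(
    r_outer_cm: float, r_inner_cm: float, length_cm: float, fluid: FluidParams = FluidParams()
) -> float:
    """Fully developed axisymmetric flow resistance of an annulus, mmHg s/mL.

    The closed form follows from the annular Poiseuille velocity profile:
    R = 8 mu L / (pi [r_o^4 - r_i^4 - (r_o^2 - r_i^2)^2 / ln(r_o/r_i)]).
    Reduces exactly to the circular-tube value for r_inner = 0 and diverges
    as the gap closes.
    """
    if r_inner_cm < 0 or r_inner_cm >= r_outer_cm:
        raise ValueError("need 0 <= r_inner < r_outer")
    if r_inner_cm == 0.0:
        return poiseuille_resistance(r_outer_cm, length_cm, fluid)
    if length_cm <= 0:
        raise ValueError("length must be positive")
    ro2, ri2 = r_outer_cm**2, r_inner_cm**2
    geom = r_outer_cm**4 - r_inner_cm**4 - (ro2 - ri2) ** 2 / math.log(r_outer_cm / r_inner_cm)
    r_cgs = 8.0 * fluid.viscosity * length_cm / (math.pi * geom)
    return r_cgs / MMHG_TO_DYN_CM2


def _stenosis_coefficients(
    radius_cm: float,
    stenosis: StenosisSpec,
    wire_radius_cm: float,
    fluid: FluidParams,
    kt: float,
) -> tuple[float, float]:
    """Linear (mmHg s/mL) and quadratic (mmHg s^2/mL^2) loss coefficients of
    a stenotic throat, with effective areas reduced by the wire."""
    r_throat = radius_cm * math.sqrt(1.0 - stenosis.degree)
    a_wire = math.pi * wire_radius_cm**2
    a0 = math.pi * radius_cm**2 - a_wire
    a_s = math.pi * r_throat**2 - a_wire
    if a_s <= 0 or wire_radius_cm >= r_throat:
        raise WireFitError(
            f"wire does not fit: wire radius {wire_radius_cm:.4f} cm blocks the "
            f"stenotic throat (radius {r_throat:.4f} cm)"
        )
    r_v = annular_resistance(r_throat, wire_radius_cm, stenosis.stenosis_length_cm, fluid)
    k_cgs = kt * fluid.density / (2.0 * a0**2) * (a0 / a_s - 1.0) ** 2
    return r_v, k_cgs / MMHG_TO_DYN_CM2


def stenosis_pressure_drop(
    q_ml_s: float,
    stenosis: StenosisSpec,
    radius_cm: float,
    wire_present: bool = False,
    fluid: FluidParams = FluidParams(),
    kt: float = DEFAULT_KT,
    wire_diameter_cm: float = 0.036,
) -> float:
    """Trans-throat pressure drop (mmHg) of a focal stenosis at flow q (mL/s).

    Viscous term is odd in q, turbulent term has the q|q| form, so the drop
    changes sign with the flow.
    """
    r_wire = wire_diameter_cm / 2.0 if wire_present else 0.0
    r_v, k = _stenosis_coefficients(radius_cm, stenosis, r_wire, fluid, kt)
    return r_v * q_ml_s + k * q_ml_s * abs(q_ml_s)


def segment_coefficients(
    segment,
    fluid: FluidParams,
    kt: float = DEFAULT_KT,
    wire_diameter_cm: float = 0.036,
) -> tuple[float, float]:
    """Total (linear, quadratic) loss coefficients of one vessel segment:
    viscous resistance of its healthy portion (annular where the wire is
    present) plus the throat coefficients if stenotic."""
    r_wire = wire_diameter_cm / 2.0 if segment.wire_present else 0.0
    if r_wire >= segment.radius_cm:
        raise WireFitError(
            f"wire does not fit: wire radius {r_wire:.4f} cm >= lumen radius "
            f"{segment.radius_cm:.4f} cm on segment {segment.segment_id}"
        )
    if segment.stenosis is None:
        return annular_resistance(segment.radius_cm, r_wire, segment.length_cm, fluid), 0.0
    healthy_length = segment.length_cm - segment.stenosis.stenosis_length_cm
    r_lin = 0.0
    if healthy_length > 0:
        r_lin = annular_resistance(segment.radius_cm, r_wire, healthy_length, fluid)
    r_v, k = _stenosis_coefficients(segment.radius_cm, segment.stenosis, r_wire, fluid, kt)
    return r_lin + r_v, k


# ---------------------------------------------------------------------------
# Network assembly and solves
# ---------------------------------------------------------------------------

class TreeNetwork:
    """Precompiled loss coefficients and topology of a coronary tree.

    Attributes
    ----------
    segment_ids : topologically ordered segment ids (parents first).
    outlet_ids : terminal segment ids (order of all per-outlet arrays).
    M : (n_segments, n_outlets) 0/1 incidence matrix; M[s, k] = 1 iff
        segment s lies on the path from the inlet to outlet k, so segment
        flows are Q = M @ q_out.
    r_lin, k_quad : per-segment loss coefficients (mmHg s/mL, mmHg s^2/mL^2).
    """

    def __init__(
        self,
        tree: CoronaryTree,
        fluid: FluidParams = FluidParams(),
        kt: float = DEFAULT_KT,
        wire_diameter_cm: Optional[float] = None,
    ):
        self.tree = tree
        self.fluid = fluid
        if wire_diameter_cm is None:
            wire_diameter_cm = tree.wire.diameter_cm if tree.wire is not None else 0.036
        self.segment_ids = [sid for sid in _topological_order(tree)]
        self.outlet_ids = tree.outlet_ids
        self._seg_index = {sid: i for i, sid in enumerate(self.segment_ids)}
        n_seg, n_out = len(self.segment_ids), len(self.outlet_ids)
        self.M = np.zeros((n_seg, n_out))
        for k, oid in enumerate(self.outlet_ids):
            for sid in tree.path_to(oid):
                self.M[self._seg_index[sid], k] = 1.0
        coeffs = [
            segment_coefficients(tree.segments[sid], fluid, kt, wire_diameter_cm)
            for sid in self.segment_ids
        ]
        self.r_lin = np.array([c[0] for c in coeffs])
        self.k_quad = np.array([c[1] for c in coeffs])
        self.path_r_lin = self.M.T @ self.r_lin  # per-outlet series viscous resistance

    def segment_flows(self, q_out: np.ndarray) -> np.ndarray:
        return self.M @ q_out

    def segment_drops(self, q_seg: np.ndarray) -> np.ndarray:
        return self.r_lin * q_seg + self.k_quad * q_seg * np.abs(q_seg)

    def path_mask(self, segment_id: int) -> np.ndarray:
        """Boolean mask (over segments) of the inlet-to-segment path."""
        mask = np.zeros(len(self.segment_ids), dtype=bool)
        for sid in self.tree.path_to(segment_id):
            mask[self._seg_index[sid]] = True
        return mask

    def index_of(self, segment_id: int) -> int:
        return self._seg_index[segment_id]

    def solve_outlet_flows(
        self,
        p_in_mmHg: float,
        outlet_resistances: np.ndarray,
        outlet_ref_pressures: np.ndarray,
        q0: Optional[np.ndarray] = None,
        tol_mmHg: float = 1e-8,
        max_iter: int = 60,
    ) -> np.ndarray:
        """Newton solve for outlet flows with each outlet loaded by a
        resistance to a reference pressure: p_in - path drop = p_ref + R q."""
        r_out = np.asarray(outlet_resistances, dtype=float)
        p_ref = np.asarray(outlet_ref_pressures, dtype=float)
        if q0 is None:
            q = (p_in_mmHg - p_ref) / (r_out + self.path_r_lin)
        else:
            q = np.array(q0, dtype=float)
        for _ in range(max_iter):
            q_seg = self.M @ q
            drop = self.r_lin * q_seg + self.k_quad * q_seg * np.abs(q_seg)
            resid = p_in_mmHg - self.M.T @ drop - p_ref - r_out * q
            if np.max(np.abs(resid)) < tol_mmHg:
                return q
            dd = self.r_lin + 2.0 * self.k_quad * np.abs(q_seg)
            jac = -(self.M.T * dd) @ self.M - np.diag(r_out)
            q = q - np.linalg.solve(jac, resid)
        raise RuntimeError(
            f"network Newton solve did not converge; max residual {np.max(np.abs(resid)):.3e} mmHg"
        )

    def nodal_pressures(self, p_in_mmHg: float, q_out: np.ndarray) -> np.ndarray:
        """Pressure at each segment's distal node (order of segment_ids)."""
        q_seg = self.M @ q_out
        drop = self.segment_drops(q_seg)
        p = np.empty(len(self.segment_ids))
        for i, sid in enumerate(self.segment_ids):
            parent = self.tree.segments[sid].parent_id
            upstream = p_in_mmHg if parent is None else p[self._seg_index[parent]]
            p[i] = upstream - drop[i]
        return p


def _topological_order(tree: CoronaryTree) -> list[int]:
    order: list[int] = []
    frontier = [tree.inlet_id]
    while frontier:
        sid = frontier.pop(0)
        order.append(sid)
        frontier.extend(tree.children(sid))
    if len(order) != len(tree.segments):
        raise ValueError("tree is disconnected")
    return order


@dataclass
class NetworkState:
    """Result of a steady network solve: nodal pressures (distal node of each
    segment, mmHg) and segment flows (mL/s)."""

    inlet_pressure_mmHg: float
    segment_ids: list[int]
    pressures_mmHg: np.ndarray
    flows_ml_s: np.ndarray
    outlet_ids: list[int]
    outlet_pressures_mmHg: np.ndarray
    outlet_flows_ml_s: np.ndarray

    def pressure_at(self, segment_id: int) -> float:
        return float(self.pressures_mmHg[self.segment_ids.index(segment_id)])

    def flow_at(self, segment_id: int) -> float:
        return float(self.flows_ml_s[self.segment_ids.index(segment_id)])


def solve_baseline(
    tree: CoronaryTree,
    map_mmHg: float,
    allocation,
    fluid: FluidParams = FluidParams(),
    kt: float = DEFAULT_KT,
) -> NetworkState:
    """Resting steady solve with prescribed inlet pressure and outlet flows.

    On a tree the prescribed outlet flows determine every segment flow
    (junction conservation); nodal pressures follow by marching from the
    inlet at MAP and subtracting each segment's (possibly nonlinear) drop.
    """
    net = TreeNetwork(tree, fluid, kt)
    if list(allocation.outlet_ids) != net.outlet_ids:
        raise ValueError("allocation outlets do not match tree outlets")
    q_out = np.asarray(allocation.outlet_flows, dtype=float)
    q_seg = net.segment_flows(q_out)
    p = net.nodal_pressures(map_mmHg, q_out)
    out_idx = [net.index_of(oid) for oid in net.outlet_ids]
    return NetworkState(
        inlet_pressure_mmHg=map_mmHg,
        segment_ids=net.segment_ids,
        pressures_mmHg=p,
        flows_ml_s=q_seg,
        outlet_ids=net.outlet_ids,
        outlet_pressures_mmHg=p[out_idx],
        outlet_flows_ml_s=q_out,
    )


@dataclass(frozen=True)
class OutletResistances:
    """Peripheral (coronary-bed) resistances per outlet.

    ``r_bln`` comes from the resting solve, R = (p_out - p_v)/q_out; the
    hyperemic values are the baseline ones divided by the total coronary
    resistance index (TCRI) and are ``None`` until
    :func:`hyperemic_resistances` is applied.
    """

    outlet_ids: tuple[int, ...]
    r_bln: np.ndarray
    r_hyp: Optional[np.ndarray] = None
    tcri: Optional[float] = None


def baseline_outlet_resistances(state: NetworkState, fluid: FluidParams = FluidParams()) -> OutletResistances:
    """Peripheral resistances from the resting pressure/flow distribution:
    R_k = (p_out,k - p_v) / q_out,k."""
    p_v = fluid.venous_pressure_mmHg
    if np.any(state.outlet_flows_ml_s <= 0):
        raise ValueError("baseline outlet flows must be positive")
    if np.any(state.outlet_pressures_mmHg <= p_v):
        raise ValueError(
            "baseline outlet pressure at or below venous pressure "
            "(unphysiological resting state; stenosis too severe or bad inputs)"
        )
    r = (state.outlet_pressures_mmHg - p_v) / state.outlet_flows_ml_s
    return OutletResistances(outlet_ids=tuple(state.outlet_ids), r_bln=r)


def hyperemic_resistances(resist: OutletResistances, tcri: float = 3.0) -> OutletResistances:
    """Hyperemic peripheral resistances: baseline divided by TCRI.

    Refuses double application (dividing twice would model a double dose of
    vasodilator).
    """
    if tcri <= 0:
        raise ValueError("TCRI must be positive")
    if resist.r_hyp is not None:
        raise ValueError("hyperemic resistances already computed; refusing to divide twice")
    return replace(resist, r_hyp=resist.r_bln / tcri, tcri=tcri)
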