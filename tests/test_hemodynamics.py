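"""Segment resistance models, stenosis losses, and the resting network solve."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import fsolve

import coroflow as cf
from coroflow.flow import allocate
from coroflow.hemodynamics import MMHG_TO_DYN_CM2, FluidParams, TreeNetwork
from coroflow.synthetic import CoronaryTree, StenosisSpec, VesselSegment

FLUID = FluidParams()


def annular_resistance_by_quadrature(r_o: float, r_i: float, length: float, mu: float) -> float:
    """Independent oracle: integrate the annular Poiseuille velocity profile
    numerically to get the flow per unit pressure gradient, mmHg s/mL."""

    def u_over_g(r: float) -> float:
        return (1.0 / (4.0 * mu)) * (
            r_o**2 - r**2 + (r_o**2 - r_i**2) * math.log(r / r_o) / math.log(r_o / r_i)
        )

    q_over_g, _ = quad(lambda r: 2.0 * math.pi * r * u_over_g(r), r_i, r_o, limit=200)
    return (length / q_over_g) / MMHG_TO_DYN_CM2


class TestPoiseuille:
    def test_closed_form(self):
        r = cf.poiseuille_resistance(0.15, 1.0, FLUID)
        expected = 8 * 0.035 * 1.0 / (math.pi * 0.15**4) / MMHG_TO_DYN_CM2
        assert r == pytest.approx(expected, rel=1e-12)

    def test_linear_in_length(self):
        assert cf.poiseuille_resistance(0.1, 2.0) == pytest.approx(2 * cf.poiseuille_resistance(0.1, 1.0))

    def test_fourth_power_radius(self):
        assert cf.poiseuille_resistance(0.05, 1.0) == pytest.approx(16 * cf.poiseuille_resistance(0.1, 1.0))

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            cf.poiseuille_resistance(-0.1, 1.0)
        with pytest.raises(ValueError):
            cf.poiseuille_resistance(0.1, 0.0)


class TestAnnular:
    def test_zero_inner_equals_poiseuille_exactly(self):
        assert cf.annular_resistance(0.12, 0.0, 1.3) == cf.poiseuille_resistance(0.12, 1.3)

    def test_guidewire_ratio_about_2p2(self):
        ratio = cf.annular_resistance(0.1, 0.018, 1.0) / cf.poiseuille_resistance(0.1, 1.0)
        assert ratio == pytest.approx(2.2, abs=0.05)

    def test_matches_velocity_profile_quadrature(self):
        for k in (0.05, 0.18, 0.5, 0.9):
            r_o, r_i = 0.1, 0.1 * k
            closed = cf.annular_resistance(r_o, r_i, 1.0, FLUID)
            oracle = annular_resistance_by_quadrature(r_o, r_i, 1.0, FLUID.viscosity)
            assert closed == pytest.approx(oracle, rel=1e-6)

    def test_monotone_divergent_as_gap_closes(self):
        rs = [cf.annular_resistance(0.1, ri, 1.0) for ri in (0.0, 0.03, 0.06, 0.09, 0.099)]
        assert all(b > a for a, b in zip(rs, rs[1:]))
        assert rs[-1] > 100 * rs[0]

    def test_rejects_inverted_radii(self):
        with pytest.raises(ValueError):
            cf.annular_resistance(0.1, 0.1, 1.0)


class TestStenosisPressureDrop:
    def test_zero_flow_zero_drop(self):
        s = StenosisSpec(degree=0.7, stenosis_length_cm=0.5)
        assert cf.stenosis_pressure_drop(0.0, s, 0.15) == 0.0

    def test_degree_zero_matches_poiseuille(self):
        s = StenosisSpec(degree=0.0, stenosis_length_cm=0.5)
        drop = cf.stenosis_pressure_drop(2.0, s, 0.15)
        assert drop == pytest.approx(2.0 * cf.poiseuille_resistance(0.15, 0.5), rel=1e-12)

    def test_brute_force_grid(self):
        """Drop equals the independently evaluated loss formula and is
        strictly increasing, superlinear and odd in the flow."""
        s = StenosisSpec(degree=0.7, stenosis_length_cm=0.5)
        r, kt, rho = 0.15, 1.52, FLUID.density
        a0 = math.pi * r**2
        a_s = a0 * (1 - s.degree)
        r_v = cf.poiseuille_resistance(r * math.sqrt(1 - s.degree), 0.5)
        k = kt * rho / (2 * a0**2) * (a0 / a_s - 1) ** 2 / MMHG_TO_DYN_CM2
        qs = np.linspace(0.25, 8.0, 16)
        drops = [cf.stenosis_pressure_drop(q, s, r) for q in qs]
        for q, d in zip(qs, drops):
            assert d == pytest.approx(r_v * q + k * q * q, rel=1e-10)
            assert cf.stenosis_pressure_drop(-q, s, r) == pytest.approx(-d, rel=1e-12)
        assert all(b > a for a, b in zip(drops, drops[1:]))
        # superlinearity
        assert drops[-1] > 2 * cf.stenosis_pressure_drop(qs[-1] / 2, s, r)

    def test_wire_blocks_tight_throat(self):
        s = StenosisSpec(degree=0.99, stenosis_length_cm=0.2)
        with pytest.raises(cf.WireFitError):
            cf.stenosis_pressure_drop(1.0, s, 0.15, wire_present=True)


def _three_segment_tree(degree: float = 0.6) -> CoronaryTree:
    segs = {
        0: VesselSegment(0, None, 1.5, 0.15),
        1: VesselSegment(1, 0, 1.2, 0.13, stenosis=StenosisSpec(degree, 0.6)),
        2: VesselSegment(2, 0, 1.0, 0.10),
    }
    return CoronaryTree(segments=segs, inlet_id=0)


class TestSolveBaseline:
    def test_single_tube_closed_form(self, patient):
        t = cf.generate_tree(1, 0.15, seed=0)
        q = 3.0
        alloc = allocate(q, [1.0], t.outlet_ids)
        state = cf.solve_baseline(t, 90.0, alloc)
        r = cf.poiseuille_resistance(0.15, t.segments[0].length_cm)
        assert state.outlet_pressures_mmHg[0] == pytest.approx(90.0 - r * q, rel=1e-12)

    def test_symmetric_bifurcation_equal_pressures(self):
        segs = {
            0: VesselSegment(0, None, 1.0, 0.15),
            1: VesselSegment(1, 0, 1.0, 0.119),
            2: VesselSegment(2, 0, 1.0, 0.119),
        }
        t = CoronaryTree(segments=segs, inlet_id=0)
        state = cf.solve_baseline(t, 95.0, allocate(4.0, [0.5, 0.5], t.outlet_ids))
        assert state.outlet_pressures_mmHg[0] == state.outlet_pressures_mmHg[1]

    def test_stenotic_drop_composes(self):
        """Outlet pressure equals the healthy solve minus the stenosis throat
        drop at that segment's flow (segment-by-segment composition)."""
        t = _three_segment_tree(0.7)
        healthy = _three_segment_tree(0.0)
        alloc = allocate(4.0, [0.6, 0.4], t.outlet_ids)
        ps = cf.solve_baseline(t, 93.0, alloc)
        ph = cf.solve_baseline(healthy, 93.0, alloc)
        q1 = 0.6 * 4.0
        s = t.segments[1].stenosis
        extra = cf.stenosis_pressure_drop(q1, s, 0.13) - q1 * cf.poiseuille_resistance(
            0.13 * 1.0, s.stenosis_length_cm
        )
        assert ps.pressure_at(1) == pytest.approx(ph.pressure_at(1) - extra, rel=1e-10)

    def test_flow_conservation_at_junctions(self, stenotic_tree):
        alloc = allocate(4.5, [0.25] * 4, stenotic_tree.outlet_ids)
        state = cf.solve_baseline(stenotic_tree, 93.33, alloc)
        for sid in stenotic_tree.segments:
            kids = stenotic_tree.children(sid)
            if kids:
                q_parent = state.flow_at(sid)
                q_kids = sum(state.flow_at(k) for k in kids)
                assert abs(q_parent - q_kids) < 1e-9 * abs(q_parent)

    def test_matches_independent_rootfind(self):
        """Full junction-equation root-find on a 3-segment toy network agrees
        with the marching solve to 1e-8."""
        t = _three_segment_tree(0.65)
        qa, qb = 2.4, 1.6
        alloc = allocate(qa + qb, [qa / 4.0, qb / 4.0], t.outlet_ids)
        state = cf.solve_baseline(t, 93.0, alloc)

        mu, kt, rho = FLUID.viscosity, 1.52, FLUID.density

        def pois(r, L):
            return 8 * mu * L / (math.pi * r**4) / MMHG_TO_DYN_CM2

        def drop_root(q):
            return pois(0.15, 1.5) * q

        def drop_sten(q):
            r, deg, ls = 0.13, 0.65, 0.6
            a0 = math.pi * r**2
            a_s = a0 * (1 - deg)
            k = kt * rho / (2 * a0**2) * (a0 / a_s - 1) ** 2 / MMHG_TO_DYN_CM2
            return pois(r, 1.2 - ls) * q + pois(r * math.sqrt(1 - deg), ls) * q + k * q * abs(q)

        def drop_b(q):
            return pois(0.10, 1.0) * q

        def residual(p):
            p1, p2, p3 = p
            return [
                93.0 - drop_root(qa + qb) - p1,
                p1 - drop_sten(qa) - p2,
                p1 - drop_b(qb) - p3,
            ]

        p1, p2, p3 = fsolve(residual, [90.0, 80.0, 85.0], xtol=1e-12)
        assert state.pressure_at(0) == pytest.approx(p1, abs=1e-8)
        assert state.pressure_at(1) == pytest.approx(p2, abs=1e-8)
        assert state.pressure_at(2) == pytest.approx(p3, abs=1e-8)

    def test_healthy_tree_drop_vanishes_with_viscosity(self):
        t = cf.generate_tree(3, 0.15, seed=2)
        alloc = allocate(4.5, [0.25] * 4, t.outlet_ids)
        drop_full = 93.0 - cf.solve_baseline(t, 93.0, alloc).outlet_pressures_mmHg.min()
        thin = FluidParams(viscosity=0.035e-3)
        drop_thin = 93.0 - cf.solve_baseline(t, 93.0, alloc, thin).outlet_pressures_mmHg.min()
        assert drop_full > 0
        assert drop_thin < 1e-3 * drop_full


class TestOutletResistances:
    def test_arithmetic(self):
        state = cf.NetworkState(
            inlet_pressure_mmHg=93.0,
            segment_ids=[0],
            pressures_mmHg=np.array([85.0]),
            flows_ml_s=np.array([2.0]),
            outlet_ids=[0],
            outlet_pressures_mmHg=np.array([85.0]),
            outlet_flows_ml_s=np.array([2.0]),
        )
        res = cf.baseline_outlet_resistances(state)
        assert res.r_bln[0] == pytest.approx(40.0)
        # doubling flow at fixed pressures halves R
        state.outlet_flows_ml_s = np.array([4.0])
        assert cf.baseline_outlet_resistances(state).r_bln[0] == pytest.approx(20.0)

    def test_subvenous_pressure_rejected(self):
        state = cf.NetworkState(
            inlet_pressure_mmHg=93.0,
            segment_ids=[0],
            pressures_mmHg=np.array([4.0]),
            flows_ml_s=np.array([2.0]),
            outlet_ids=[0],
            outlet_pressures_mmHg=np.array([4.0]),
            outlet_flows_ml_s=np.array([2.0]),
        )
        with pytest.raises(ValueError, match="venous"):
            cf.baseline_outlet_resistances(state)

    def test_hyperemia_divides_by_tcri(self):
        res = cf.OutletResistances(outlet_ids=(0,), r_bln=np.array([40.0]))
        hyp = cf.hyperemic_resistances(res, 3.0)
        assert hyp.r_hyp[0] == 40.0 / 3.0
        assert cf.hyperemic_resistances(res, 1.0).r_hyp[0] == 40.0

    def test_double_application_guarded(self):
        res = cf.hyperemic_resistances(cf.OutletResistances(outlet_ids=(0,), r_bln=np.array([40.0])))
        with pytest.raises(ValueError, match="twice"):
            cf.hyperemic_resistances(res)

    def test_nonpositive_tcri_rejected(self):
        res = cf.OutletResistances(outlet_ids=(0,), r_bln=np.array([40.0]))
        with pytest.raises(ValueError):
            cf.hyperemic_resistances(res, 0.0)
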