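"""The paired guidewire study: pipeline orchestration and diagnostic statistics.

For every lesion the full prediction pipeline runs twice — once on the bare
tree (wire-absent, FFR_pred) and once with the pressure guidewire inserted
from the ostium past the lesion (wire-included, gFFR_pred) — under each
requested flow-distribution setup.  Peripheral resistances are always
calibrated from the wire-absent resting state (clinically there is no wire
at rest) and reused for both configurations, so the two runs differ only in
epicardial geometry.

Results are summarised per severity class (mean percentage FFR drop, rise in
trans-stenotic pressure drop, drop in hyperemic inflow when the wire is
added) and evaluated against invasive FFR with Bland-Altman agreement,
2x2 diagnostic indices at the 0.8 cutoff, and ROC AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import windkessel as wk_mod
from .config import PipelineConfig
from .hemodynamics import (
    FluidParams,
    baseline_outlet_resistances,
    hyperemic_resistances,
    solve_baseline,
)
from .synthetic import (
    CohortLesion,
    CoronaryTree,
    classify_ffr,
    insert_guidewire,
    resolve_measurement,
)

FLOW_SETUPS = ("murray", "length_based")


@dataclass
class PredictionResult:
    """Single pipeline run on one tree: predicted FFR plus the cycle-mean
    trans-stenotic drop (mmHg) and inlet flow (mL/s)."""

    ffr: float
    delta_p_mmHg: float
    inflow_ml_s: float
    mode: str
    converged: bool = True


def _fluid_from(config: PipelineConfig) -> FluidParams:
    return FluidParams(
        density=config.fluid.density,
        viscosity=config.fluid.viscosity,
        venous_pressure_mmHg=config.fluid.venous_pressure_mmHg,
    )


def _ensure_measurement(tree: CoronaryTree, config: PipelineConfig) -> CoronaryTree:
    if tree.measurement is not None and tree.measurement.segment_id is not None:
        return tree
    out = tree.copy()
    out.measurement = resolve_measurement(out, out.inlet_id, config.measurement.distal_offset_cm)
    return out


def predict_lesion(
    tree: CoronaryTree,
    patient,
    config: Optional[PipelineConfig] = None,
    *,
    wire: bool = False,
    mode: Optional[str] = None,
    flow_method: Optional[str] = None,
) -> PredictionResult:
    """Run the full FFR prediction pipeline on one (possibly stenotic) tree.

    Steps: total resting flow from CO -> outlet split (Murray or
    stem-and-crown) -> resting steady solve at MAP -> peripheral resistances
    (baseline, then divided by TCRI for hyperemia) -> compliance split ->
    hyperemic solve (pulsatile Windkessel-coupled, or the steady fast path)
    -> FFR from cycle-mean pressures.  ``wire=True`` inserts the guidewire
    before the hyperemic solve; the resting calibration stays wire-absent.
    """
    if config is None:
        config = PipelineConfig()
    mode = mode or config.study.mode
    method = flow_method or config.flow.method
    fluid = _fluid_from(config)
    tree = _ensure_measurement(tree, config)

    # Steps 1-2: total resting coronary flow, split among outlets
    q_cor = flow_mod.total_coronary_flow(patient.co_l_min, config.flow.q_cor_fraction_of_co)
    weights = flow_mod.distribution_weights(tree, method, config.flow.murray_exponent)
    allocation = flow_mod.allocate(q_cor, weights, tree.outlet_ids)

    # Step 3: resting solve, prescribed inlet pressure and outlet flows
    baseline = solve_baseline(tree, patient.map_mmHg, allocation, fluid, config.stenosis.kt)

    # Steps 4-5: peripheral resistances at rest, then hyperemia via TCRI
    resist = baseline_outlet_resistances(baseline, fluid)
    resist = hyperemic_resistances(resist, config.hyperemia.tcri)

    # Compliances are split by Murray weights regardless of the flow setup
    murray_w = flow_mod.murray_fractions(
        flow_mod.outlet_diameters(tree), config.flow.murray_exponent
    )
    c_out = wk_mod.distribute_compliance(
        murray_w,
        config.windkessel.total_arterial_compliance,
        config.windkessel.coronary_compliance_fraction,
    )
    wk = wk_mod.split_windkessel(
        resist.r_hyp, c_out, config.windkessel.r_fractions, config.windkessel.c_fractions
    )

    if wire:
        from .synthetic import WireSpec, default_wire_path

        spec = WireSpec(
            path=default_wire_path(tree, config.wire.path_mode),
            diameter_cm=config.wire.diameter_cm,
        )
        sim_tree = insert_guidewire(tree, spec)
    else:
        sim_tree = tree

    # Steps 6-7: hyperemic solve and FFR extraction
    if mode == "steady":
        res = wk_mod.run_hyperemic_steady(sim_tree, wk, patient.map_mmHg, fluid, config.stenosis.kt)
        return PredictionResult(
            ffr=res.ffr, delta_p_mmHg=res.delta_p_mmHg, inflow_ml_s=res.q_in_ml_s, mode="steady"
        )
    if mode != "transient":
        raise ValueError(f"unknown pipeline mode {mode!r}")
    aortic = wk_mod.scale_waveform(
        wk_mod.normalized_aortic_waveform(),
        patient.map_mmHg,
        patient.pulse_pressure_mmHg,
        patient.cycle_duration_s,
    )
    lv = wk_mod.scale_lv_waveform(
        wk_mod.normalized_lv_waveform(),
        patient.map_mmHg + patient.pulse_pressure_mmHg / 2.0,  # systolic pressure proxy
        patient.cycle_duration_s,
    )
    sim = wk_mod.run_hyperemic_transient(
        sim_tree,
        wk,
        aortic,
        lv,
        fluid,
        config.stenosis.kt,
        dt_s=config.transient.dt_s,
        max_cycles=config.transient.max_cycles,
        periodicity_tol=config.transient.periodicity_tol,
    )
    return PredictionResult(
        ffr=wk_mod.compute_ffr(sim),
        delta_p_mmHg=sim.mean_delta_p,
        inflow_ml_s=sim.mean_q_in,
        mode="transient",
        converged=sim.converged,
    )


# ---------------------------------------------------------------------------
# Paired study
# ---------------------------------------------------------------------------

@dataclass
class LesionResult:
    """Paired wire-absent/wire-included prediction for one lesion and setup."""

    lesion_id: int
    ffr_id: int
    flow_setup: str
    ffr_pred: float  # wire-absent
    gffr_pred: float  # wire-included
    delta_p_abs_mmHg: float
    delta_p_wire_mmHg: float
    inflow_abs_ml_s: float
    inflow_wire_ml_s: float
    ffr_class: Optional[int] = None
    ffr_invasive: Optional[float] = None
    failed: bool = False
    failure_reason: str = ""

    @property
    def ffr_drop_pct(self) -> float:
        return 100.0 * (self.ffr_pred - self.gffr_pred) / self.ffr_pred

    @property
    def delta_p_rise_pct(self) -> float:
        return 100.0 * (self.delta_p_wire_mmHg - self.delta_p_abs_mmHg) / self.delta_p_abs_mmHg

    @property
    def inflow_drop_pct(self) -> float:
        return 100.0 * (self.inflow_abs_ml_s - self.inflow_wire_ml_s) / self.inflow_abs_ml_s


def paired_wire_study(
    cohort: Sequence[CohortLesion],
    flow_setups: Sequence[str] = FLOW_SETUPS,
    config: Optional[PipelineConfig] = None,
    mode: Optional[str] = None,
) -> list[LesionResult]:
    """Run the paired wire-absent/wire-included pipeline over a cohort.

    Each lesion is simulated under every requested flow setup with and
    without the guidewire on an identical tree.  Per-lesion failures are
    recorded (``failed=True``) and the study continues.
    """
    if config is None:
        config = PipelineConfig()
    results: list[LesionResult] = []
    for lesion in cohort:
        for setup in flow_setups:
            try:
                absent = predict_lesion(
                    lesion.tree, lesion.patient, config, wire=False, mode=mode, flow_method=setup
                )
                included = predict_lesion(
                    lesion.tree, lesion.patient, config, wire=True, mode=mode, flow_method=setup
                )
                results.append(
                    LesionResult(
                        lesion_id=lesion.lesion_id,
                        ffr_id=lesion.ffr_id,
                        flow_setup=setup,
                        ffr_pred=absent.ffr,
                        gffr_pred=included.ffr,
                        delta_p_abs_mmHg=absent.delta_p_mmHg,
                        delta_p_wire_mmHg=included.delta_p_mmHg,
                        inflow_abs_ml_s=absent.inflow_ml_s,
                        inflow_wire_ml_s=included.inflow_ml_s,
                        ffr_class=lesion.ffr_class,
                        ffr_invasive=lesion.ffr_invasive,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - study must survive lesion failures
                results.append(
                    LesionResult(
                        lesion_id=lesion.lesion_id,
                        ffr_id=lesion.ffr_id,
                        flow_setup=setup,
                        ffr_pred=math.nan,
                        gffr_pred=math.nan,
                        delta_p_abs_mmHg=math.nan,
                        delta_p_wire_mmHg=math.nan,
                        inflow_abs_ml_s=math.nan,
                        inflow_wire_ml_s=math.nan,
                        ffr_class=lesion.ffr_class,
                        ffr_invasive=lesion.ffr_invasive,
                        failed=True,
                        failure_reason=str(exc),
                    )
                )
    return results


def results_frame(results: Sequence[LesionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "lesion_id": r.lesion_id,
            "ffr_id": r.ffr_id,
            "flow_setup": r.flow_setup,
            "ffr_pred": r.ffr_pred,
            "gffr_pred": r.gffr_pred,
            "delta_p_abs_mmHg": r.delta_p_abs_mmHg,
            "delta_p_wire_mmHg": r.delta_p_wire_mmHg,
            "inflow_abs_ml_s": r.inflow_abs_ml_s,
            "inflow_wire_ml_s": r.inflow_wire_ml_s,
            "ffr_class": r.ffr_class,
            "ffr_invasive": r.ffr_invasive,
            "failed": r.failed,
            "failure_reason": r.failure_reason,
        }
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClassAggregate:
    """Per-class mean percentage wire effects for one flow setup."""

    flow_setup: str
    ffr_class: int
    n: int
    mean_ffr_drop_pct: Optional[float]
    mean_delta_p_rise_pct: Optional[float]
    mean_inflow_drop_pct: Optional[float]

    @property
    def missing(self) -> bool:
        return self.n == 0


def class_aggregates(results: Sequence[LesionResult]) -> list[ClassAggregate]:
    """Mean percentage FFR drop, trans-stenotic pressure-drop rise and
    hyperemic inflow drop after wire insertion, per severity class and flow
    setup.  Classes come from the invasive FFR where available, otherwise
    from the wire-absent predicted FFR; empty classes are flagged missing."""
    setups = sorted({r.flow_setup for r in results})
    aggregates: list[ClassAggregate] = []
    for setup in setups:
        for cls in (1, 2, 3, 4):
            members = [
                r
                for r in results
                if r.flow_setup == setup
                and not r.failed
                and (r.ffr_class if r.ffr_class is not None else classify_ffr(r.ffr_pred)) == cls
            ]
            if not members:
                aggregates.append(ClassAggregate(setup, cls, 0, None, None, None))
                continue
            aggregates.append(
                ClassAggregate(
                    flow_setup=setup,
                    ffr_class=cls,
                    n=len(members),
                    mean_ffr_drop_pct=float(np.mean([r.ffr_drop_pct for r in members])),
                    mean_delta_p_rise_pct=float(np.mean([r.delta_p_rise_pct for r in members])),
                    mean_inflow_drop_pct=float(np.mean([r.inflow_drop_pct for r in members])),
                )
            )
    return aggregates


def aggregates_frame(aggregates: Sequence[ClassAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "flow_setup": a.flow_setup,
                "ffr_class": a.ffr_class,
                "n": a.n,
                "mean_ffr_drop_pct": a.mean_ffr_drop_pct,
                "mean_delta_p_rise_pct": a.mean_delta_p_rise_pct,
                "mean_inflow_drop_pct": a.mean_inflow_drop_pct,
            }
            for a in aggregates
        ]
    )


# ---------------------------------------------------------------------------
# Diagnostic statistics
# ---------------------------------------------------------------------------

def bland_altman(
    pred: Sequence[float],
    invasive: Sequence[float],
    direction: str = "invasive_minus_pred",
) -> tuple[float, float]:
    """Bland-Altman agreement: (bias, SD) of the paired differences.

    With the default direction the differences are invasive - predicted, so
    a positive bias means the model under-predicts the invasive FFR on
    average; 'pred_minus_invasive' flips the sign.  SD uses the n-1
    denominator.  Outputs are always labelled with the direction used.
    """
    p = np.asarray(pred, dtype=float)
    v = np.asarray(invasive, dtype=float)
    if p.shape != v.shape:
        raise ValueError("paired vectors must have equal length")
    if p.size < 2:
        raise ValueError("need at least two pairs")
    if direction == "invasive_minus_pred":
        diff = v - p
    elif direction == "pred_minus_invasive":
        diff = p - v
    else:
        raise ValueError(f"unknown difference direction {direction!r}")
    return float(diff.mean()), float(diff.std(ddof=1))


@dataclass
class DiagnosticIndices:
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0


def diagnostic_indices(
    pred: Sequence[float], invasive: Sequence[float], cutoff: float = 0.8
) -> DiagnosticIndices:
    """2x2 diagnostic indices at the FFR cutoff (positive: FFR <= cutoff).

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
    (TP+TN)/total.  An index with a zero denominator is reported as None
    (undefined), never coerced to 0 or 1.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    p = np.asarray(pred, dtype=float)
    v = np.asarray(invasive, dtype=float)
    if p.shape != v.shape:
        raise ValueError("paired vectors must have equal length")
    pred_pos = p <= cutoff
    true_pos = v <= cutoff
    tp = int(np.sum(pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / p.size if p.size > 0 else None
    return DiagnosticIndices(sens, spec, acc, tp=tp, tn=tn, fp=fp, fn=fn)


def roc_auc(pred: Sequence[float], invasive: Sequence[float], cutoff: float = 0.8) -> float:
    """Area under the ROC curve for detecting invasively positive lesions
    (invasive FFR <= cutoff) from the predicted FFR.

    Lower predicted FFR argues for disease, so the score is 1 - FFR_pred.
    Computed by the trapezoidal sweep over all distinct prediction
    cut-points; equals the pairwise concordance probability with ties
    counting one half.
    """
    from sklearn.metrics import roc_auc_score

    p = np.asarray(pred, dtype=float)
    v = np.asarray(invasive, dtype=float)
    if p.shape != v.shape:
        raise ValueError("paired vectors must have equal length")
    truth = (v <= cutoff).astype(int)
    if truth.min() == truth.max():
        raise ValueError("invasive labels are single-class; ROC undefined")
    return float(roc_auc_score(truth, 1.0 - p))


def diagnostics_table(
    results: Sequence[LesionResult], cutoff: float = 0.8
) -> pd.DataFrame:
    """Diagnostic indices, Bland-Altman agreement and AUC versus invasive
    FFR, per flow setup and wire state (mirrors the study's summary table)."""
    rows = []
    for setup in sorted({r.flow_setup for r in results}):
        sub = [r for r in results if r.flow_setup == setup and not r.failed and r.ffr_invasive is not None]
        if not sub:
            continue
        invasive = [r.ffr_invasive for r in sub]
        for label, preds in (
            ("wire_absent", [r.ffr_pred for r in sub]),
            ("wire_included", [r.gffr_pred for r in sub]),
        ):
            idx = diagnostic_indices(preds, invasive, cutoff)
            bias, sd = bland_altman(preds, invasive)
            try:
                auc = roc_auc(preds, invasive, cutoff)
            except ValueError:
                auc = math.nan
            rows.append(
                {
                    "flow_setup": setup,
                    "model": label,
                    "n": len(sub),
                    "sensitivity": idx.sensitivity,
                    "specificity": idx.specificity,
                    "accuracy": idx.accuracy,
                    "bias_invasive_minus_pred": bias,
                    "sd": sd,
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)
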