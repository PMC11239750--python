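# coroflow

Reduced-order, model-based prediction of Fractional Flow Reserve (FFR) in
coronary arteries, with and without the pressure guidewire that is present
during the invasive measurement.

## The problem

FFR is the clinical gold standard for judging whether a coronary stenosis is
ischemia-inducing: under pharmacological hyperemia, a pressure wire records
the aortic pressure p_a and the pressure p_d a few centimetres distal to the
lesion, and FFR = mean(p_d)/mean(p_a) over a cardiac cycle; FFR ≤ 0.8 marks a
functionally significant lesion. Simulation-based ("virtual") FFR predicts
this ratio from imaging and routine clinical data without instrumenting the
artery — but almost all such models simulate an *empty* vessel, while the
measurement they are compared against is taken with a 0.036 cm guidewire
sitting across the stenosis. `coroflow` quantifies that discrepancy: it runs
the same prediction pipeline on identical vascular trees with and without
the wire and reports how the wire shifts flow, trans-stenotic pressure drop,
FFR, and the downstream diagnostic statistics.

Real coronary anatomies come from CCTA segmentations that are not public, so
the package ships a first-class synthetic generator: binary trees whose
bifurcation radii obey Murray's law (r_p³ = r_l³ + r_r³), with focal
stenoses calibrated by bisection so the cohort's predicted FFR values span
the four clinical severity classes (0.38–0.52, 0.52–0.72, 0.72–0.84,
0.84–1), six lesions per class, each paired with a row of the packaged
18-patient / 24-lesion clinical tables (MAP, cardiac output, dominance,
invasive FFR).

## The model

The pipeline mirrors the standard CCTA-derived FFR workflow on a 0D network:

1. **Baseline flow** — total resting coronary flow q_cor = 0.045 · CO,
   distributed among the N tree outlets either by distal Murray's law
   (q_k ∝ d_k³) or by a stem-and-crown vessel-length rule (q_k ∝ crown
   length).
2. **Resting solve (Scenario I)** — inlet pressure = MAP, outlet flows
   prescribed; nodal pressures march down the tree through each segment's
   loss model.
3. **Peripheral resistance calibration** — R_out,k = (p_out,k − p_v)/q_out,k
   with venous reference p_v = 5 mmHg.
4. **Hyperemia** — R_hyp = R_bln / TCRI with total coronary resistance index
   TCRI = 3.
5. **Pulsatile hyperemic solve (Scenario II)** — a scaled aortic waveform
   drives the inlet; every outlet is loaded by a five-element coronary-bed
   Windkessel (Ra, Ca, Ra-micro, Cmyo, Rd; resistance split 0.01/0.84/0.15,
   compliance split 0.025/0.975) whose myocardial capacitor rides on the
   left-ventricular pressure, reproducing systolic flow impediment.
   Δt = 1 ms, cycles repeat to periodicity.
6. **FFR** — ratio of cycle-mean p_d (at the clinical sensor position,
   ~2.5 cm distal to the lesion) to cycle-mean p_a.

Segment losses: Hagen–Poiseuille resistance for plain lumens, the exact
annular-Poiseuille closed form where the guidewire is present, and a
Young–Tsai-type stenosis model
ΔP = R_v·q + K_t·ρ/(2A₀²)·(A₀/A_s − 1)²·q|q| with K_t = 1.52, where both
areas shrink by the wire cross-section when the wire traverses the throat.
Blood: ρ = 1.05 g/cm³, μ = 0.035 g/(cm·s), rigid walls, laminar flow.

See `docs/methods.md` for assumptions, parameter provenance and limitations.

## Worked example

```python
import coroflow as cf

patient = cf.load_patient_fixtures()[0]          # MAP 93.33 mmHg, CO 6.0 L/min
tree = cf.generate_tree(n_generations=3, root_radius_cm=0.15, seed=1)
tree = cf.add_stenosis(tree, segment_id=1, degree=0.7)   # 70% area stenosis

absent = cf.predict_lesion(tree, patient, wire=False)
wired = cf.predict_lesion(tree, patient, wire=True)
print(f"FFR_pred  (wire absent)   : {absent.ffr:.3f}")
print(f"gFFR_pred (wire included) : {wired.ffr:.3f}")
print(f"trans-stenotic drop       : {absent.delta_p_mmHg:.1f} -> {wired.delta_p_mmHg:.1f} mmHg")
print(f"hyperemic inflow          : {absent.inflow_ml_s:.2f} -> {wired.inflow_ml_s:.2f} mL/s")
```

prints

```
FFR_pred  (wire absent)   : 0.548
gFFR_pred (wire included) : 0.449
trans-stenotic drop       : 38.5 -> 44.9 mmHg
hyperemic inflow          : 10.59 -> 9.69 mL/s
```

A 70% area stenosis on this tree predicts FFR ≈ 0.55 (severe). Threading
the wire raises the trans-stenotic drop by ~6 mmHg and cuts inflow by ~8%,
pulling the predicted FFR down by a tenth — the same severity-dependent
underestimation seen when virtual FFR is compared against the instrumented
invasive measurement.

The same experiment at cohort scale, from the shell:

```bash
coroflow full-study --seed 1 --out coroflow_out
```

writes the cohort manifest and trees, `lesion_results.csv` (one row per
lesion × flow setup, wire-absent and wire-included side by side),
`class_aggregates.csv` (mean percentage FFR drop, ΔP rise and inflow drop
per severity class), `diagnostics.csv` (sensitivity/specificity/accuracy at
the 0.8 cutoff, Bland–Altman bias and SD, ROC AUC against invasive FFR) and
agreement plots.

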