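# valveflow

Quantification of atrioventricular valve regurgitation from whole-heart
4D-flow CMR, built for the left atrioventricular valve (LAVV) after
atrioventricular septal defect correction — a valve whose regurgitant
jets are frequently multiple, eccentric, dynamic in direction across
systole, and non-circular in cross-section, which defeats
single-plane 2D flow measurement and echocardiographic jet-area
grading.

The package implements the full analysis chain for three-directional,
time-resolved velocity data and for researchers who want to test such a
chain without patient data, a parametric 4D-flow phantom with exact
ground truth.

**Method.** For each jet, a measurement plane is tracked retrospectively
through systole: per cardiac phase the plane is placed perpendicular to
the jet direction, 1–2 cm proximal to the valve. The through-plane
velocity map is background-corrected by subtracting the mean myocardial
(tissue ROI) velocity, integrated over the jet region to a flow rate

&nbsp;&nbsp;&nbsp;&nbsp;Q(t) = Σ<sub>ROI</sub> v<sub>⊥</sub>(t) · ΔA&nbsp;&nbsp;[mL/s],

and integrated over the tracked cycle interval to a volume. With
multiple jets, each gets its own plane series and the volumes are
summed. The derived quantities are

&nbsp;&nbsp;&nbsp;&nbsp;R<sub>total</sub> = Σ<sub>jets</sub> R<sub>j</sub>,&nbsp;&nbsp;
EFF = V<sub>inflow</sub> − R<sub>total</sub>,&nbsp;&nbsp;
RF = R<sub>total</sub> / V<sub>inflow</sub> × 100%,

with internal validation EFF − V<sub>aortic</sub> ≈ 0 in the absence of
shunts (aortic flow from the same acquisition). Jets are further
characterized by their per-phase angle to the annulus line in the 2-/4-
chamber views (streamline-style direction reading, angles in [0°, 180°))
and by the circularity index (shortest/longest Feret diameter of the jet
core at peak regurgitant flow). Velocity aliasing beyond the encoding
limit Venc is corrected by temporal phase unwrapping. Supporting modules
cover Simpson-rule planimetry, EF, biplane area–length atrial volume, Du
Bois BSA indexing, the indirect regurgitant volume (stroke volume −
aortic flow), and Pearson/Spearman/Bland–Altman method comparison.

## Worked example

Simulate the default phantom — a single dynamic regurgitant jet carrying
11 mL at 2.3 × 2.3 × 3.0 mm / 30 phases / Venc 150 cm/s, sweeping its
annulus angle 50°→86° across systole with cross-sectional axis ratio
0.61, over 70 mL of diastolic inflow — and quantify it end to end:

```bash
valveflow report --config examples/pipeline_config.yaml --out report.json
```

The report (abridged) prints:

```
flow:
  forward_volume_ml: 70.42
  total_regurgitant_ml: 10.92
  effective_forward_ml: 59.51
  regurgitant_fraction_pct: 15.50
  aortic_volume_ml: 58.53
  internal_validation_diff_ml: 0.98
jet lavv_jet_1:
  angle 2ch min/max/diff: 49.9 / 87.4 / 37.5 deg
  circularity_index: 0.633  peak_phase: 5
```

Reading: the pipeline recovered 10.92 mL of the programmed 11 mL
regurgitation (−0.7%) and a regurgitant fraction of 15.5% vs the
programmed 15.7%; the effective forward volume agrees with the
independently tracked aortic volume to 0.98 mL (true difference 0 by
construction); the jet-angle sweep is recovered to within ~1.5° at both
ends; and the measured circularity 0.633 matches the programmed 0.61
within the rasterisation tolerance. Numbers vary at this order with the
noise seed.

The same pipeline runs on clinical-format data (three component NIfTIs +
JSON sidecar, declared view planes and seed points) via
`dataset_dir`/`measurement` in the config; `valveflow simulate`,
`quantify`, `characterize` and `cohort` expose the individual stages.
The library surface (`import valveflow`) mirrors the CLI one-to-one.

## Layout

| path | contents |
|---|---|
| `src/valveflow/flow_core.py` | dataset model, NIfTI I/O, sampling, Venc unwrapping |
| `src/valveflow/phantom.py` | synthetic 4D-flow generator + analytic ground truth |
| `src/valveflow/reformat.py` | oblique plane reformatting, MPR stacks, polygon ROIs |
| `src/valveflow/valve_tracking.py` | jet tracking, background correction, flow integration |
| `src/valveflow/jet_metrics.py` | streamlines, jet–annulus angles, circularity |
| `src/valveflow/volumetry.py` | Simpson planimetry, EF, LA volume, BSA, indirect regurgitation |
| `src/valveflow/agreement.py` | correlation and Bland–Altman statistics |
| `src/valveflow/pipeline.py` | orchestration, config/report models, cohort summaries |
| `docs/methods.md` | models, estimators, numerical choices, limitations |

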