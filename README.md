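# myodti

Cardiac diffusion-tensor (cDTI) biomarkers of chronic myocardial
infarction: regional analysis of in vivo imaging plus a Monte-Carlo
diffusion simulator that links the biomarkers to microstructure.

## The problem

After a myocardial infarction, scar and border-zone remodeling change the
water diffusion environment of the myocardium. Diffusion tensor imaging
measures, per voxel, a symmetric tensor **D** whose eigenvalues
e₁ ≥ e₂ ≥ e₃ (mm²/s) summarize diffusion along and across the
cardiomyocyte long axis. Derived scalars:

- **MD** = (e₁ + e₂ + e₃)/3 — mean diffusivity
- **RD** = (e₂ + e₃)/2 — radial diffusivity (transverse to the myocyte axis)
- **FA** = √(3/2) · ‖(e₁−MD, e₂−MD, e₃−MD)‖ / ‖(e₁, e₂, e₃)‖

Because myocyte loss widens the extracellular space *between* fibers, the
transverse eigenvalues (and hence RD) are expected to respond to scar more
strongly than e₁ — making RD a candidate contrast-free infarct biomarker.
The package implements the full analysis chain needed to test this:

1. **Segmentation** (`myodti.segmentation`) — LGE signal-intensity
   thresholds: remote SI ≤ μᵣ + 2σᵣ, infarct SI ≥ (μᵣ + μᵢ)/2, border in
   between; μ/σ pooled from operator ROIs across slices.
2. **Registration** (`myodti.registration`) — diastolic LGE-based label
   maps onto systolic cDTI slices: quaternion rigid alignment, uniform
   longitudinal rescaling (systolic shortening), Canny-based endo/epi
   contouring with distance-weighted mask averaging, per-slice
   symmetric-demons non-rigid registration of the myocardial support, and
   one-hot linear label interpolation back to the cDTI slice positions.
3. **Tensor fitting** (`myodti.dti`) — log-linear least squares per voxel,
   eigenvalue invariants, and rejection of voxels with MD above free water
   (3×10⁻³ mm²/s).
4. **ECV mapping** (`myodti.ecv`) — ECV = (1 − Hct)·ΔR1_myo/ΔR1_blood from
   pre/post-contrast T1.
5. **Regional statistics** (`myodti.regional_stats`) — voxel pooling by
   region, Anderson–Darling normality, pairwise two-group Kruskal–Wallis
   with Bonferroni adjustment (significance p < 0.01), summary and
   percent-change tables.
6. **Microstructure simulation** (`myodti.diffsim`) — random-walk diffusion
   (Gaussian steps, Δt = 10 µs, 51 ms, impermeable membranes, periodic
   0.5 mm voxel) through synthetic myocyte "trees" (9–20 µm cylinders,
   100 µm segments, transverse branches) built to a target extracellular
   volume fraction (ECV); 12-direction displacement projection and tensor
   reconstruction relate ECV to MD/FA/e₁/RD.
7. **Synthetic data** (`myodti.synthdata`) — a seeded infarcted-LV phantom
   (diastolic LGE/T1 grids, systolic DWI grid, Rician noise at SNR ≈ 16)
   with exact ground truth for every stage.

## Worked example

```bash
myodti make-phantom --out study --seed 11
myodti run-pipeline --config study/pipeline.yaml
```

`study/results/table2_percent_change.csv` then contains, among others
(percent change of regional medians, Bonferroni-adjusted p):

```
quantity  comparison      percent_change  p_adjusted  significant
RD        border-remote   16.5            4.6e-34     True
RD        infarct-remote  31.3            1.9e-101    True
e1        infarct-remote  17.4            2.1e-65     True
FA        infarct-remote  -16.8           8.9e-22     True
ECV       infarct-remote  51.4            0.0         True
```

Reading: in the phantom's infarct zone the radial diffusivity median is
~31% above remote myocardium while e₁ rises only ~17% and FA falls — the
transverse eigenvalues carry most of the infarct contrast, and every
regional difference is significant at p < 0.01. `table1_summary.csv` holds
the per-region mean/median/Q1–Q3 for native T1, ECV, FA, MD, e₁–e₃ and RD.

The simulator connects this to microstructure:

```bash
myodti simulate-diffusion --target-ecvs 0.3,0.6,1.0 \
    --structures-per-ecv 2 --repeats 2 --seed 3 --out sweep.csv
```

Cluster medians (in `sweep.clusters.csv`) rise with ECV for MD, e₁ and RD
and fall for FA; from ECV 0.3 to 1.0 RD rises ~150% versus ~12% for e₁ —
radial diffusivity is the eigenvalue most sensitive to extracellular
expansion.

## Data formats

NIfTI-1 for all volumes and label maps (labels: 0 background, 1 remote,
2 border, 3 infarct); FSL-dialect bval/bvec text for gradient tables; YAML
for configs; CSV/JSON outputs. See `docs/methods.md` for the model
assumptions, parameter defaults and limitations.
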