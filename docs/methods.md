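# Methods

This note documents the models, parameter choices and numerical decisions
behind `myodti`, and what the synthetic phantom does and does not
demonstrate about real data.

## Regional subdivision (segmentation)

Thresholds follow the two-threshold signal-intensity rule for chronic
infarct sizing on LGE: with μᵣ, σᵣ from remote ROIs and μᵢ from infarct
ROIs (pooled across all slices of a subject),

- remote: SI ≤ t_low = μᵣ + 2σᵣ
- border: t_low < SI < t_high = (μᵣ + μᵢ)/2
- infarct: SI ≥ t_high

Boundary handling follows the displayed inequalities (≤ for remote, ≥ for
infarct, strict for border), which keeps the three classes an exact
partition of the myocardium. σ uses the population formula (ddof = 0) by
default; `ddof` is configurable since the convention is not universal.
σ_infarct is computed and stored although the classification rule never
uses it. ROIs are file inputs; for phantom work they are drawn
automatically from ground-truth labels eroded by one voxel, standing in
for a human analyst. The myocardium mask is an explicit input — automatic
LGE contouring is out of scope.

## Label registration (diastolic LGE → systolic cDTI)

Five stages, each restricted to the label alphabet {0,1,2,3}:

1. **Rigid.** Rotation composed from the two orientation quaternions
   (q_fixed · q_moving⁻¹); translation aligns foreground centroids. The
   default foreground is the hole-filled Otsu mask; callers can supply
   masks explicitly (the pipeline uses the label support for the moving
   volume, because the plain Otsu centroid of an LGE image is biased
   toward the bright enhancing scar and blood pool). An image-based
   quaternion reading (principal axes of the foreground) is available
   behind `quaternion_source="image"`; metadata is the default.
2. **Longitudinal rescale.** Slice z positions are mapped affinely so the
   most basal/apical label slices land on the corresponding cDTI slices
   (systolic longitudinal shortening); interior spacing scales uniformly.
3. **cDTI myocardium contours.** Canny edges per slice, hysteresis
   thresholds at 0.5×/1.0× the Otsu level of the smoothed gradient
   magnitude (one retry at half thresholds). Closed edge components are
   found by connected-component analysis; each ring is then refined to the
   iso-contour of the smoothed image at the ring's mean intensity. This
   removes the ±1-pixel bias a rasterized edge ring would impose on the
   annulus — Canny localizes the edge, the iso-level traces it with
   subpixel accuracy. Masks at the label-slice z positions come from
   distance-weighted averaging of the two neighboring slice masks through
   their signed distance maps (true shape interpolation; a 0.5 threshold
   on averaged *binary* masks would collapse to a union/intersection vote
   at mid weights). Endpoint weights return the input masks exactly.
4. **Non-rigid.** Per-slice symmetric-forces demons registration of the
   (smoothed, ×100-scaled) binary myocardial supports; 200 iterations,
   update-field smoothing σ = 1 mm. Labels are warped with
   nearest-neighbor sampling, so the alphabet is closed under the warp. A
   support Dice below 0.80 is flagged in the diagnostics.
5. **3D interpolation.** One-hot indicators interpolated linearly in z,
   arg-max with ties to the more severe label (infarct > border > remote >
   background). Targets outside the stack span extrapolate by nearest
   slice.

Stages 1–4 run on a 1 mm in-plane working grid
(`working_spacing_mm`) and the result is sampled at the cDTI voxel centers
at the end; this halves nearest-neighbor quantization at 2 mm voxels.
Finally the map is clipped to the detected cDTI myocardium and unlabeled
myocardial voxels are filled from their nearest labeled neighbor, so the
output partitions the myocardium by construction.

## Tensor fitting and biomarkers

Plain OLS on the log signal, ln S = ln S₀ − b gᵀDg, solved for the six
tensor components and ln S₀ with one pseudo-inverse shared by all voxels.
No weighting, no positivity constraint: negative eigenvalues from noisy
fits are reported as-is (a `clip_negative` flag exists). Multiple b = 0
volumes/averages are averaged arithmetically before fitting. Voxels with
any nonpositive signal are marked invalid. FA uses the standard
normalized eigenvalue-dispersion definition and is defined 0 for the zero
tensor. The MD rejection filter removes voxels with MD strictly above
free water (3×10⁻³ mm²/s); equality is kept, with a 10⁻⁹ relative guard so
eigensolver rounding cannot flip the comparison.

## ECV

ECV = (1 − Hct)·ΔR1_myo/ΔR1_blood, ΔR1 = 1/T1_post − 1/T1_pre. Blood T1 is
a scalar pair per subject (blood-pool ROI means). Voxels with nonpositive
myocardial ΔR1 are set to 0 and flagged; ECV > 1 is flagged but retained —
the statistics stage can exclude flagged voxels. The pipeline pools ECV
and native T1 on the diastolic (LGE-grid) label map, since both live on
the diastolic grid already; re-registering ECV slices through the same
chain is possible with the library but not wired into the default
pipeline.

## Regional statistics

Voxels are pooled per region and (optionally) across subjects by
concatenation. Normality: Anderson–Darling with estimated mean/variance,
the small-sample correction A*² = A²(1 + 0.75/n + 2.25/n²), and the
standard piecewise-exponential p approximation (implemented here; scipy
exposes the statistic but not this p-value). Regional differences:
two-group Kruskal–Wallis (tie-corrected H, χ²(1) p) per region pair,
Bonferroni ×3, significance p < 0.01. Quantiles use linear interpolation
between order statistics — comparisons of medians/IQRs against tables
computed under another convention can differ slightly. Percent changes are
computed from unrounded medians; recomputing them from medians rounded to
two decimals can shift the first decimal (≈ ±1 percentage point), which is
the tolerance used when comparing against published rounded tables.

## Synthetic phantom

The phantom emulates a chronically infarcted swine LV imaged with three
short-axis protocols. Defaults (chosen once as realistic mid-LV values):

| parameter | default | note |
|---|---|---|
| LGE grid | 96×96 @ 1.33 mm, 5 slices @ 8 mm | diastole |
| cDTI grid | 64×64 @ 2.0 mm, slices @ 8 mm | systole |
| endo/epi radius | 20 / 30 mm | diastole |
| wall thickening | +10 % | epicardium fixed, wall thickens inward |
| longitudinal z scale | 0.75 | systolic shortening |
| infarct sector | 90° (transmural) | half-angle tapers 40 % toward apex |
| border rim | 35° per side | |
| region eigenvalues | remote (1.94, 1.38, 1.06)·10⁻³; border (2.14, 1.65, 1.24)·10⁻³; infarct (2.28, 1.83, 1.42)·10⁻³ mm²/s | pooled in vivo medians for chronic infarcts |
| LGE intensities | remote N(100, 10²), infarct N(300, 20²) | arbitrary units; border uniform strictly between the two class thresholds |
| native T1 | 1282 / 1389 / 1554 ms | remote/border/infarct medians |
| post-contrast T1 | derived | so ECV medians are 0.31 / 0.38 / 0.47 at Hct 0.30, blood T1 1700/400 ms |
| DWI | b = 0 + 12 icosahedral directions at b = 350 s/mm², S₀ = 100, Rician SNR 16 | σ = S₀_myo/SNR |

The fiber frame sets e₁ circumferential with a ±60° transmural helix sweep
and e₃ radial; only the eigenvalues matter to the scalar biomarkers — the
frame makes the DWI signals directionally realistic. The apical taper of
the infarct sector makes labels z-dependent, so the longitudinal-rescale
stage has measurable value (its ablation strictly lowers Dice). Border
LGE intensity is drawn uniformly strictly between the two class
thresholds, making ground truth consistent with the classifier by
construction — the real border zone is a biological mixture with no known
distribution, so phantom intensity parameters are placeholders, not
estimates of any acquired data.

**What phantom results do and do not show.** The phantom shares the
pipeline's own forward models (monoexponential DWI, exact annular
geometry, analytic systolic transform), so passing tests demonstrate
internal consistency, correct implementation of each rule, and correct
error propagation — not robustness to real-world confounds (motion, eddy
currents, partial volume at trabeculae, papillary muscles, perfusion,
contour errors on low-SNR data, non-annular anatomy).

## Diffusion simulator

Cardiomyocytes are capsules (cylinders with hemispherical end-caps
implied by the point-to-segment distance test): per-tree diameter uniform
in 9–20 µm, 100 µm segments chained along x with ≤3° axial jitter, trees
on a jittered hexagonal lattice, one transverse branch per adjacent tree
pair by default (`branch_density`). The lattice spacing is solved by
bisection against a Monte-Carlo point-in-capsule estimate of the
extracellular volume fraction until the measured ECV is within ±0.05 of
target (±0.02 is usually reached); a target of 1.0 yields an empty voxel.
At tight packings radii are capped at 0.47× the lattice spacing to
prevent overlap, which bounds the reachable ECV from below (≈0.15 for
this radius range); unreachable targets raise with the achievable bound.

Walkers are seeded uniformly in the extracellular space (intracellular
simulation is available behind `simulate_intracellular`; only
extracellular displacements are ever read out). Steps are Gaussian per
axis with variance 2·D₀·Δt (D₀ = 3×10⁻³ mm²/s extracellular, 2.2×10⁻³
intracellular), Δt = 10 µs, duration 51 ms (5100 steps), default 20 000
walkers. Membranes are impermeable: steps that would cross are rejected
and redrawn (up to 64 attempts, then the walker rests this step); a
bounce-back reflection mode and a fixed-step-length mode exist as
sensitivity alternatives. The cube is periodic with the minimum-image
convention (valid because segment length + radius < half the edge);
displacements accumulate unwrapped. A uniform spatial grid (CSR buckets)
accelerates the point-in-capsule tests. At the default parameters the RMS
step (√(6·D₀·Δt) ≈ 0.42 µm) is ~9 % of the smallest cylinder radius, so
membrane interactions are well resolved; a warning fires if the ratio
exceeds 1/3.

Readout follows the narrow-pulse Gaussian assumption: per direction g the
apparent diffusivity is D_g = ⟨(Δx·g)²⟩/(2t); the tensor solves
D_g = gᵀDg by least squares over the 12 icosahedral directions (design
matrix rank 6, verified at load). The ECV sweep enumerates target ECVs ×
structures × repeated walks (full grid: 9 × 5 × 5 = 225 runs; tests and
the acceptance script use scaled grids — 3 targets × 2 × 2 at 2000–5000
walkers — chosen as the package's own desk-scale defaults) and clusters
runs with similar measured ECV (±0.05) before taking medians.

Numerical notes: all randomness flows from explicit integer seeds
(structure build, walker seeding and walking use separately derived
seeds; sweep seeds derive from `SeedSequence`), so identical
(config, seed) reproduce identical tables bitwise on a given platform.
The walker kernel is `numba`-compiled; first use pays a JIT cost.

## Known limitations

- No membrane permeability, relaxation weighting, or exchange; no
  intracellular readout (matching the extracellular-only analysis the
  simulator is built for).
- Branch geometry between trees is a modeling choice
  (mid-segment transverse capsules at `branch_density` per neighboring
  pair); sweep trends are robust across densities but absolute FA at low
  ECV depends on it.
- Registration assumes short-axis stacks with in-plane rotations only;
  through-plane deformation is not modeled.
- The pipeline treats T1/ECV maps as living on the LGE grid; a separate
  T1 grid would need resampling before pooling.
- DICOM ingestion, PSIR reconstruction, cine handling, and eddy/motion
  correction are out of scope.
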