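# Methods

This note documents the models behind `mreh`, the parameters that matter,
and what the synthetic experiments do and do not demonstrate.

## The measurement problem

Multifrequency MR elastography (MRE) drives shear waves (here 35, 40, 45,
50, 55, 60 Hz) into the liver and images the 3-component displacement field
at 8 phase offsets of each vibration period on a 9-slice, 100 × 78,
3 × 3 × 5 mm³ grid. From those wave images one reconstructs maps of
shear-wave speed (SWS, m/s — a stiffness surrogate) and fluidity (φ, rad —
the phase angle of the complex shear modulus; 0 is a pure solid, π/2 a pure
fluid). The biomarker of interest is the voxelwise **coefficient of
variation** of SWS inside a liver volume of interest,
CV = 100·SD/mean, which quantifies how *spatially heterogeneous* fibrosis
is rather than how severe it is on average. Focal, segmental disease (as in
primary sclerosing cholangitis) should raise CV; diffuse disease (viral
hepatitis) should not.

## Phantoms

`make_phantom` builds a voxelwise ground truth on the acquisition grid:

* **Liver**: a simply connected ellipsoid (~650 cm³ at the default grid),
  embedded in uniform background tissue at the subject's baseline speed.
* **Focal archetype** (`heterogeneous_focal`): 2–5 spherical stiff lesions
  with radii 30–60 mm and ~6 mm smoothed edges, covering ≈`lesion_fraction`
  (default 0.25) of the liver. The radii are deliberately segmental-to-lobar
  — at or above the shear wavelength (≈40 mm at these frequencies and
  speeds). Heterogeneity imposed below the wavelength is invisible to any
  elastographic method, so sub-wavelength texture would make the recovery
  experiments test the phantom, not the pipeline.
* **Diffuse archetype** (`homogeneous_diffuse`): a smooth Gaussian random
  texture with ≈35 mm correlation length — "homogeneous" disease is modeled
  as low-amplitude, spatially smooth variation rather than a literal
  constant, except when `target_cv_percent=0` is requested.
* **CV targeting**: when `target_cv_percent` is set, the pattern is
  standardized over liver-minus-vessels and applied as
  `c(x) = c₀·(1 + t·z(x))` with `t = CV/100`, which pins the parenchymal
  spatial mean to `background_sws_mps` and the CV to the target exactly.
  Targets that would drive the speed nonpositive, or patterns with no
  spatial variation (e.g. `lesion_fraction = 0`), raise an "infeasible
  heterogeneity target" error.
* **Vessels**: 4 straight tubes (radius 4–6 mm) through the liver interior
  at 0.5 m/s and φ = 1.0 rad, standing in for major branches of the portal
  and hepatic veins; they sit below the 1 m/s VOI threshold by
  construction.
* **Fluidity**: constant `phi_background_rad` (default 0.49 rad, a typical
  hepatic value) in the parenchyma.

## Wave synthesis

`synthesize_wavefield` launches one damped wave per source from
`n_sources` (default 12) arcs of the field-of-view boundary — emulating
surface drivers at different positions. Each front is propagated with a
first-arrival **eikonal** solve (vectorized Jacobi iteration of the Godunov
upwind scheme, per slice): travel time T satisfies |∇T| = 1/c(x), so the
synthesized phase Φ = 2πf·T has local wave-number magnitude exactly
k(x) = 2πf/c(x) — the property the phase-gradient estimator inverts. Plane
solutions are machine-exact in this scheme at any propagation angle, which
gives clean closed-form oracles. A second eikonal with integrand
tan(φ/2)/c accumulates the log-amplitude, so amplitude decays as
exp(−k·tan(φ/2)·distance), the plane-wave consequence of a complex modulus
with phase angle φ. The model therefore includes refraction and viscous
damping but **not** diffraction, scattering, reflections or mode
conversion.

Sources are assigned round-robin to the three displacement components
(through-plane first), keeping each component's directional spectrum sparse
— the role polarization plays for real shear waves. Offsets sample
u(x,t) = Re[U(x)e^{−i2πft}] uniformly over one period. Optional Gaussian
noise (default σ = 5% of the mean in-body amplitude) is added on the
displacement samples. Everything is driven by the spec's integer seed;
identical inputs give bit-identical fields. Square in-plane voxels are
required (true of the default grid).

## Inversion

`invert_subject` composes four stages, all deterministic:

1. **Harmonic extraction** — DFT over the offset axis; the 2/N-scaled
   positive-frequency bin maps A·cos(2πft+θ) to A·e^{iθ}.
2. **Directional filtering** — per slice, the 2D spatial spectrum is split
   into 12 angular sectors with raised-cosine (cos²) windows and a radial
   band-pass. Window half-width is 3 sector spacings (90°): windows this
   wide still vanish for counter-propagating waves, sum to a constant at
   every angle (partition of unity, so the bank reconstructs its input when
   the radial band is open), and impose far less spatial smoothing than
   minimal-width sectors — with 30° half-widths the angular truncation
   low-passes the maps enough to erase roughly half of genuine lesion
   contrast. Before filtering, the field is amplitude-normalized as
   u/(|u| + 0.05·max|u|): hepatic fluidity implies strong decay
   (α ≈ 0.25·k at φ = 0.49), which otherwise smears each wave's spatial
   spectrum into a wide Lorentzian and biases speeds upward by ~15%.
   The radial low cut is k ≥ 2πf/c_lowcut with c_lowcut = 5 m/s: the cut
   must sit **above** the fastest plausible shear speed (focal cirrhotic
   tissue approaches 3 m/s, so cutting at 3 m/s clips genuine shear energy
   in stiff lesions), while compression-wave leakage lives at far lower k
   (c_p ≈ 1500 m/s) and is still rejected. High cut defaults to the
   in-plane Nyquist wave number.
3. **Phase-gradient speed** — per directional field and slice: 2D phase
   unwrapping, central differences scaled by the physical voxel size,
   SWS = 2πf/|∇phase|. Voxels below 5% of the strongest filtered amplitude
   for that component/frequency, or implying speeds above 5 m/s, are
   flagged invalid (insufficient excitation / degenerate gradient).
4. **Compounding** — energy-weighted (amplitude²) average over all
   12 × 3 × 6 = 216 contributions per slice; voxels with no valid
   contribution are zeroed and flagged. **Fluidity** comes from an
   algebraic Helmholtz estimate: φ = |arg(−∇²u / u)| per component and
   frequency, aggregated by |u|²-weighted averaging of the unit phasor of
   k*², clipped to [0, π/2). The discrete Laplacian rescales k*² by a real
   factor only, so the φ estimate is unbiased by discretization; the tissue
   density is fixed at 1000 kg/m³.

Measured fidelity at the defaults (5 phantoms per group, 5% noise): group
mean SWS within ~3%, recovered group-mean CV within 2 points of the imposed
21% / 18%, φ within ~0.01 rad; a constant phantom reconstructs with a
~4–5% artifact CV floor (front collisions, vessel partial volume, boundary
taper), which partially offsets the variance the finite resolution
removes.

## VOI statistics, staging, cohort layer

The VOI is `liver_mask ∧ (SWS ≥ 1.0 m/s)` — the threshold is inclusive and
removes vessels and poorly excited regions; its volume is reported after
thresholding. Mean and SD (sample, N−1 — immaterial at ~10⁴ voxels but
fixed for reproducibility) give CV per subject and per map. Staging uses
the inclusive cutoffs F1 ≥ 1.52, F2 ≥ 1.55, F3 ≥ 1.67, F4 ≥ 1.72 m/s;
values below 1.52 are F0. Group summaries report mean and interindividual
SD per metric; **group CV is the mean of per-subject CVs**, never the ratio
of group-level summaries (the two differ whenever subjects' means differ).

Group comparison uses the Welch two-sided t-test by default (unequal group
sizes and variances; the pooled-variance Student variant is available via
config), α = 0.05 with no multiplicity correction. AUC for the CV
biomarker is the Mann–Whitney estimator (ties ½) with a DeLong 95%
normal-approximation CI (cross-checked against an independent reference
implementation in the tests). APRI is 100·(AST/ULN)/platelets with the
published bands, edges assigned half-open as <0.5 / [0.5,1) / [1,1.5) /
[1.5,2] / >2. The Mayo risk score uses the revised PSC model,
R = 0.0295·age + 0.5373·ln(bilirubin) − 0.8389·albumin + 0.5380·ln(AST) +
1.2426·(variceal bleeding), with risk groups ≤0 / (0,2] / >2; the
coefficients are module constants (`mreh.stats.MRS_COEFFICIENTS`).

Cohort simulation draws per-subject baseline SWS and target CV from
group-specific truncated normals (PSC-like: 1.70 ± 0.28 m/s, 21 ± 5%;
hepatitis-like: 1.84 ± 0.38 m/s, 18 ± 3%) and laboratory values from
moment-matched lognormals / truncated normals (AST, bilirubin, albumin,
age); platelets use lognormals with medians 220/180 ×10⁹/L and the AST
upper limit of normal is fixed at 40 U/L.

## Problem sizes and numerical choices

* Unit tests run the physics chain on a reduced grid (3 × 48 × 64); the
  parameter-recovery experiments use the full 9 × 78 × 100 grid with
  5 phantoms per group; the end-to-end determinism check uses a small
  4-subject cohort. The statistical null experiment (100 repeats at
  n = 20/26) runs at the cohort-sampling layer — the property under test
  is the behavior of the AUC/t-test layer under identical generating
  distributions, which does not depend on the wave physics.
* Eikonal iteration: convergence tolerance 1e-9, checked every 8 Jacobi
  sweeps; ties between the 1D and 2D upwind updates follow the standard
  Godunov rule.
* Degenerate inputs raise typed errors rather than returning NaN: empty
  VOI, nonpositive VOI mean (CV undefined), all-zero fields, empty groups,
  zero-variance correlations.

## Limitations

* No diffraction, scattering, reflections, standing waves or mode
  conversion in the synthetic fields; no MRI encoding (no motion-encoding
  gradients, no k-space sampling, no phase wraps from acquisition). Passing
  recovery tests show the *processing chain* is consistent and unbiased
  under the stated wave model, not that it would perform identically on
  acquired data.
* Heterogeneity is modeled at segmental scales. CV contributed by
  sub-wavelength fibrosis texture is outside the method's resolving power
  by construction, and no claim is made about it.
* The VOI is the phantom's own liver mask (the manual-contouring step of a
  human reader is replaced by mask input); reader variability is not
  modeled.
* Clinical covariates are sampled independently of the imposed imaging
  truth, so cross-domain correlations (e.g. APRI vs CV) carry no biological
  signal in simulated cohorts; those columns exercise the statistical
  machinery only.
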