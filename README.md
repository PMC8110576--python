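# mreh — spatial heterogeneity of liver stiffness by multifrequency MR elastography

`mreh` is an end-to-end, fully synthetic test bed for quantifying the
**spatial heterogeneity of hepatic fibrosis** with multifrequency MR
elastography (MRE). It targets the contrast between primary sclerosing
cholangitis (PSC), whose fibrosis is focal and segmental, and chronic viral
hepatitis, whose fibrosis is diffuse: global liver stiffness can be similar
in the two diseases while the *spatial variability* of stiffness differs.

The pipeline covers, without any patient data:

1. **Phantoms** (`mreh.phantom`) — viscoelastic liver phantoms in two disease
   archetypes (focal stiffening vs. smooth diffuse stiffening, plus
   vessel-like low-speed tubes), with the ground-truth spatial coefficient
   of variation of shear-wave speed dialled exactly to a requested value.
2. **Wave synthesis** — time-resolved, 3-component displacement fields at
   drive frequencies 35–60 Hz on the emulated acquisition grid (9 axial
   slices, 100 × 78 matrix, 3 × 3 × 5 mm³ voxels, 8 time offsets). Wave
   fronts obey the eikonal equation, so the local wave number is exactly
   `k(x) = 2πf / c(x)`; amplitude decays with `α = k·tan(φ/2)`, the
   plane-wave attenuation implied by the fluidity `φ` (the phase angle of
   the complex shear modulus, 0 = pure solid, π/2 = pure fluid).
3. **Inversion** (`mreh.inversion`) — tomoelastography-style compounding:
   temporal harmonic extraction, directional k-space filtering
   (12 directions), per-direction phase-gradient wave-number estimation
   `SWS = 2πf / |∇phase|`, amplitude-weighted compounding of the
   12 × 3 × 6 = 216 images per slice, and an algebraic Helmholtz estimate
   of fluidity `φ = arg(−ρω²u / ∇²u)`.
4. **VOI statistics and staging** (`mreh.roi`) — the analysis volume keeps
   liver voxels with SWS ≥ 1 m/s (excluding vessels and poorly excited
   regions); per subject it reports mean, SD and **CV = 100·SD/mean** of SWS
   and φ, and assigns fibrosis stages by fixed cutoffs
   F1 ≥ 1.52, F2 ≥ 1.55, F3 ≥ 1.67, F4 ≥ 1.72 m/s.
5. **Cohort statistics** (`mreh.stats`) — Welch two-sided t-tests, Pearson
   correlations, AUC with DeLong 95% CI for the CV biomarker, and the two
   clinical calculators: APRI (`100·(AST/ULN)/platelets`) and the revised
   Mayo risk score for PSC.

## Worked example

```python
from mreh import PipelineConfig, run_end_to_end

cfg = PipelineConfig(seed=7)          # 5 PSC-like + 5 hepatitis-like subjects
run_dir = run_end_to_end(cfg, "demo_run")
print(open(run_dir / "report.md").read())
```

This simulates ten subjects (PSC-like: focal lesions, mean SWS drawn around
1.70 m/s with target CV around 21%; hepatitis-like: diffuse texture around
1.84 m/s, CV around 18%), synthesizes and inverts their wave fields, and
prints the cohort table (group mean with interindividual SD in
parentheses):

```
| Metric          | All         | PSC         | Viral hepatitis | P     |
| SWS (m/s)       | 1.72 (0.24) | 1.62 (0.12) | 1.83 (0.30)     | 0.205 |
| SD of SWS (m/s) | 0.34 (0.09) | 0.33 (0.04) | 0.35 (0.13)     | 0.677 |
| CV of SWS (%)   | 20 (3)      | 20 (2)      | 19 (4)          | 0.574 |
| phi (rad)       | 0.50 (0.01) | 0.50 (0.02) | 0.49 (0.01)     | 0.330 |
| ...
- CV of SWS (%): AUC 0.68 (95% CI 0.27-1.00)
```

Reading it: reconstructed group-mean stiffness (1.62 vs 1.83 m/s) tracks
the generating distributions; the per-subject CV of SWS is the
heterogeneity biomarker, and the AUC row asks how well it separates the two
groups (at n = 5 + 5 the confidence interval is appropriately wide — group
differences of a few CV points need cohort-scale samples).

The same stages are available as a CLI:

```bash
mreh simulate --archetype heterogeneous_focal --target-cv 21 --seed 3 --out-dir sim/
mreh invert   --wave-dir sim/S000 --directions 12 --out-dir maps/
mreh analyze  --sws maps/sws.nii --phi maps/phi.nii --mask sim/S000/liver_mask.nii --out stats.csv
mreh cohort   --stats stats.csv --clinical clinical.csv --out-dir cohort/
mreh run      --seed 7 --out-dir demo_run     # everything end to end
mreh config                                    # print all numeric defaults
```

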