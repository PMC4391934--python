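# qdki67

Quantitative multispectral imaging analysis of Ki67 proliferation in
breast-cancer tissue microarrays (TMAs), for researchers evaluating
spectral immunofluorescence as a replacement for manual Ki67 scoring.

Tumour sections are double-stained with quantum dots — QD-605 (red) on
nuclear Ki67, QD-525 (green) on cytoplasmic cytokeratin (CK), which marks
all carcinoma cells — and imaged as 21-band spectral cubes (450–650 nm,
10-nm steps). The package implements the whole analysis chain:

1. **Spectral unmixing.** Each pixel spectrum *y* is decomposed over the
   endmember matrix *E* (columns: CK, Ki67, autofluorescence) by
   non-negative least squares, *a\** = argmin₍a≥0₎ ‖*Ea* − *y*‖₂; the
   autofluorescence component is deleted before quantification.
2. **Quantification.** Per core (six fields), Ki67 sum and CK sum are the
   total unmixed signal intensities; the proliferation statistic is the
   **Ki67/CK ratio** = Ki67 sum ÷ CK sum, which normalises Ki67 signal by
   tumour content and may exceed 1.
3. **Grading.** Each biomarker is dichotomized into grade I/II at the
   observed value maximizing the two-group log-rank χ² against five-year
   disease-free survival (the "best-P" / X-tile principle), with the
   Miller–Siegmund correction for the implicit multiple testing.
4. **Prognostic evaluation.** Kaplan–Meier curves and log-rank tests by
   grade, a multivariate Cox proportional-hazards model (Breslow ties,
   Wald CIs) against the classical factors (T, N, histological grade, ER,
   HER2), and ROC/AUC (Hanley–McNeil CI) for recurrence prediction.

A synthetic-data module generates both multispectral fields with known
ground-truth abundances (elliptical CK-positive tumour nests containing
Ki67-positive nuclei at a controlled proliferation fraction) and patient
cohorts whose event times follow a proportional-hazards model on the
Ki67/CK ratio, so every stage is testable without image downloads.

## Worked example

```python
import numpy as np
from qdki67 import (
    SceneParams, build_default_library, simulate_core, unmix_cube,
    drop_autofluorescence, quantify_field, aggregate_core, noise_threshold,
    CohortParams, simulate_cohort, optimal_cutpoint,
)

library = build_default_library()                 # QD-525, QD-605, AF endmembers
params = SceneParams(noise_sd=1.0, seed=1)       # 1% read-out noise
cubes, truth = simulate_core(params, library)    # one core = six 256x256x21 fields
thr = noise_threshold(library, params.noise_sd)  # 3-sigma abundance noise cut
fields = [quantify_field(drop_autofluorescence(unmix_cube(c, library)), thr)
          for c in cubes]
core = aggregate_core(fields)
print(f"recovered ratio {core.ratio:.4f}  true {truth.true_ratio:.4f}")
# recovered ratio 0.2161  true 0.2162

records = simulate_cohort(CohortParams(seed=2))  # 240 patients, 60-month follow-up
ratio = np.array([r.ratio for r in records])
cut = optimal_cutpoint(ratio,
                       [r.dfs_months for r in records],
                       [r.event for r in records])
print(f"best-P cut-off {cut.cutoff:.3f}  chi2 {cut.chi_square:.1f}  "
      f"grades {cut.n_low}/{cut.n_high}  p_corr {cut.p_corrected:.2g}")
# best-P cut-off 0.208  chi2 16.9  grades 123/117  p_corr 0.0015
```

The recovered core ratio matches the noise-free ground truth to a fraction
of a percent, and the cut-point scan recovers a threshold near the
generator's true prognostic cut-off (0.186) with a strongly significant
corrected p — the high-ratio grade II group carries roughly double the
recurrence hazard.

A command-line interface mirrors the library
(`qdki67 simulate-images | simulate-cohort | unmix | quantify | grade |
survival | roc | run-all`); `qdki67 run-all -c config.yaml -o out/` runs
the full pipeline from a YAML config and writes cohort, scan, Cox, KM and
ROC tables plus a deterministic run manifest.

## Layout

- `qdki67.spectral` — wavelength grid, endmember library, cube I/O (TIFF/npz)
- `qdki67.simulate` — synthetic fields, cores and survival cohorts
- `qdki67.unmixing` — per-pixel NNLS abundance maps, AF deletion
- `qdki67.quantify` — field/core Ki67 sum, CK sum, ratio
- `qdki67.grading` — candidate scan, best-P cut-point, Miller–Siegmund
- `qdki67.survival` — KM, log-rank, Cox (Breslow/Efron), ROC
- `qdki67.cohort` / `qdki67.pipeline` / `qdki67.cli` — table I/O, orchestration, CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
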