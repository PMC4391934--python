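# Methods

## Imaging model

Each pixel of a 21-band spectral cube (450–650 nm, 10-nm band centres,
fixed 800-ms exposure) is modelled as a non-negative linear mixture

    y = E a + ε,    a ≥ 0,

where the columns of E are the endmember emission spectra of CK-QD525,
Ki67-QD605 and tissue autofluorescence, a holds the per-pixel abundances
in the instrument's intensity units, and ε is zero-mean read-out noise.
The linear model assumes no detector saturation, no chromatic aberration
and negligible photobleaching over one acquisition — reasonable for
quantum-dot labels, which are bright and photostable.

Endmember lineshapes are Gaussians. Quantum-dot emission is narrow and
symmetric; only the nominal peaks (525 and 605 nm) are fixed by the
labels, so the width is a parameter: FWHM 30 nm, a typical QD emission
width. Autofluorescence is a broad Gaussian (peak 500 nm, FWHM 150 nm)
standing in for the smooth tissue background a spectral imager estimates
from unstained regions; its exact shape is instrument- and
tissue-dependent and is not claimed to be more than qualitatively right.
Because both QD peaks fall between 10-nm band centres, the library
renormalizes each sampled spectrum to maximum 1; a pure pixel's unmixed
abundance then equals its staining amplitude. The default library is well
conditioned (condition number ≈ 3.0, smallest singular value ≈ 1.1).

## Unmixing

Per-pixel non-negative least squares, solved two ways that are verified
against each other: `unmix_pixel` uses the Lawson–Hanson active-set
solver (scipy), and `unmix_cube` enumerates all 2³ support sets of the
three components, solves each restricted least-squares problem for every
pixel at once, and keeps the feasible candidate with minimal residual.
For a convex objective the minimum-residual feasible support solution is
the global optimum, so the enumeration is exact, and it vectorises over
whole fields (a 256×256×21 field unmixes in ~0.1 s). Negative input
intensities (possible if external background subtraction precedes the
pipeline) are clipped to zero with a logged count. No spatial
regularization is applied: quantification sums pixels, so per-pixel
independence is the faithful model. The autofluorescence plane is kept
during the solve — it absorbs background that would otherwise leak into
the markers — and zeroed afterwards (`drop_autofluorescence`) so it never
enters quantification.

## Quantification

Per field, Ki67 signal and CK signal are the sums of the respective
abundance maps over pixels strictly above a threshold (default 0);
supra-threshold pixel counts are reported as diagnostics. A core
aggregates six fields (other counts accepted with a warning); the Ki67/CK
ratio is the quotient of the core sums and is undefined (core excluded)
when the CK sum is zero. Summed intensity, not pixel count, is the
canonical signal definition.

Non-negative solvers rectify noise: background pixels receive small
positive marker abundances, which biases sums upward (~5% on the ratio at
1% noise under the default geometry, because Ki67 occupies less area than
CK). For noisy data the recommended threshold is `noise_threshold`,
n·σ_a with n = 3 and σ_a the largest per-component abundance noise
obtained by propagating the per-band noise SD through the unmixing
pseudo-inverse (σ_a = noise_sd·max_j‖row_j(E⁺)‖ ≈ 0.85·noise_sd for the
default library). Any threshold a few σ_a wide works — recovery error is
flat from ~2σ_a up to far below the staining amplitudes — so the choice is
not delicate.

## Synthetic fields and cores

A field emulates a stained carcinoma section at the level that matters
for signal quantification, not visual realism: elliptical tumour nests
(random semi-axes within `nest_axes`, rotation, centres separated by at
least the mean semi-axis sum; unplaceable nests reduce the count with a
warning) carry uniform cytoplasmic CK at `ck_amplitude`; nuclei disks
(radius `nuclei_radius`, `nuclei_density` per nest pixel) are seeded
inside nests and are Ki67-positive with probability
`proliferation_fraction`, carrying `ki67_amplitude`; autofluorescence is
uniform at `af_amplitude`; Gaussian noise of SD `noise_sd` is added per
band and the cube clipped at zero. Ground-truth sums come from the
noise-free abundance maps, so the true ratio is independent of noise and
autofluorescence by construction. Cores derive per-field seeds as
`seed + field_index`: reproducible cores, independent fields.

Defaults (256×256, 4 nests of semi-axes 20–45 px, nuclei radius 3 px,
density 0.02 px⁻¹, proliferation fraction 0.3, amplitudes 100/150/20,
noise SD 1 = 1% of the CK amplitude) give core ratios around 0.2, inside
the observed cohort range. Not emulated: stromal Ki67, in-situ vs
invasive architecture, texture within nests, shot noise (additive
Gaussian was chosen because it controls SNR directly; a Poisson mode
would be a straightforward extension). Passing tests therefore
demonstrate correctness of the estimation chain under the linear mixing
model, not robustness to structured artefacts of real slides.

## Synthetic cohorts

Per patient: ratio ~ LogNormal(ln 0.186, 1.7), CK sum ~ LogNormal(ln
2.30×10⁷ − ln 0.186, 0.7), Ki67 sum = ratio × CK sum. The log-medians
reproduce the reference cohort's medians (ratio 0.186, Ki67 sum
2.30×10⁷) exactly in expectation; the log-SDs were set once from the
reported ranges — the ratio spans ~2×10⁻⁴–4 over 240 draws (≈ ±2.9 σ),
and the CK spread is kept modest because the observed Ki67-sum range is
narrower than independence of ratio and CK would imply (in real data the
two are negatively coupled through the denominator; the generator keeps
them independent, as only marginal realism is needed).

Outcomes follow a two-group exponential proportional-hazards model:
hazard = `baseline_hazard` × exp(`log_hr`) iff ratio > `true_cutoff`
(defaults 0.005/month, ln 2.019, 0.186), censoring is the minimum of an
Exp(`censor_rate` = 0.002/month) draw and 60-month administrative
follow-up. This yields ≈ 35% five-year event probability, a plausible
recurrence burden for the reference setting (event counts are not
published for it). Covariates (age, menopause, T, N, histological grade,
ER, HER2) are drawn from the reference cohort's marginal frequencies,
independent of outcome and of each other; any correlation structure
would be a user extension, not a claim.

## Cut-point grading

Candidates are the observed biomarker values whose split (value ≤ c →
grade I) leaves both groups ≥ ceil(`min_group_frac`·n); the default 10%
guard mirrors common maximally-selected-statistic practice. For each
candidate a two-group log-rank χ² (pooled-ties hypergeometric variance)
is computed by a vectorized in-package routine — cross-checked against
lifelines — and the maximizing candidate wins, ties breaking toward the
smaller cut-off. The raw p uses the χ²(1) reference of the winning split;
the corrected p applies the Miller–Siegmund formula with the quantile
bounds actually scanned, clamped into [p_raw, 1], returning 1 outside the
formula's domain (z ≤ 1) and p_raw as z → ∞. No training/validation
split is used by default: the grading is applied to the full cohort, with
both p values reported side by side. In null simulations the corrected p
rejects at ≤ 10% (α = 0.05) where the raw minimal p rejects several-fold
more often.

## Survival statistics

Kaplan–Meier estimation and the multi-group log-rank test delegate to
lifelines. The Cox model is fitted in-package by Newton iteration on the
partial likelihood with Breslow tie handling (the convention of classical
clinical software; Efron is an option and matches lifelines on tied
data), convergence at gradient norm < 1e-8, step-halving with a relative
likelihood slack, covariates centred for stability. Monotone likelihood
is detected as a per-SD log hazard ratio exceeding 15 and raised, not
returned. Wald 95% CIs use the 1.96 normal quantile; covariate coding for
cohort runs is per-increment integer scores for T/N/histological grade
and 0/1 for ER, HER2 and the biomarker grades, so each factor yields one
hazard ratio.

ROC analysis defines cases as recurrence within the follow-up horizon;
records censored before the horizon are excluded with a logged count
(their five-year status is unknown). AUC is the tie-corrected
Mann–Whitney statistic, the CI uses the Hanley–McNeil standard error, and
the p-value tests AUC = 0.5 by normal approximation.

## Problem sizes and determinism

The test suite and the acceptance script use six-field 256×256 cores for
end-to-end imaging checks, 64×64 single-nest fields for exactness tests,
cohorts of 30–1000 for oracle and recovery simulations, and 20–50
replicates for coverage/null-rate checks; the full suite runs in well
under a minute of simulation time. Every generator takes an explicit
seed; identical config + seed reproduces all output tables byte for byte.

## Known limitations

- The endmember spectra are parametric stand-ins; real instruments
  require a measured library (endmember estimation is out of scope).
- The grading step reports both raw and corrected p but applies no
  resampling validation of the selected cut-off.
- Proportional-hazards diagnostics, time-dependent ROC and competing
  risks are out of scope.
- Cohort covariates are independent of outcome in simulation, so
  multivariate adjustment in synthetic runs perturbs the biomarker hazard
  ratio only through sampling noise.
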