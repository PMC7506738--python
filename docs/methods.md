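# Methods

## Scope and data model

The package implements the calibration chain for NIR screening of total
anthocyanin content (TAC, mg per kg fresh fruit) in whole elderberries.
Spectra are diffuse-reflectance measurements on a descending
10,000 → 4000 cm⁻¹ grid at 4 cm⁻¹ point spacing (1501 points), several
replicates per sample. The container treats the 4 cm⁻¹ grid as ground
truth (the instrument measures at 8 cm⁻¹ resolution and its vendor
software interpolates; that interpolation is not re-implemented), and
assumes the external Teflon reference correction has already been applied
by the instrument. Grids must be strictly monotone subsets of a regular
lattice — region restriction leaves gaps that are integer multiples of the
base step, which the validation accepts.

Two conventions are fixed deliberately:

- **Absorbance before averaging.** Reflectance is converted per replicate
  to pseudo-absorbance a = log₁₀(1/R) and the replicates are averaged
  afterwards. The transform is nonlinear, so the order matters; the test
  suite pins it with a counterexample.
- **Regions as closed (low, high) cm⁻¹ intervals**, independent of the
  descending storage order.

## Pretreatment operators

All operators act per spectrum (row-wise) and are scikit-learn
transformers, so recipes are ordinary pipelines.

- **SNV** subtracts the spectrum mean and divides by the sample (n−1)
  standard deviation — the dominant chemometrics convention; the
  alternative denominator changes only a constant factor. Dispersion below
  10⁻¹² of unit scale is treated as zero and raises a degenerate-spectrum
  error: this catches spectra annihilated by earlier operators (e.g.
  detrending a pure polynomial baseline) where only float round-off
  remains.
- **Detrend (order 2)** subtracts the least-squares polynomial baseline
  via an orthonormal (QR) basis. Because the grid is affine in the point
  index, the polynomial subspace — and hence the projection — is the same
  whether parameterized by wavenumber or index; the operator is an
  idempotent linear projection and its residual is orthogonal to the
  basis.
- **Savitzky–Golay derivatives** use windows of 5, 7 or 9 points with
  polynomial order 2 and derivative order 1 or 2, implemented with
  `scipy.signal.savgol_filter`. Edge points are produced by re-fitting the
  boundary-window polynomial (`mode="interp"`), keeping output length
  equal to input length, so region selections near the grid ends stay
  interpretable. Derivatives are scaled to physical per-cm⁻¹ units via the
  signed grid spacing (a descending grid flips the sign of odd
  derivatives); a `per_index` toggle reproduces vendor-style per-point
  values.
- **Maximum normalization** divides by the maximum absolute value.
- **Region selection** keeps the grid points inside a list of closed
  intervals.

Two named recipes reproduce the pretreatments of the two best-performing
TAC models, with operators applied in the order the recipes list them:

- `RECIPE_PHDIFF` (pH-differential reference): detrend(2) → SG(7, 2, 1st)
  → SNV.
- `RECIPE_HPLC` (HPLC reference): max-normalize → SG(7, 2, 1st) → SNV →
  selection of the HPLC model's meaningful regions (4188–4516, 4704–4716,
  4772–4924, 4976–5076, 5188–5276, 5812–5900, 6416–6432, 7100–7208,
  8956–8968 cm⁻¹). The exact wavelength preselection used originally is
  not published; the meaningful-region list is the closest available
  proxy and is overridable by config.

Whether SNV preceded or followed the derivative in the original software
is not documented; the recipe order here follows the published
description's sentence order and is fixed.

## PLS regression and diagnostics

`NIPALSPLSRegression` is PLS1 by NIPALS on column-centered X and centered
y with **no variance scaling** — derivative spectra are conventionally
used centered only. For a single response NIPALS is non-iterative per
factor. The regression vector is b = W(P'W)⁻¹q; prediction is
ŷ = ȳ + (x − x̄)·b. If the residual rank is exhausted before the requested
factor count, extraction stops with a warning and the achieved count is
recorded.

- **Cross-validation** is full leave-one-out with centering recomputed
  inside every fold (no information leakage). RMSECV(k) is reported for
  every factor count up to the requested maximum; the automatic choice is
  the parsimony rule — the smallest k whose RMSECV is within 2% of the
  global minimum. Three factors can also be fixed explicitly, matching
  the established models.
- **Metrics.** RMSEC, RMSECV, RMSECV/RMSEC, R²cal, R²val, and
  RSD_PLSR = 100·RMSECV / mean(y_cal). The "average concentration" is
  read as the mean of the calibration references; the range midpoint is
  available via `rsd_denominator="midrange"`.
- **Hotelling T²** uses the score-space statistic T²ᵢ = Σ_k t²ᵢₖ/var(t_k)
  with the F-based limit k(n−1)/(n−k)·F(1−α; k, n−k) at α = 0.05 (the
  test level is not documented for the original analysis; 0.05 is the
  standard default). The workflow runs a single pass: flagged samples are
  removed and the model refitted once, without iterative re-testing.
- **Uncertainty test.** Martens-style jack-knife over the LOO segments:
  v_j = Σ_s (b_j − b_j⁽ˢ⁾)²·(n−1)/n, significant when |b_j|/√v_j exceeds
  the two-sided t quantile at α = 0.05 with n−1 degrees of freedom.
  Vendor implementations differ in constant factors; the (n−1)/n Martens
  bias factor is used here. Degenerate cases are defined, not errors:
  v_j = 0 with b_j = 0 is not significant, v_j = 0 with b_j ≠ 0 is.
  Contiguous significant grid points are merged into closed intervals and
  annotated with the assigned cyanidin-3-O-glucoside bands within
  ±20 cm⁻¹ (regions with no assigned binary combination or first overtone
  nearby are reported "uncertain").

## Reference-method arithmetic

The pH-differential TAC uses the AOAC differential absorbance
A = (A520 − A700)_pH1.0 − (A520 − A700)_pH4.5 and
TAC = A·MW·DF·10³/(ε·l) with MW = 449.2 g/mol, ε = 26,900 L mol⁻¹ cm⁻¹,
DF = 30 and l = 1 cm by default; a negative differential is arithmetically
defined and returned with a warning. The bridge to fresh-weight units
multiplies by (extra dilution)·(extract volume, mL)/(sample mass, g) —
mg/L × mL/g is exactly mg/kg. The HPLC sum parameter adds the three
quantified glycosides; analytes below LOQ contribute zero and flag the
record "partial", and a fully censored record reports no numeric value
(an LOQ/2 substitution policy is deliberately not applied, matching how
censored control samples are reported). DIN 32645 limits use the
calibration-curve variant: LOD = (s_res/|slope|)·t(1−α; n−2)·
√(1/m + 1/n + x̄²/S_xx) with α = 0.01 and LOQ = 3·LOD (quick-estimate
convention). The F-test compares the larger to the smaller sample variance
against F(1−α/2) at α = 0.05, two-sided; the repeatability helpers report
within-day RSD (averaged over days when several are given) and pooled
across-day RSD.

## Synthetic data generator

The generator emulates the measurement design of the screening study: 27
samples, 9 replicate spectra each, true TAC uniform over 500–8300 mg/kg
(the span of the two reference tables). Per sample the "true" absorbance
is

    a(ν) = baseline(ν) + matrix(ν) + (TAC/TAC_mid)·A_anth·s_anth(ν),

where s_anth is the max-normalized sum of Gaussians at the 33 assigned
cyanidin-3-O-glucoside band centers, the matrix is broad water bands near
6900 and 5188 cm⁻¹, and the baseline is an order-2 polynomial with
coefficients drawn per sample. Each replicate multiplies the absorbance by
a log-normal scatter factor and adds Gaussian point noise; reflectance
10^(−a) is positive by construction. Reference values are the true TAC
perturbed by multiplicative error at a configurable RSD.

Parameter choices (all configurable; defaults fixed once):

| parameter | default | rationale |
|---|---|---|
| band width (Gaussian sd) | 25 cm⁻¹ | typical solid-state NIR bandwidth; the quantum-chemical assignment provides centers only |
| 2νOH intensities | ×0.5 | anharmonic calculations overestimate OH-stretch intensities |
| matrix amplitude | 0.5 AU, 5× the anthocyanin signal at mid-range TAC | water dominates fresh fruit spectra |
| anthocyanin amplitude at mid TAC | 0.1 AU | keeps the analyte at roughly 1–15% of total absorbance across the TAC range — a realistically hard inverse problem |
| baseline coefficient sd | (0.05, 0.02, 0.02) | gentle instrument drift in a normalized grid coordinate |
| scatter log-sd | 0.05 | few-percent multiplicative scatter between replicate packings |
| point noise sd | 0.001 AU | FT-NIR detector noise scale |
| reference RSD | 10% | the wet-chemistry precision scale: between the HPLC table (1–6%) and the pH-differential table (4–34%) |

What the generator does **not** emulate: Kubelka–Munk/radiative-transfer
scattering physics, wavelength-dependent multiplicative effects,
temperature and moisture shifts of the water bands, sample heterogeneity
beyond the scatter factor, or the true (unpublished) pure-component NIR
spectrum — the Gaussian absorptivity is a modeling stand-in and never
claimed to match measured intensities. Passing recovery tests therefore
demonstrate the pipeline's correctness and statistical behavior under the
assumed noise structure, not instrument-level performance on real berries.

## Study-condition results and their limits

With the defaults above, a 3-factor calibration after `RECIPE_PHDIFF`
typically reaches R²val ≈ 0.94 and RSD_PLSR ≈ 12% (medians over 50
seeds). The joint event {R²val ≥ 0.9 and RSD_PLSR ≤ 15%} occurs in about
80% of seeds — and cannot occur much more often: with 10% multiplicative
reference error the RMS reference error is ≈ 0.10·√E[TAC²] ≈ 494 mg/kg,
an RSD_PLSR floor of ≈ 11%, whose per-seed sampling fluctuation alone
(relative sd ≈ 1/√(2n)) pushes a noticeable fraction of seeds past 15%
even for an oracle predicting the true TAC exactly (measured: 94% of
seeds). The corresponding acceptance test states the stronger ≥ 90%
joint-rate condition and is expected to fail at these noise conditions;
it is retained unweakened as the documented target.

The jack-knife wavenumber selection is assessed at the HPLC-reference
precision scale (2% reference RSD): there the selected points overlap
anthocyanin band support 1.5–2× more than a uniform random mask of equal
size (permutation check), and at least one contiguous region overlaps an
assigned band interval. At 10% reference noise the jack-knife
t-statistics are noise-dominated and selection approaches the null rate —
a realistic illustration that variable selection needs a precise
reference.

## Numerical choices and degenerate inputs

- Spectra tables are written with 17 significant digits and parsed with
  round-trip float precision, so write → read is bit-exact.
- NIPALS stops a factor when ‖X'y‖ falls below 10⁻¹² of the initial data
  norm (rank exhaustion), warning and recording the achieved count.
- A constant-y CV fold predicts the fold mean (the zero-variance error is
  reserved for the top-level fit).
- The Hotelling statistic handles zero-variance score directions by
  omitting them (identical samples give T² = 0, no flags).
- Ties in the parsimony rule resolve to the smallest factor count.

## Problem sizes

The test suite simulates at the study scale (27 × 9 × 1501) where the
behavior under test depends on it, and on a coarser 16 cm⁻¹ lattice for
Monte-Carlo checks that only need the statistical structure; the
acceptance script runs 50 full-scale simulated calibrations plus the
selection and outlier studies, a few seconds of compute in total, since
PLS1 NIPALS is non-iterative and leave-one-out refits are O(n·p) per
factor.
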