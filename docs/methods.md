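# Methods

`irdecide` implements a complete analysis pipeline for binary tissue
classification from mid-infrared hyperspectral extinction images, organized
around the idea that a *linear* SVM is not a black box: trained on
standardized spectra it reduces to a portable *decision equation*, and that
equation can be decomposed wavenumber-by-wavenumber into a physically
interpretable feature-selection curve, the *Decision Contribution Spectrum*.

## The decision equation

Each spectrum is a vector over a shared wavenumber grid (descending,
inclusive; the full-range reference grid is 4000–750 cm⁻¹ in 2 cm⁻¹ steps,
1626 points). Training spectra are standardized per spectral step by the
training mean `Train̄_j` and standard deviation `σ_Train,j` (n−1 denominator;
a floor of `1e-12·max(σ)` guards featureless steps). A soft-margin linear
SVM on the standardized spectra yields a decision value for any test
spectrum `Test_k`:

    d_k = b + Σ_j ((Test_k,j − Train̄_j) / σ_Train,j) · β_j

with `β_j` the primal weight vector — equivalently the dual sum
`Σ_i α_i y_i (SV_i,j − Train̄_j)/σ_Train,j` over support vectors. Both
evaluation routes are implemented (`decide` and `decide_sv_form`); their
algebraic identity is verified to ~1e-13 on every trained model and serves
as a standing self-check. `d_k > 0` classifies tumor, `d_k ≤ 0` nontumor;
`d_k` is the signed distance to the separating hyperplane and is reported
unnormalized, because its magnitude carries information (transition tissue
sits near zero).

The classifier is therefore fully described by three spectra and a constant
(`Train̄`, `σ_Train`, `β`, `b`), which the package exports as a plain CSV
(17 significant digits, so re-imported equations reproduce decisions
bit-exactly) together with the class-mean spectra.

The quadratic program itself is solved by scikit-learn's `SVC`
(libsvm, linear kernel). Defaults are `C = 1` and solver tolerance 1e-3;
both are exposed. Invariances that are exact in exact arithmetic
(row permutation, duplication of a hard-margin training set) hold in
practice only to about the solver tolerance; the tests check them at 1e-6
with a tightened solver.

## The Decision Contribution Spectrum

For class-mean spectra `T̄` (tumor) and `NT̄` (nontumor), evaluating the
decision equation's per-step contributions at each mean and differencing
gives

    Δd̄_j = ((T̄_j − NT̄_j) / σ_Train,j) · β_j ,

in which the bias and training mean cancel. `Σ_j Δd̄_j = d(T̄) − d(NT̄)`
exactly (conservation; asserted to 1e-8 relative in tests). `Δd̄` is the
average contribution of step `j` to the tumor/nontumor decision: large
magnitudes mark wavenumbers worth measuring, near-zero regions can be
dropped — the feature-selection reading that drives the probe-design
ablations. Note `β` alone is not sufficient for feature selection; it must
be weighted by the standardized class-mean difference, which is what `Δd̄`
does.

## Preconditioning

Four per-spectrum options: `raw`; `bc` (rubber-band baseline correction:
subtract the lower convex hull of the spectrum over the wavenumber axis —
parameter-free, removes the broad scattering offsets of unfixed frozen
sections); `bc_ratio` (baseline correction then division by the amide-I
peak height, searched in 1600–1700 cm⁻¹); and `bc_norm` (baseline
correction then unit Euclidean norm, removing section-thickness
information). `bc_norm` is the default throughout, as the variant relevant
to probe design. Baseline correction is idempotent and commutes with
positive scaling, so `bc_norm` is exactly invariant to per-pixel
multiplicative thickness and additive linear baselines (tested to 1e-9);
concave baseline components are not representable by a convex minorant and
leave a small residue — visible as ~1e-4-level differences between
otherwise identical synthetic cases.

A display-only 5-point second derivative (central stencil exact through
quartics, edges replicated from the nearest interior value, multiplied by
−250 so up-going peaks mark band centers) is provided for band-structure
inspection.

Normalization norm (Euclidean vs area) and the amide-I "response" used for
ratioing (height vs area) were genuinely open choices; vector norm and peak
height were chosen and are configurable.

## Validation

Leave-one-case-out (LOCO): one fold per case (patient), training on all
spectra of the other cases, testing on every spectrum of the held-out case.
Preconditioning is per spectrum and applied up front; the standardization
scaler is re-fit inside each fold. Pooled error is total errors over total
tests, not the mean of fold percentages. `leakage_compare` runs a
pixel-level random split (ignoring cases) next to LOCO on the same data to
quantify how case leakage inflates apparent accuracy. Decision-value
histograms record class-resolved counts on shared bins with the d = 0
boundary and ±1 pooled-SD reference lines.

## Ablations

All probe-design experiments reduce the spectra first (range restriction,
decimation anchored at the high-wavenumber end, 200 cm⁻¹ sliding windows,
or an explicit coarse probe grid snapped onto the native one) and then
re-fit scaler and SVM on the reduced grid only — no full-range statistics
leak into a reduced-grid model. Both evaluation protocols are available:
`loco` (default) and `pixel_split` (the window-split protocol such range
studies traditionally use; also ~7× cheaper). The sliding-window stride
defaults to 100 cm⁻¹ and window edges are inclusive.

## Component maps

A minority-component reference spectrum is derived by scaled subtraction:
`ref = a − s·b` with `s` chosen to cancel the amide-I peak height of `b`
against `a`, leaving the component (e.g. lipid) in which the two spectra
differ. Each pixel is scored by Pearson correlation with the reference
(full grid by default, range configurable since lipid C–H bands straddle
the fingerprint and H-stretch regions); pixels with correlation > 0.5
(strict) form the component mask; flat pixels are flagged undefined and
excluded. Secondary binary decision equations (lymphocyte vs nontumor)
reuse the main training machinery with a different positive class.

## Imaging

Decision images: positive values in red scaled by the positive extreme,
negative in green scaled by the negative extreme, zero black; `mean2sd`
scaling clamps each sign group at mean ± 2 SD so rare extremes saturate.
Transition shading draws −0.5 < d ≤ 0 light green and 0 < d ≤ +0.5 light
red ("light" = 50% white blend; the published figures name the colors but
not their values). Overlays replace masked pixels with a flat color
(lipid yellow, lymphocyte purple).

## The synthetic study conditions

The methods were developed against a private clinical library (756,096
full-range spectra from 14 frozen sections of 7 patients, available only on
request), so the package ships a generator that emulates that library's
statistical structure; all quantitative claims in the tests are claims
about these synthetic conditions, not about clinical data.

Defaults (chosen once, as a plausible frozen-section liver scenario):

- **Grid / geometry** — reference grid 4000–750/2 cm⁻¹; 7 cases of 64×64
  pixels (6.25 μm pixel edge). Desk-scale rather than clinical-scale: the
  window spectra per library (1512) give binomial error bars of a couple of
  percent on LOCO rates, which is enough to separate "near-perfect" from
  "chance".
- **Bands** — Gaussian lineshapes (Lorentzian available): amide-I sub-bands
  1694/1658/1646/1630 cm⁻¹ (fwhm 14), amide II 1547, lipid 1741/2925/2853,
  phosphate 1240/1083, glycogen 1008. Tumor/nontumor differences are
  concentrated in the amide-I sub-band composition with alternating sign
  (tumor higher at 1694 and 1646, lower at 1658 and 1630) plus small
  differentials at 1240 (tumor up) and 1008 (tumor down). Real relative
  amplitudes for metastatic liver tissue are not tabulated anywhere usable,
  so these are plausibility-based synthetic values; the narrow sub-band
  width keeps neighboring opposite-sign differential lobes resolvable on
  the 2 cm⁻¹ grid, which is what makes ground-truth recovery a well-posed
  test.
- **Nuisance structure** — per-pixel scattering baseline `b0 + b1·u +
  b2·u²` (u ∈ [0,1] across the grid), per-pixel multiplicative thickness
  0.8–1.2 (bands only), i.i.d. Gaussian noise sd 0.02 ≈ amide-I SNR 50.
- **Case effects** — per (case, band): log-normal amplitude multiplier
  (sd 0.12) and center jitter uniform in ±2 cm⁻¹. This is the minimal
  structure that makes case leakage demonstrable: a pixel split can learn a
  case's amide shape, LOCO cannot.
- **Layout** — tumor columns on the left (fraction 0.42), an 8-pixel
  transition band of linear tumor/nontumor mixtures (so decision values
  there land near zero), nontumor on the right; three lipid blobs (radius
  4, 70% lipid + 30% local tissue) centered on the transition; one 10×10
  lymphocyte region in the nontumor corner; six 6×6 tumor/nontumor windows
  per case placed strictly inside pure-class tissue, plus one lymphocyte
  and one lipid window for secondary models.

`null_config` equalizes the tumor/nontumor amplitudes of every band and
changes nothing else, giving a matched no-signal library for calibration:
LOCO on it must sit at chance, and does.

What the generator does *not* emulate: realistic tissue morphology and
texture, Mie/EMSC-type scattering physics, detector drift, pixel-to-pixel
spatial correlation of noise, and the true amplitude differences between
tumor and normal liver. Passing tests therefore demonstrate that the
pipeline's algebra, protocols and recovery logic are correct under known
ground truth — not that any particular clinical error rate is attainable.

## Numerical choices and degenerate inputs

- Ties in `nearest_index` and `top_features` resolve toward the higher
  wavenumber; grid arithmetic requires the span to divide the step to 1e-9
  relative.
- Baseline correction needs ≥ 3 points; collinear input falls back to the
  straight chord. Zero spectra cannot be normalized or ratioed; such pixels
  are zeroed (cubes) or dropped (labeled matrices) with a logged count.
- Training requires both classes; LOCO folds whose training side lost a
  class are skipped with a warning; pooled errors always use total counts.
- Probe grids snap each requested wavenumber to the nearest native grid
  point and refuse points farther than half a probe step away.
- All randomness flows from explicit integer seeds; the generator is a pure
  function of (config, case index, seed).

## Problem sizes

Default analyses train on 1512 window spectra (216 per case) over 1626
spectral points; multi-seed checks (band recovery, leakage) use 10
generator seeds. These sizes were chosen so that the complete analysis
suite and the reproduction script each run in minutes on a single core
while keeping binomial uncertainty on error rates near ±2.5 percentage
points.
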