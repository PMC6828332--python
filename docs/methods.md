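# Methods

## Scope and intent

`glowmix` models dual-reporter bioluminescence imaging at the level of
region-of-interest (ROI) radiance vectors: one number per bandpass filter
per sample. It does not model image formation (lens, CCD geometry, scatter
blur) or photon transport beyond a single effective attenuation coefficient.
Everything downstream of the ROI reduction — library construction, NNLS
unmixing, percentage adjustment, subset ranking, correlation validation —
operates identically on simulated vectors, CSV tables, or ROI sums extracted
from multi-page TIFF stacks.

## Emission spectra

Each (enzyme, substrate) pair is a registry entry with peak wavelength,
full width at half maximum (FWHM), a red-tail skew weight, and a relative
photon yield. Spectra are rendered as skew-normal bells on a shared 1 nm
grid over 400–900 nm, re-parametrised so the mode sits exactly at the
registered peak and the half-max width equals the registered FWHM, then
normalised to unit area (trapezoidal). The skew-normal shape parameter is
`alpha = 4 * skew`.

Peak wavelengths are the characterised in vitro values: 560/560/620 nm for
FLuc_green/FLuc_natural/FLuc_red with D-luciferin (LH₂); 680/700/720 nm with
infraluciferin (iLH₂); 600 nm (CycLuc1) and 660 nm (AkaLumine) for all three
mutants — the single-colour behaviour of the latter two is why they cannot
support dual reporting. Widths and skews are *not* published for these
pairs; they are calibration constants of this package (see Calibration).
Photon yields are 1.0 for LH₂ pairs and 10⁻² for iLH₂ pairs, the midpoint of
the reported two-to-three orders of magnitude brightness penalty of the
infraluciferin reaction.

## Tissue optics

Attenuation is Beer–Lambert with a single wavelength-dependent effective
coefficient: `T(λ, d) = exp(−μ_eff(λ) · d)`, with scattering folded into
μ_eff. The packaged μ_eff curve is **synthetic, not measured**. It is
piecewise linear with the qualitative anatomy of mammalian soft-tissue
attenuation: ~2–2.6 mm⁻¹ below 600 nm, oxy-haemoglobin Q-band maxima near
542 and 576 nm flanking a local transparency notch at 560 nm, a steep fall
across 600–620 nm, and a flat near-infrared plateau (0.30 → 0.21 mm⁻¹ over
620–900 nm). Attenuated spectra are deliberately not renormalised: depth
costs photons as well as colour.

Named tissue contexts carry a mean source depth and a per-animal standard
deviation: subcutaneous 1 mm, systemic 4 mm (femoral marrow), intracranial
6 mm, each with 0.5 mm SD; in vitro is depth 0. The depths are nominal
configuration values, not measured anatomy.

## Instrument

Filters are ideal top-hats, 20 nm wide at unit transmission, centred
500–840 nm in 20 nm steps (18 filters tiling 490–850 nm without overlap).
Band radiance is the trapezoidal integral of the spectral density over the
passband times source flux. In vivo acquisition presets drop filters that
carry no signal: 540–820 nm for LH₂, 600–820 nm for iLH₂, following the
stated acquisition wavelength ranges (the filter *counts* quoted alongside
those ranges are inconsistent with a 20 nm grid, so the ranges win).
Peak-filter ties resolve to the longer wavelength.

## Synthetic data

The generator realises exactly the statistical structure the analysis
assumes:

- **Linearity.** A fraction-*f* mixture's expectation is the convex
  combination of the pure populations' expectations, weighted by photon
  yield. This is exact in noise-free mode (an explicit flag returning
  expectations, not a large-budget approximation).
- **Noise.** Counts are Poisson around the expectation, plus additive
  Gaussian read noise (SD 5 counts), clipped at zero. The photon budget —
  10⁶ expected total counts for a pure LH₂ well of 10⁶ cells at depth 0 —
  anchors the scale; iLH₂ wells inherit ~10⁴ counts through the yield ratio,
  dim but imageable, consistent with the reported brightness penalty.
- **Cohorts.** Each animal draws its own depth from
  Normal(context depth, SD), truncated at 0.1 mm. Library (pure) animals and
  mixed animals draw independent depths; this mismatch, not photon noise, is
  the dominant error source in vivo and is the mechanism that degrades LH₂
  unmixing specifically.
- **Ground truth** is the known input fraction; the flow-cytometry protocol
  that established engrafted fractions experimentally is out of scope, so
  truth is exact by construction.
- **Designs.** In vitro plates titrate green fraction
  {0, 10, 25, 50, 75, 90, 100}% with 6 replicates; in vivo cohorts use
  {90, 75, 50, 25, 10}% with 4 animals each. The in vitro gradation list is
  a configurable merge of the plate gradient with the in vivo ratios.
- **Time-course demo.** Tumour (green) grows exponentially (0.3/day from
  10⁵ cells); T cells (red) expand logistically (1.2/day from a 10³ dose,
  capacity 5×10⁵) and suppress tumour signal through a Hill term (EC50 10⁵,
  slope 2). These are demonstration defaults — no published kinetics exist
  to calibrate against — chosen so the qualitative pattern (green first,
  red overtakes by day 6, control keeps rising) emerges.

What the generator does **not** emulate: spatial tumour structure, optical
cross-talk between neighbouring animals, autoluminescence background,
substrate pharmacokinetics, or engraftment variability in absolute radiance.
Consequently, passing validations demonstrate the *analysis* is correct
under the stated model, not that the model captures every feature of real
animal data; in particular absolute red:green radiance ratios are not
reproduced (real ones are confounded by engraftment differences).

## Unmixing

Library signatures are the per-class means of unit-sum-normalised pure
measurements; the 2-column signature matrix's condition number is recorded
and libraries above 10⁶ are rejected as collinear (separating genuinely
rank-deficient subsets from merely ill-conditioned ones at double
precision). Abundances solve the nonnegative least-squares problem via
`scipy.optimize.nnls`, which is provably optimal for two columns; an
exhaustive 2-D grid-search oracle in the test suite independently verifies
optimality on randomised instances. Percentages divide abundances by the
pure-population reference radiances before normalising to 100 — the
"adjusted to pure populations" convention, interpreted here as brightness
correction so that a 50:50 cell mixture reads 50:50 regardless of the
reporters' relative brightness (the source material does not define the
adjustment; this is the package's interpretation, recorded as such).

Subset ranking exhaustively enumerates all k-filter combinations, restricts
and renormalises the library on each, unmixes the whole plate, and ranks by
squared Pearson correlation with the known fractions; collinear subsets are
flagged failed and sort last, and accuracy ties resolve lexicographically.

R² is the squared Pearson correlation (spreadsheet-style correlation of
recovered vs input percentage), not regression-through-origin R². In vivo
validation repeats the whole pipeline over seeds (default 10) and reports
mean and SD, mimicking variability across imaging sessions.

## Calibration

Only peak positions are anchored by published values; spectral widths,
skews, and the μ_eff curve are free parameters. They were calibrated once,
jointly, against the published in vivo spectral geometry, and then frozen:

- green LH₂ peak filter shifts 560 → 620 nm at systemic depth (the ~60 nm
  in vivo red shift into the 610–630 nm band) with a secondary local maximum
  in the 560 nm filter (bimodal distortion from the Q-band notch);
- red LH₂ stays at 620 nm;
- green iLH₂ shifts one filter step, 680 → 700 nm, red iLH₂ stays at
  720 nm, preserving the ~20 nm in vivo separation at all depths ≤ 10 mm.

Two regimes compete: the 680 → 700 nm green iLH₂ shift needs a μ_eff slope
across 680–700 nm, while depth-stability of the iLH₂ signatures (and hence
in vivo unmixing accuracy) wants the near-infrared plateau flat. The
resolution is a wide (FWHM 100 nm), strongly red-skewed (skew 0.8) iLH₂
bell whose 700 nm band integral sits just below the 680 nm one, so a gentle
slope (0.255 → 0.225 mm⁻¹) flips the peak at depth without tilting the
overall signature appreciably. LH₂ pairs keep FWHM 70 nm, skew 0.25. With
these frozen values the noise-free iLH₂ in vivo correlation changes by
< 0.01 across depth-jitter SDs from 0 to 1 mm, matching the qualitative
depth-consistency of the real system.

## Numerical choices

- Shared 1 nm wavelength grid, 400–900 nm; all integrals trapezoidal;
  filter edges fall on grid points, so adjacent 20 nm bands tile without
  double counting.
- Noise-free simulation is float-deterministic; seeded simulation is
  bit-reproducible per seed (numpy `default_rng`). Multi-seed experiments
  derive per-seed streams as `base + 7919·s + offset`.
- Peak-filter ties break toward the longer wavelength; subset-ranking ties
  break lexicographically.
- Zero-total pure samples, constant truth vectors, all-zero measurements,
  and in vitro cohort requests raise explicit errors rather than returning
  degenerate results; a both-abundances-zero sample has undefined
  percentages and is flagged missing (NaN in batch prediction).

## Problem sizes

Default experiment sizes are those of the study designs: 42-well plates,
20-animal mixed cohorts plus 10 pure characterisation animals, 10 seeds for
in vivo validation. All validation workflows complete in seconds on one
core; the exhaustive 2- and 3-filter subset searches over the 18-filter bank
(153 and 816 subsets) take a few seconds each.

## Known limitations

- μ_eff is a single effective coefficient: no radiative transfer, no
  spatially resolved diffusion, no anatomical heterogeneity.
- Two endmembers only; no background/autoluminescence component is fitted.
- The brightness-adjustment convention for percentages is an interpretation
  (see Unmixing).
- The tumour-only control in the real time-course shows a slowly rising
  "red" signal attributed to optical cross-talk from the neighbouring
  treated animal; ROI-level simulation has no such channel, so the demo's
  control red signal is exactly zero in noise-free mode.
- Registry widths/skews and the attenuation curve are calibration
  constants; conclusions about real tissues require measured spectra and
  attenuation for the system at hand (both are overridable: the registry as
  JSON, the attenuation table as CSV).
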