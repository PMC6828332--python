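# glowmix

Dual-reporter bioluminescence imaging (BLI) promises to track two biological
processes — say, a tumour and a therapeutic cell population — in the same
living animal with a single substrate injection. The catch is physics: tissue
strongly attenuates visible light, so a green-emitting luciferase imaged
through a few millimetres of mouse becomes nearly indistinguishable from a
red-emitting one, and spectral unmixing of the two signals falls apart at
depth. Pairing stabilised firefly-luciferase colour mutants (FLuc_green,
FLuc_red) with the near-infrared luciferin analogue infraluciferin (iLH₂)
moves both emission peaks into the 650–900 nm bio-optical window, where the
spectra keep their ~20 nm separation at any practical depth and unmixing
stays accurate.

`glowmix` is a tested, reusable pipeline for this analysis. It provides:

- a registry of enzyme–substrate emission spectra (three FLuc colour mutants
  × D-luciferin, infraluciferin, CycLuc1, AkaLumine) rendered as unit-area
  skew-normal curves on a shared 1 nm grid;
- a Beer–Lambert tissue forward model, `exp(-μ_eff(λ)·d)`, with a packaged
  synthetic effective-attenuation curve shaped by the haemoglobin bands and
  the near-infrared window;
- an 18-filter bandpass camera model (20 nm top-hat filters, 500–840 nm)
  that reduces spectra to per-filter region-of-interest radiance vectors;
- a synthetic-data generator for mixing plates, animal cohorts with
  per-animal depth jitter, and a tumour/CAR-T time-course, with Poisson +
  read noise and an exact noise-free mode;
- the analysis core: library signatures built from pure populations,
  non-negative least-squares (NNLS) unmixing, brightness-adjusted
  percentages, and exhaustive filter-subset ranking.

## The model in brief

A mixed sample containing a fraction *f* of green-reporter cells produces the
per-filter expectation

```
y = c · [ f · q_g · M F(d) s_g  +  (1 − f) · q_r · M F(d) s_r ]
```

where `s_g, s_r` are unit-area emission spectra, `F(d) = diag(e^{−μ_eff(λ) d})`
is attenuation at depth `d`, `M` is the filter-bank integration operator,
`q` the relative photon yields, and `c` the cell load. Unmixing solves

```
min_{a ≥ 0} ‖ y − a_g ŝ_g − a_r ŝ_r ‖²
```

with `ŝ` the unit-sum library signatures measured from pure populations, and
reports the brightness-adjusted green percentage
`100 · (a_g/R_g) / (a_g/R_g + a_r/R_r)` with `R_g, R_r` the pure-population
reference radiances. Accuracy is validated as the squared Pearson correlation
R² between recovered and known fractions.

The central class is `SpectralUnmixer`, a scikit-learn estimator
(`fit` on pure-population vectors, `transform` → abundances, `predict` →
green percentage), so it composes with sklearn pipelines and model
selection.

## Worked example

```python
import numpy as np
from glowmix import (MixtureDesign, NoiseModel, SpectralUnmixer,
                     simulate_plate, r_squared)

plate = simulate_plate(MixtureDesign.in_vitro_default("iLH2"),
                       NoiseModel(noise_free=True))
pure = [m for m in plate if m.truth in (0.0, 100.0)]
est = SpectralUnmixer().fit(
    np.vstack([m.radiance for m in pure]),
    ["green" if m.truth == 100.0 else "red" for m in pure])
pct = est.predict(np.vstack([m.radiance for m in plate]))
print(round(r_squared([m.truth for m in plate], pct), 4))   # 1.0
```

The same workflows are scripted on the command line. Output below is what
the commands print:

```
$ glowmix reproduce fig2 --substrate LH2
invitro_LH2: R^2 = 1.0000

$ glowmix reproduce fig4 --substrate iLH2
iLH2 systemic: green peak 700 nm, red peak 720 nm, red:green ratio 1.06

$ glowmix reproduce fig5 --substrate iLH2 --seeds 10
invivo_iLH2_systemic: mean R^2 = 0.994 (SD 0.002)

$ glowmix reproduce fig5 --substrate LH2 --seeds 10
invivo_LH2_systemic: mean R^2 = 0.921 (SD 0.057)
```

Reading these numbers: noise-free in vitro plates unmix essentially
perfectly with either substrate — the library spans the data exactly, so
recovered percentages equal the input fractions. In vivo, per-animal source
depth varies, which distorts the green reporter's visible-band spectrum with
D-luciferin (LH₂) and degrades unmixing (R² ≈ 0.92, large spread), while the
near-infrared infraluciferin spectra barely change with depth and unmixing
stays accurate (R² ≈ 0.99, small spread). The ~20 nm peak separation of the
two mutants with iLH₂ survives at systemic depth; with LH₂ both mutants
collapse onto the 610–630 nm band.

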