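# bonetomo

Image-quality and specimen-characterization analysis for neutron and X-ray
tomography of bone.

Neutron imaging sees hydrogen, which makes hydrated soft and bony tissue
glow — and drowns internal structure in hydrated specimens.  A common remedy
is to exchange tissue water for heavy water (D₂O, ~7× lower neutron
attenuation) or to dry and rehydrate specimens, and then to ask: *how much
image quality did each hydration state buy, and did the treatment change the
bone?*  `bonetomo` implements the quantitative toolkit for that question:

- **Edge sharpness** — fit the Gaussian CDF
  `low + (high−low)·Φ((x−µ)/σ)` to line profiles across material
  boundaries (the edge-spread function) and report
  `FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ` with a range-normalized RMSE.
- **Contrast-to-noise ratio** —
  `CNR = |mean(S₁)−mean(S₂)| / √(sd(S₁)²+sd(S₂)²)` between phase ROIs,
  plus background-noise estimation.
- **Phase histograms** — 250-bin grey-value histograms of the specimen
  interior with void/bone/marrow peak detection, absent-peak and
  merged-peak reporting, and a valley-based separation score.
- **BV/TV morphometry** — radius-2 median filter, instrument-named
  threshold presets (`next` = 30375–65535, `4dlab` = 53500–65535 on 16-bit
  images), bone volume fraction against a specimen mask.
- **Compression mechanics** — stress/strain normalization after a 15 N
  pre-load, first-clear-peak failure detection with the exclusion rule,
  max-slope elastic modulus, area-under-curve toughness (MJ/m³), and a
  tidy export table for external mixed-model fitting.
- **Hydration kinetics** — percent weight change
  `C = (w_after − w_initial)/w_initial × 100` and
  fraction-of-lost-weight-regained summaries.

Every stage is driven and verified by a **synthetic phantom generator**
(`bonetomo.phantom`): seeded volumes with known phase geometry, grey means,
Gaussian point-spread blur and additive noise — plus synthetic compression
curves and drying/rehydration weight series — so the whole pipeline is
testable with exact ground truth.  See `docs/methods.md` for the models and
their assumptions.

## Worked example

```python
import bonetomo as bt

# a noisy synthetic edge with known blur (sigma = 2 px)
x, y = bt.generate_edge_profile(mu=0.0, sigma=2.0, levels=(9000, 32000),
                                n_points=200, noise_sigma=0.05 * 23000, seed=7)
profile = bt.LineProfile(x, y, units="px")
conditioned = bt.condition_profile(profile, savgol_span=9, upsample_factor=4)
fit = bt.fit_edge(conditioned)
print(fit.sigma, fit.fwhm, fit.nrmse)
```

prints (run `python examples/edge_sharpness.py` for the annotated version):

```
fitted sigma    : 2.080 px
FWHM            : 4.899 px  (= 2.3548 * sigma)
NRMSE           : 0.0187
```

The fitted σ recovers the generator's blur within a few percent at 5%
contrast noise; FWHM is σ × 2.3548 by construction, and the NRMSE of ~0.02
signals a clean sigmoid fit.  The other capabilities have one short script
each under `examples/`:

```
examples/edge_sharpness.py        ESF fit on a synthetic edge
examples/cnr_panel.py             CNR vs hydration state (dry > 12 h > 40 h)
examples/histogram_phases.py      void/bone/marrow peaks, merged & absent cases
examples/bvtv_morphometry.py      BV/TV recovery on a rod-lattice phantom
examples/compression_analysis.py  failure/modulus/toughness + exclusion rule
examples/hydration_kinetics.py    drying loss and regained-weight statistics
```

## Layout

```
src/bonetomo/     phantom, edges, contrast, histogram, morphometry,
                  mechanics, hydration, io
tests/            unit + property + acceptance suites (pytest)
examples/         one narrative script per capability
docs/methods.md   models, parameter choices, limitations
```
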