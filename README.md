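# peatspec

Spectral unmixing and α-diversity estimation for boreal peatland
vegetation plots.

Peatland plant communities — fen (minerotrophic) sites dominated by
vascular plants and bog (ombrotrophic) sites dominated by *Sphagnum*
mosses — can be characterized non-destructively from their reflectance
spectra. `peatspec` implements the full analysis chain that links
field/laboratory spectroscopy to community composition:

1. **Harmonization** of reflectance-factor spectra on the 1-nm
   350–2500 nm grid: segmented Savitzky–Golay smoothing (order-2
   polynomial; windows of 15 nm below 1000 nm, 39 nm in 1001–2000 nm,
   75 nm in 2001–2500 nm), removal of the noisy 350–399 nm edge and the
   atmospheric water-absorption regions (1330–1549, 1761–2024,
   2311–2500 nm), and per-species averaging of leaf replicates. The
   retained grid is 400–1329 ∪ 1550–1760 ∪ 2025–2310 nm — 1427
   wavelengths.
2. **Band simulation**: convolution with Sentinel-2 MSI spectral response
   functions (bands B2–B8a, B11, B12) to compare hyperspectral against
   multispectral information content.
3. **Spectral unmixing**: per-plot non-negative least squares against a
   trophic-level endmember library,

   a&#770; = argmin<sub>a ≥ 0</sub> ‖E a − y‖₂,

   followed by post-hoc normalization (a&#770;/Σa&#770;) and removal of pairs whose
   observed cover is zero. Abundances are reported in percent and scored
   with R² = 1 − SSres/SStot, RMSE and bias.
4. **α-diversity**: Shannon–Wiener H = −Σ p ln p and Simpson D = 1 − Σ p²
   from point-intercept fractional covers (100-cell grid on a 1 m² frame),
   and prediction of both indices from plot spectra by NIPALS PLS1
   regression with 10-fold cross-validated component selection and a
   70/30 train/test evaluation.

Because the measured spectral libraries live in external repositories,
the package ships a synthetic-study generator (`peatspec.synthetic_data`)
that produces endmember spectra, mixed plot spectra, covers and
point-intercept grids with the statistical structure the analysis
assumes; every stage is testable offline, and the CSV readers accept real
libraries in the same layout.

## Worked example

Unmix the ombrotrophic plots of the default synthetic study (60 plots,
six endmembers, rf noise sd 0.002):

```python
import peatspec as ps

study = ps.gen_study(ps.SimulationConfig(seed=1))
plots = ps.harmonize(study.plots)
endmembers = ps.harmonize(study.endmembers)

comms = study.communities_of("ombrotrophic")
species = ps.select_endmembers(comms)           # abundance-based rule -> 6 species
E = ps.EndmemberSet.from_library(endmembers, species, "ombrotrophic")
result = ps.unmix_trophic_level(plots.subset([c.plot_id for c in comms]), E, comms)
print(result.per_species_metrics().round(3).to_string(index=False))
```

```
            species    r2  rmse   bias  n
   Calluna vulgaris 0.989 1.459  0.021 56
             Litter 0.996 1.062  0.274 55
  Rubus chamaemorus 0.996 1.089 -0.042 59
Sphagnum cuspidatum 0.996 1.016 -0.127 53
    Sphagnum fuscum 0.992 1.588 -0.279 51
  Sphagnum rubellum 0.994 1.288 -0.013 56
```

Each row scores one species' predicted versus observed percent cover over
the plots where it occurs: here the linear mixing model recovers cover to
~1–1.6 percentage points RMSE with negligible bias, because the synthetic
plots really are (noisy, brightness-jittered) linear mixtures — the
idealized regime against which real-data performance can be judged.

The same objects drive the diversity side:

```python
h = [ps.shannon_index(c) for c in comms]
print("Shannon range: %.2f-%.2f" % (min(h), max(h)))   # Shannon range: 0.79-1.63
```

A command-line interface mirrors the library
(`peatspec simulate | harmonize | bandsim | unmix | profile | diversity |
diversity-model | run`); `peatspec run --config config.yaml --out-dir out/`
executes the configured stages end to end and writes a manifest with the
config hash so runs reproduce bit-for-bit.

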