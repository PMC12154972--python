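# dermometry

Morphometry of dermal collagen organization on calibrated microscopy
images, for researchers quantifying how topical treatments (e.g.
hyaluronic-acid formulations) remodel the extracellular matrix of skin
explants.

The package implements, as a tested and reusable pipeline, the readouts
such studies report across two imaging scales:

* **Light microscopy** — the amorphous-ECM area fraction of H&E-stained
  dermis: pixels brighter than a threshold *t* are counted as unstained
  (amorphous ground substance), the rest as eosin-stained (fibrillar
  collagen), and the statistic is
  `amorphous % = 100 · N_unstained / (N_unstained + N_stained)`
  within the dermal region of interest, evaluated separately for the
  compact papillary and the looser reticular dermis.
* **Transmission electron microscopy** — five measurements on
  longitudinally sectioned collagen bundles: bundle thickness (mean
  perpendicular dark-band width, nm), bundle **linearity index**
  `LI = L_path / L_chord ≥ 1` (arc length of the bundle centerline over
  the straight-line distance between its endpoints; higher = more
  tortuous), fibril size and interfibrillar (edge-to-edge) distance from
  half-depth edge crossings on a perpendicular transect, and the
  axial D-band periodicity (~60–67 nm) from the autocorrelation of the
  detrended axial intensity profile, cross-checked against its spectral
  peak.
* **Group statistics** — per group (condition × timepoint × dermis
  layer): mean ± SEM; pairwise comparisons by the two-sided
  Mann–Whitney U test (exact enumeration for min(n) ≤ 8 without ties,
  normal approximation with tie and continuity corrections otherwise)
  for all variables except D-band periodicity, which uses the two-sample
  t-test; significance at p < 0.05, uncorrected.

Because raw micrographs from such studies are rarely deposited, the
package ships a first-class synthetic-data generator with exact ground
truth: H&E-like fields built from thresholded Gaussian random fields
(the realized amorphous fraction is pinned to the target), and TEM-like
fields of parallel wavy fibrils with known diameter, gap, sinusoidal
centerline (hence analytically known linearity index) and D-band
modulation. Every downstream stage is validated against this ground
truth.

## Worked example

Run the full synthetic experiment — 2 conditions (CT, HA) × 2
timepoints (24, 48 h) × 2 layers × 2 replicates, 40 measurements per
condition per variable (100 for D band), with the HA effects encoded in
the reticular dermis at 24 h:

```sh
python analysis/02_measure_and_compare.py --seed 1
```

prints

```
2400 measurements, 0 excluded

reticular dermis, 24 h, CT vs HA:
  * amorphous_pct            p = 2.087e-14 (mann_whitney)
  * bundle_thickness         p = 4.719e-07 (mann_whitney)
  * linearity_index          p = 2.519e-13 (mann_whitney)
  * fibril_size              p = 0.0006468 (mann_whitney)
  * interfibrillar_distance  p = 3.704e-11 (mann_whitney)
    d_band_length            p = 0.4944 (t_test)
```

i.e. the treatment raised the amorphous fraction (23% → 28%), thinned
and kinked the collagen bundles, swelled the fibrils and packed them
closer — while D-band periodicity, which reflects molecular assembly
rather than hydration, stayed unchanged. Group means, SEMs and the full
comparison plan (CT vs HA per layer × timepoint; 24 vs 48 h; papillary
vs reticular) land in `results/experiment/`.

The other drivers: `analysis/01_simulate_cohort.py` writes the cohort's
ground truth (add `--export` for TIFFs), `analysis/03_validate_estimators.py`
sweeps the estimators over a generator grid (median relative errors are
well under 5%, D-band under 2%), `analysis/04_power_and_null.py` checks
type-I error (≈0.05) and per-variable detection power.

The same pipeline runs from the shell on your own annotated micrographs:

```sh
dermometry ecm --image section.tiff --threshold auto
dermometry tem --image bundle.tiff --annotations lines.json --kind bundle --pixel-size-nm 8
dermometry run --config run.yaml --seed 1 --out results/
```

Real mode consumes a `manifest.csv` (image path, kind, condition,
timepoint, layer, replicate) with JSON polyline sidecars; a synthetic
cohort exported to disk and re-ingested in real mode reproduces the
synthetic-mode report exactly.

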