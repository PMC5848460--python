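# magrule

Synthetic membrane-immunohistochemistry simulation and morphometry: a
pipeline that renders IHC-like images of tumor cells with membranous
chromogen (DAB) bands of known width and optical density, separates stains
by color deconvolution, measures band width (FWHM of perpendicular line
profiles) and relative intensity, classifies specimens into 0/1+/2+/3+
scores via microscope-objective resolution windows (Abbe's law), and runs
the cohort statistics (Welch tests at alpha = 1%, width-intensity Pearson
correlation, ISH-subgroup comparison).

## Layout

| module | purpose |
| --- | --- |
| `magrule.optics` | Abbe resolution `d = lambda/(2 NA)`, objective specs, width-to-score windows |
| `magrule.stain` | Beer-Lambert stain mixing (forward) and color deconvolution (inverse), relative intensity scale |
| `magrule.synth` | synthetic specimen/cohort renderer with ground-truth manifests |
| `magrule.morphometry` | ROI placement, sub-pixel line profiles, FWHM width, aggregation, scoring |
| `magrule.stats` | Welch two-sample tests, Pearson correlation, category summaries |
| `magrule.pipeline` / `magrule.cli` / `magrule.config` | orchestration, `magrule` CLI, YAML/JSON config |

## CLI

```bash
# render a synthetic cohort (images + manifest.csv + config_used.yaml)
magrule synth --config examples/cohort.yaml --out out/images

# measure a rendered cohort -> profiles.csv, cells.csv, specimens.csv
magrule measure --config examples/cohort.yaml \
    --images out/images --manifest out/images/manifest.csv --out out/tables

# statistics report -> summary.csv, comparisons.csv, correlation.csv
magrule stats --config examples/cohort.yaml \
    --cells out/tables/cells.csv --specimens out/tables/specimens.csv \
    --out out/report --plots

# everything in one deterministic run
magrule run-all --config examples/cohort.yaml --out out/run --seed 1
```

Without `--config` the built-in defaults are used: 40 specimens per
category (1+/2+/3+), 10 cells per specimen, 4 ROIs per cell, 5.11 px/um,
Gaussian PSF sigma 0.10 um, H-DAB stain vectors, thresholds 0.4/1.0/2.0 um.
See `magrule.config.DEFAULT_CONFIG` for all keys; any subset may be
overridden from the YAML/JSON file.

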