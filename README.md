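# thermotol

Critical heat-injury temperatures of plant leaves, derived from three
complementary measurements:

* **DSC thermograms** — heat flow of a leaf during a constant 1 K min⁻¹
  ramp from 25 to 65 °C. Vital leaves show a shallow linear endothermic
  decline, a steeper decline, an endothermic dip and a pronounced exotherm.
  The pipeline extracts **T_endo** (dip) and **T_exo** (peak) by prominence-
  based extremum detection, and **T_init** as the intersection of two fitted
  lines: the best-R² 10 K band searched from 29 °C up to T_endo, and the
  best-R² 3 K band between that band's upper edge and T_endo. Reheated
  (heat-killed) leaves lack the dip/peak signature and are classified as
  such when a single line fits the whole curve.
* **T-F0 curves** — basic chlorophyll fluorescence against leaf temperature.
  **T_c** is the intersection of a baseline line with the maximal-slope rise
  line (an algorithmic version of the usual graphical two-tangent rule);
  **T_p** and **T_pII** are the first and second prominent F0 maxima.
* **Classical heat-tolerance assays** — Fv/Fm after heating to target
  temperatures, fitted with the four-parameter damage sigmoid
  `y = A2 + (A1 − A2) / (1 + (x/x0)^p)`. **LT_50** is the inflection `x0`;
  **LT_d** inverts the curve in closed form. A resampling bootstrap
  (3 samples per temperature, 250 repetitions by default) yields percentile
  confidence intervals.

A synthetic-data module generates all three curve types with known ground
truth (breakpoints, peak centers, sigmoid parameters, seeds), so every
analysis stage is recovery-testable without instrument data. A summary
module pools per-leaf thresholds (n, mean, sd, median, quartiles) and
computes pairwise-complete Pearson/Spearman correlations between
parameters measured on the same leaf.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(protocol arithmetic, brute-force band-search equivalence, closed-form vs
numeric LT inversion, parameter recovery, vitality classification,
threshold ordering, determinism).

## Command line

```sh
# synthetic fixtures (curve + ground-truth sidecar)
thermotol synth dsc --seed 1 --out data/
thermotol synth dsc-reheat --seed 1 --out data/
thermotol synth tf0 --seed 1 --out data/
thermotol synth lt --seed 1 --out data/

# validate + normalize + aggregate thermograms listed in a YAML manifest
thermotol ingest --manifest manifest.yaml --out ingested/

# threshold extraction
thermotol dsc --manifest manifest.yaml --out thresholds.csv
thermotol tf0 --manifest tf0_manifest.yaml --out tf0.csv

# sigmoid fit + bootstrap
thermotol lt --table assay.csv --reps 250 --per-temp 3 --seed 7 --out lt.csv

# pooled summaries and correlations
thermotol summarize --inputs thresholds.csv --inputs tf0.csv \
    --out-summary summary.csv --out-corr corr.csv
```

A manifest is a YAML list of records with `sample_id`, `path` and, for
thermograms, `fresh_mass` (mg), plus optional `species` and `run_kind`
(`initial`/`reheat`). Curve files are comma- or tab-delimited text with a
header; analysis tunables (band widths, prominence fraction, grid step,
sign convention, …) can be overridden with `--config config.yaml`.

## Layout

```
src/thermotol/
  thermo_io.py       curve data model, readers/writers, normalization,
                     resampling, aggregation, temperature-program model
  dsc_analysis.py    T_init / T_endo / T_exo extraction, vitality classing
  tf0_analysis.py    T_c / T_p / T_pII extraction
  heat_tolerance.py  damage sigmoid, LT_10/LT_50, bootstrap
  synthetic_data.py  ground-truth curve generators
  summary_stats.py   pooled summaries and correlations
  cli.py             `thermotol` command-line interface
```
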