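# digibead

Compartmentalization-free **digital bead-assay quantification** for static
fluorescence micrographs.

In a digital bead assay, analyte molecules are captured on magnetic beads and
amplified (e.g. by rolling circle amplification) so that any bead carrying at
least one labeled molecule lights up brightly. Instead of sealing beads into
femtoliter wells, the beads are simply dispersed between glass substrates and
imaged in paired localization (brightfield or darkfield) and fluorescence
channels. Quantification is then a counting problem:

- beads are located in the localization channel with a circular-object
  (Hough) detector, and each bead's **maximum fluorescence pixel** is read;
- the blank (zero-analyte) condition's bead intensities are fitted to a
  Gaussian; beads above **mean + 2 SD** are "on";
- with Poisson loading, the on-fraction `f_on` inverts to the **average
  number of molecules per bead**:

  `AMB = −ln(1 − f_on)`

- a dilution series of AMB (digital) or grand-mean intensity (analog)
  readouts is calibrated with a **four-parameter logistic** curve

  `f(x) = d + (a − d) / (1 + (x/c)^b)`

  and the **limit of detection** is the concentration whose predicted
  response equals the blank **mean + 3 SD** (masses follow
  ng/mL × µL = pg).

The package is aimed at assay developers who want a tested, reproducible
implementation of this readout chain, plus a ground-truthed synthetic
assay/micrograph generator to validate every stage without raw instrument
data: per-bead Poisson molecule counts, bimodal on/off intensities, ~21% of
beads imaged across many fields of view, background and read noise.

## Worked example

`examples/04_digital_vs_analog.py` simulates one dilution series
(8 concentrations × 3 replicates, 5 000 beads per condition, 24 frames at a
21% imaged fraction) and quantifies the *same* frames both ways:

```text
digital LOD: 0.195 ng/mL (0.389 pg in 2 uL)
analog  LOD: 1.020 ng/mL (2.040 pg in 2 uL)
-> counting single molecules improves the LOD 5.2-fold on identical images
```

The digital readout counts "on" beads against the blank-derived threshold and
is limited mainly by bead-counting statistics; the analog readout averages
all pixels (beads and background) and inherits the field-to-field background
fluctuations — hence the order-of-magnitude-scale gap in LOD.

The other examples walk the individual stages:

| script | shows |
| --- | --- |
| `examples/01_poisson_counting.py` | Poisson loading, blank threshold, why `−ln(1−f_on)` is unbiased while raw `f_on` is not |
| `examples/02_detect_and_measure.py` | bead detection scored against ground truth (center error ≈ 0.1 px) |
| `examples/03_calibration_and_lod.py` | full digital calibration with 4PL fit and LOD |

A thin CLI mirrors the pipeline for shell use —
`digibead simulate -c config.yaml -o run/`, `digibead analyze -i run/ -o out/`,
`digibead calibrate -i out/quantification.csv -o out/` — exchanging
multi-page TIFF stacks and CSV tables, and serializing the resolved
configuration next to each run for bit-identical reruns.

## Layout

- `src/digibead/synthetic.py` — assay + micrograph generator (ground truth included)
- `src/digibead/detection.py` — circular Hough bead detection, per-bead max intensity
- `src/digibead/quantify.py` — blank Gaussian fit, on/off classification, AMB, analog mean
- `src/digibead/calibrate.py` — 4PL fit, LOD, unit conversions
- `src/digibead/pipeline.py` — experiment-level orchestration
- `src/digibead/cli.py`, `src/digibead/io.py` — shell interface and TIFF/CSV/YAML I/O
- `docs/methods.md` — models, parameter choices, numerical details, limitations
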