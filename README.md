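# buho

Automated detection and quantification of cytoplasmic mRNA foci — stress
granules (SGs), processing bodies (PBs), synaptic mRNA-silencing foci — in
two-channel fluorescence micrographs, for cell biologists running
time-course, size-change and high-content RNAi screening experiments.

Supramolecular aggregates of repressed mRNAs form and dissolve with cell
physiology; counting them per cell across thousands of micrographs by eye
is slow and operator-dependent. This package automates the workflow:

1. **Cell segmentation.** The nuclear (DAPI) channel is clipped,
   contrast-stretched and thresholded at 60% of its maximum into a nuclear
   mask. The foci channel is gain-boosted (×2), Wiener-denoised and
   inverted into a topographic surface with nuclei forced to the basin
   bottoms; a marker-controlled watershed then grows one catchment basin
   per nucleus, so basin = cell and ridge = cell border. Cells with less
   than 30 µm² of stained area are discarded.
2. **Foci detection by prototype correlation.** A bank of eight example
   granule patches ("prototypes" I–VIII, each a granule plus a margin of
   cytoplasm) is slid over the foci channel with normalized 2-D
   cross-correlation. Pixels whose correlation exceeds the prototype's
   similarity threshold (ST; defaults 0.89, 0.88, 0.80, 0.88, 0.86, 0.86,
   0.92, 0.85) become *seeds*. A second pass on the unsharp-filtered image
   recovers faint, blurry foci (16 correlation maps per field in total).
   Nuclear and extracellular seeds are removed; surviving seeds are
   dilated to 3×3 squares and merged by connected components, one object —
   one focus.
3. **Quantification.** Each focus is assigned to the cell whose basin
   contains it. A cell is *positive* with ≥ 2 foci; fields report cell
   count, focus count, % positive cells and foci per positive cell. Focus
   size is the object pixel count (reliable above 6 px width), optionally
   re-measured by half-max thresholding for size studies. Proximity
   between object classes (e.g. synapse → nearest focus, < 0.5 µm) uses
   the Euclidean distance transform.
4. **Screening.** Wells pool their fields cell-weighted; the screen score
   of a well is `pct_positive / mean(pct_positive of in-plate control
   wells)` — controls score ~1, suppressors < 1, enhancers > 1.

A synthetic-field generator renders DAPI-bright nuclei, faint cytoplasm
and granules of the eight morphologies with exact ground truth, so the
whole pipeline is testable without any image download.

## Worked example

```python
from buho import (SyntheticSpec, default_bank, evaluate_detection,
                  generate_field, validate_config)
from buho.pipeline import process_field

images, truth = generate_field(SyntheticSpec(seed=7))   # 512x512, 15 cells
result = process_field(images, validate_config(None), default_bank())
s = result.summary
print(f"{s.n_cells} cells, {s.n_foci} foci, {s.pct_positive:.1f}% positive, "
      f"{s.mean_foci_per_positive_cell:.2f} foci per positive cell")
report = evaluate_detection(result.foci, truth, match_radius_um=1.0)
print(f"precision {report.precision:.3f}, recall {report.recall:.3f}")
```

prints

```
15 cells, 28 foci, 53.3% positive, 3.50 foci per positive cell
precision 1.000, recall 0.933
```

Fifteen cells were segmented; 28 foci passed the similarity thresholds and
the nuclear/extracellular filters. Eight cells contained ≥ 2 foci (53.3%),
averaging 3.5 foci each. Scored against the generator's ground truth,
every detection corresponds to a planted granule (precision 1.0) and 28 of
30 planted granules were found (recall 0.933; pooled over the 20-field
test suite the recall is ≥ 0.95).

The same pipeline runs from the shell:

```sh
buho synth --seed 7 --out fields/                   # make test images
buho quantify --nuclear fields/field000_nuclear.tif \
              --foci fields/field000_foci.tif --out out/
buho screen --layout plate.csv --images-glob 'wells/*_foci.tif' --out report.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates synthetic data from the given seed and runs the pipeline end
to end: one full-size field (with detection precision/recall against the
planted truth), a focus-proximity analysis, and a five-well screening
plate with a knockdown treatment planted at 0.6× the control positive
fraction, printing per-well percentages and screen scores. The JSON
summary is written to `--out`.

## Documentation

`docs/methods.md` describes the model, the calibrated defaults, what the
synthetic generator does and does not emulate, and known limitations.
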