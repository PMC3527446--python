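# Methods

## The detection model

Foci are identified by similarity rather than by a parametric spot model.
A prototype is a small patch cut from a reference image containing one
example granule plus a margin of surrounding cytoplasm; the margin anchors
the local contrast and is what separates a bright compact focus from
bright diffuse signal. Sliding the prototype over the foci channel and
computing a normalized (Pearson) cross-correlation at every position
yields a map in [−1, 1] that is invariant to local affine intensity
changes — detection is therefore insensitive to staining strength and
photobleaching, and responds to *pattern*.

Each prototype carries its own similarity threshold (ST), calibrated so
that the prototype alone produces no false positives. Strict thresholds
cost per-prototype sensitivity (a single template recognises only the
minority of foci that resemble it); the union over a bank of eight
prototypes spanning the frequent morphologies — round, elliptical, uniform
and brighter-cored, at several sizes — restores sensitivity while keeping
precision. Default STs: 0.89, 0.88, 0.80, 0.88, 0.86, 0.86, 0.92, 0.85
for prototypes I–VIII. A second correlation pass on the unsharp-filtered
channel (3×3 kernel, α = 0.2) recovers the small fraction of faint,
blurred foci that fall just below threshold in the raw image; its seeds
are added to the raw-pass seeds, giving 16 correlation maps per field.

Supra-threshold pixels ("seeds") cluster: several per focus, from several
prototypes. Each seed is dilated to a centred 3×3 square — the size of a
small focus at 63×/512-px resolution — and 8-connected components of the
dilated mask become the counted objects, each reduced to a representative
point (component centroid snapped to the nearest in-object pixel; a
deterministic, order-free replacement for iterative morphological
shrinking). Seeds inside the nuclear mask are removed first (nuclear
polyadenylated RNA correlates with any bright template), as are seeds
outside the stained-foreground mask.

Rotated prototypes (90°/180°/270°, thresholds inherited) are implemented
but disabled by default: on rotationally symmetric foci they are fully
redundant with the unrotated bank, and anisotropic foci are covered by the
bank's differently oriented ellipses.

## Cell segmentation

Nuclei come from the DAPI channel: clip to the working cap (255),
quantile contrast stretch (1%/99%), threshold at 60% of the image maximum
(the observed maximum, not the theoretical cap, so dim fields behave),
fill interior holes. The foci channel — gain ×2 to compensate faint
cytoplasmic staining, Wiener-denoised (3×3 adaptive window, replicate
borders) — is inverted into an elevation surface (`cap − min(gain·I,
cap)`) with nuclear pixels forced to 0. A marker-controlled watershed
(8-connectivity, ridge lines kept) grows exactly one basin per nucleus
component. Because the watershed tessellates the whole field, two
post-filters apply: a stained-foreground mask (≥ 20% of the
denoised+stretched foci-channel maximum; pixels below it are
"extracellular") and a 30 µm² minimum stained area per cell. Cells
touching the field border are kept but flagged.

## Quantification and screening

A focus belongs to the cell whose basin contains its representative
point; foci on ridge pixels are counted as unassigned, never silently
dropped. A cell is positive with ≥ 2 foci; "foci per cell" averages over
positive cells only. Focus size defaults to the merged-object pixel count,
reliable only above 6 px bounding-box width.

For size-change studies (`quantification.size_mode: halfmax`) the merged
pixel count is deliberately replaced: it measures the correlation
footprint of the fixed-scale template bank, which saturates for foci
larger than the templates and therefore compresses true size changes (a
planted 3.5× area ratio reads back as ~2.2–2.9). Instead each detected
focus is re-segmented from the intensity image at half amplitude: local
background = median of the analysis-window border ring, peak = maximum of
the 3×3 box-smoothed image over the object with the box attenuation of a
curved peak undone via a provisional width estimate, footprint = connected
component above background + 0.5·(peak − background). This FWHM-style
footprint tracks the planted area across a 3.5× range to within ~8%.
Detection and counting are unaffected by the mode.

Distances between object classes use the Euclidean distance transform of
the complement of the pooled focus mask, sampled at each target's
representative point (a target overlapping a focus is at distance 0);
the reported fraction-within uses a 0.5 µm default radius, the
physiologically relevant synapse neighbourhood.

Wells pool fields cell-weighted (not mean-of-field-percentages, since
fields differ in cell count). The screen score is the well's % positive
divided by the mean % positive of untreated control wells on the same
plate; zero-cell fields are excluded with a warning and a zero control
mean flags the score undefined.

## The synthetic stated world

`SyntheticSpec` defaults emulate a 63× confocal field at 512×512 px,
0.2 µm/px: ~15 non-overlapping elliptical cells of ~100 µm² (semi-adherent
insect-cell regime), nuclei ~0.22–0.30 of the cell radius, DAPI nuclei at
intensity 200 on background 5, foci channel with cytoplasm 12, nuclear
poly(A) signal 35 and background 2 on a 0–255 working range (the
post-clipping regime of 16-bit confocal data whose foci-channel signal
stays below ~50). Half the cells are positive and carry 2–6 granules drawn
from the eight-morphology library with ±10% size jitter, peak amplitudes
24–45 over cytoplasm, and additive Gaussian noise σ = 2 (worst-case
granule SNR 12). Granule centres keep ≥ 12 px mutual separation and a 9-px
clearance from the nuclear rim and the cytoplasm edge so that each planted
granule is an unambiguous detection target whose correlation window is not
contaminated by the bright nuclear rim or the cell border. Positive-cell
counts per field use stochastic rounding of `fraction_positive · n_cells`
(unbiased with minimal variance); the recorded truth reflects the
*realised* field — a cell whose cytoplasm could not fit two granules is
not counted positive.

The default prototype bank is extracted from noiseless renderings of the
eight morphologies on plain cytoplasm, with a 2-px margin, paired with the
calibrated STs above. Because the bank and the generator share the
morphology library, a green detection test establishes that the
correlation/threshold/merge machinery works at the published operating
point — it does **not** establish performance on real micrographs, whose
granules are not drawn from the template family and whose background
contains structured texture, illumination gradients and optical blur that
the generator does not model (no PSF simulation, no photobleaching, no
camera gain). The `compound` granule mode renders large foci as
multi-lobed aggregates (max-composed round lobes) for experiments on
textured objects.

## Numerical choices

- Correlation maps are invalid (NaN) where the patch does not fit; no
  padding, so no rim artifacts. Zero-variance windows correlate 0.
- "Above the ST" is strict (`>`); FFT-based correlation values are clipped
  to [−1, 1] and NaN-scrubbed before thresholding.
- All filters replicate borders; outputs are clamped to the channel's
  representable range.
- Constant images pass through contrast stretch unchanged (logged).
- The Wiener gain is `max(σ²−ν, 0)/max(σ², ν)` with ν the mean local
  variance; a zero-variance image divides safely to 0.
- Downscaling is bicubic with anti-aliasing and rescales the pixel size by
  the geometric factor, preserving physical areas.
- Watershed, connected components and dilation all use 8-connectivity;
  with 3×3 dilation two seeds merge iff their Chebyshev distance ≤ 3
  (at 4 a one-pixel gap remains).
- Determinism: the pipeline has no randomness; the generator is fully
  reproducible from (spec, seed), and plate seeds are spawned via
  `SeedSequence`.

## Known limitations

- Object size from merged seeds is a correlation footprint, not a physical
  area; use `halfmax` mode for size comparisons, and no size measured by
  confocal microscopy escapes the point-spread-function convolution —
  absolute areas near the diffraction limit are overestimates.
- Touching nuclei are not declumped; each merged nuclear component becomes
  one marker, hence one cell.
- The screen score is a plain control ratio; no plate-effect normalisation
  (B-score/Z′) or hit-calling statistics are provided.
- Multi-series microscope containers are not parsed; single-plane TIFF/LSM
  pages (and PNG fixtures) only.
- Detection runs on the clipped, unscaled foci channel; the gain/denoise
  chain feeds only the watershed elevation (configurable via
  `detection.detect_on_denoised`). The alternative reading — detecting on
  the denoised channel — changes little on synthetic fields but is kept
  switchable because the original processing order is ambiguous.
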