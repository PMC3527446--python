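"""End-to-end field processing: preprocess -> segment -> detect -> quantify.

The stage order is fixed and fully deterministic:

1.  clip both channels to the working cap;
2.  contrast-stretch the nuclear channel and threshold it into the
    nuclear mask (markers);
3.  denoise and gain-boost the foci channel, invert it into the elevation
    surface, and run the marker-controlled watershed;
4.  correlate the (clipped, unscaled) foci channel against the prototype
    bank, with an optional second pass on the unsharp-filtered channel;
5.  remove nuclear/extracellular seeds, merge the survivors into focus
    objects, and drop cells below the minimum area;
6.  assign foci to cells and summarise.

Per-field failures are reported and skipped so one bad field does not
abort a plate run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import cell_segmentation as seg
from . import foci_detection as det
from . import image_io as io
from . import quantification as quant
from .config import PipelineConfig
from .foci_detection import FocusObject, PrototypeBank
from .image_io import ImageSet

logger = logging.getLogger(__name__)


class FieldProcessingError(RuntimeError):
    """A stage failed for one field; carries the field id and stage name."""

    def __init__(self, field_id: str, stage: str, cause: Exception):
        super().__init__(f"field {field_id!r} failed at stage {stage!r}: {cause}")
        self.field_id = field_id
        self.stage = stage
        self.cause = cause


@dataclass
class FieldResult:
    """All per-field outputs of one pipeline run."""

    field_id: str
    labels: seg.CellLabelMap
    nuclear_mask: seg.BinaryMask
    foreground: seg.BinaryMask
    foci: list[FocusObject]
    cells: list[quant.CellRecord]
    summary: quant.FieldSummary
    intermediates: dict[str, object] = field(default_factory=dict)

    def cell_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "n_foci": c.n_foci,
                "positive": c.positive,
                "area_um2": c.area_um2,
                "nucleus_row": self.labels.nucleus_centroids.get(c.cell_id, (float("nan"),) * 2)[0],
                "nucleus_col": self.labels.nucleus_centroids.get(c.cell_id, (float("nan"),) * 2)[1],
                "border_touching": self.labels.border_touching.get(c.cell_id, False),
            }
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "n_foci", "positive", "area_um2",
                "nucleus_row", "nucleus_col", "border_touching",
            ],
        )

    def focus_table(self) -> pd.DataFrame:
        rows = [
            {
                "focus_id": o.focus_id,
                "row": o.point[0],
                "col": o.point[1],
                "pixel_count": o.pixel_count,
                "area_um2": o.area_um2,
                "size_reliable": o.size_reliable,
                "cell_id": o.cell_id,
                "prototype_hits": "+".join(sorted(o.prototype_hits)),
            }
            for o in self.foci
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "focus_id", "row", "col", "pixel_count", "area_um2",
                "size_reliable", "cell_id", "prototype_hits",
            ],
        )


def process_field(
    images: ImageSet,
    config: PipelineConfig,
    bank: PrototypeBank,
    keep_intermediates: bool = False,
) -> FieldResult:
    """Run the full pipeline on one field."""
    pp, sg, dt, qc = (
        config.preprocessing,
        config.segmentation,
        config.detection,
        config.quantification,
    )
    if dt.similarity_thresholds is not None:
        bank = bank.with_thresholds(dt.similarity_thresholds)
    if dt.use_rotations:
        bank = bank.with_rotations()

    stage = "preprocess"
    try:
        nuclear = io.clip_intensity(images.nuclear, pp.cap)
        foci_clipped = io.clip_intensity(images.foci, pp.cap)
        nuclear_stretched = io.contrast_stretch(nuclear, pp.stretch_low, pp.stretch_high)

        stage = "nuclear_mask"
        nuc_mask = seg.make_nuclear_mask(nuclear_stretched, sg.threshold_frac)

        stage = "watershed"
        foci_denoised = io.wiener_denoise(foci_clipped, pp.wiener_window)
        elevation = seg.build_elevation(foci_denoised, nuc_mask, pp.gain, pp.cap)
        labels = seg.segment_cells(elevation, nuc_mask)
        foci_stretched = io.contrast_stretch(
            foci_denoised, pp.stretch_low, pp.stretch_high
        )
        foreground = seg.cell_foreground(foci_stretched, labels, sg.foreground_frac)
        labels = seg.filter_small_cells(labels, sg.min_cell_area_um2, foreground)

        stage = "detect"
        detect_channel = foci_denoised if dt.detect_on_denoised else foci_clipped
        seeds = det.detect_seeds(
            detect_channel, bank, dt.use_sharpened_pass, pp.unsharp_alpha
        )
        seeds = det.mask_seeds(seeds, nuc_mask, foreground)

        stage = "merge"
        foci = det.merge_seeds(seeds, images.pixel_size_um)
        for obj in foci:
            obj.size_reliable = det.size_reliability(obj, qc.size_reliability_width_px)
        if qc.size_mode == "halfmax":
            foci = det.refine_focus_sizes(
                detect_channel, foci, min_width_px=qc.size_reliability_width_px
            )
        if dt.min_focus_area_um2 > 0:
            foci = det.filter_small_foci(foci, dt.min_focus_area_um2)

        stage = "quantify"
        foci = quant.assign_foci_to_cells(foci, labels)
        cells = quant.tally_cells(foci, labels, qc.min_foci_for_positive)
        summary = quant.summarize_field(
            cells,
            qc.min_foci_for_positive,
            foci=foci,
            field_id=images.field_id,
            well_id=images.well_id,
        )
    except Exception as exc:
        raise FieldProcessingError(images.field_id, stage, exc) from exc

    intermediates: dict[str, object] = {}
    if keep_intermediates:
        intermediates = {
            "nuclear_stretched": nuclear_stretched,
            "elevation": elevation,
            "seeds": seeds,
        }
    return FieldResult(
        field_id=images.field_id,
        labels=labels,
        nuclear_mask=nuc_mask,
        foreground=foreground,
        foci=foci,
        cells=cells,
        summary=summary,
        intermediates=intermediates,
    )


def run_pipeline(
    image_sets: Iterable[ImageSet],
    config: PipelineConfig,
    bank: PrototypeBank,
    on_error: str = "skip",
) -> tuple[list[FieldResult], list[FieldProcessingError]]:
    """Process many fields; failed fields are collected, not fatal.

    With ``on_error="raise"`` the first failure propagates instead.
    """
    results: list[FieldResult] = []
    errors: list[FieldProcessingError] = []
    for images in image_sets:
        try:
            results.append(process_field(images, config, bank))
        except FieldProcessingError as err:
            if on_error == "raise":
                raise
            logger.warning("%s", err)
            errors.append(err)
    return results, errors
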