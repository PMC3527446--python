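"""Nuclear masking and marker-controlled watershed cell segmentation.

Cells are segmented by treating the (denoised, gain-boosted, inverted) foci
channel as a topographic surface: nuclei, forced to zero elevation, are the
basin bottoms; the stained cytoplasm forms the valley slopes; unstained
background is the high ground.  A marker-controlled watershed grown from
the nucleus components then assigns each pixel to the cell of its nearest
(in the topographic sense) nucleus, with watershed ridge lines separating
adjacent cells.

Because the watershed tessellates the whole field, implausibly small cells
and extracellular territory are removed afterwards with a stained-material
foreground mask and a minimum cytoplasmic-area filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .image_io import ChannelImage

logger = logging.getLogger(__name__)

# 8-neighbour connectivity structure used throughout segmentation.
_STRUCT8 = np.ones((3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when no nuclei are found in a field."""


@dataclass
class BinaryMask:
    """A 2-D {0,1} mask with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class CellLabelMap:
    """Integer partition of the field into per-cell regions.

    ``labels`` holds 0 for unassigned/ridge/excluded pixels and k >= 1 for
    cell k.  Each surviving label is tied to exactly one nucleus component;
    per-label centroids and areas are carried alongside.
    """

    labels: np.ndarray
    pixel_size_um: float
    nucleus_centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    cell_areas_um2: dict[int, float] = field(default_factory=dict)
    border_touching: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def cell_ids(self) -> list[int]:
        """Sorted list of surviving cell labels."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def make_nuclear_mask(
    nuclear: ChannelImage, threshold_frac: float = 0.6
) -> BinaryMask:
    """Threshold the (contrast-stretched) nuclear channel into a mask.

    Pixels at or above ``threshold_frac`` of the image maximum become 1,
    the rest 0.  Using the observed maximum rather than the theoretical cap
    keeps the rule robust on dim fields.  Interior holes (e.g. dark
    nucleoli) are filled so each nucleus is a single solid marker.

    Raises
    ------
    EmptyMaskError
        If no pixel reaches the threshold (field should be skipped).
    """
    if not (0 < threshold_frac < 1):
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    mx = float(nuclear.pixels.max()) if nuclear.pixels.size else 0.0
    mask = nuclear.pixels >= threshold_frac * mx if mx > 0 else np.zeros_like(
        nuclear.pixels, dtype=bool
    )
    if not mask.any():
        raise EmptyMaskError("no nuclei found (empty nuclear mask)")
    if mask.all():
        logger.warning("make_nuclear_mask: whole field above threshold (degenerate)")
    mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(pixels=mask, pixel_size_um=nuclear.pixel_size_um)


def build_elevation(
    foci: ChannelImage, nuc_mask: BinaryMask, gain: float = 2.0, cap: float = 255.0
) -> ChannelImage:
    """Build the watershed elevation surface from the foci channel.

    The faint cytoplasmic stain is boosted by ``gain`` (then capped) and
    inverted, so stained material is low and empty background high; nuclear
    pixels are forced to elevation 0 and become the basin bottoms.
    """
    if foci.shape != nuc_mask.shape:
        raise ValueError("foci channel and nuclear mask shapes differ")
    if gain < 1:
        raise ValueError(f"gain must be >= 1, got {gain}")
    boosted = np.minimum(gain * foci.pixels, cap)
    elevation = cap - boosted
    elevation[nuc_mask.pixels] = 0.0
    return foci.with_pixels(elevation)


def segment_cells(elevation: ChannelImage, nuc_mask: BinaryMask) -> CellLabelMap:
    """Marker-controlled watershed: one basin per nucleus component.

    Nucleus components are the markers, so the number of cell labels equals
    the number of nuclei and each basin contains its entire marker.  Ridge
    pixels between basins carry label 0.
    """
    markers, n_nuclei = ndimage.label(nuc_mask.pixels, structure=_STRUCT8)
    if n_nuclei == 0:
        raise EmptyMaskError("nuclear mask has no components")
    labels = watershed(
        elevation.pixels, markers=markers, connectivity=2, watershed_line=True
    )
    centroids: dict[int, tuple[float, float]] = {}
    for prop in regionprops(markers):
        centroids[int(prop.label)] = (float(prop.centroid[0]), float(prop.centroid[1]))
    px_area = elevation.pixel_size_um**2
    areas = {
        int(k): float(v) * px_area
        for k, v in zip(*np.unique(labels[labels > 0], return_counts=True))
    }
    border = _border_touching(labels)
    return CellLabelMap(
        labels=labels,
        pixel_size_um=elevation.pixel_size_um,
        nucleus_centroids=centroids,
        cell_areas_um2=areas,
        border_touching=border,
    )


def _border_touching(labels: np.ndarray) -> dict[int, bool]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    on_edge = set(int(v) for v in np.unique(edge) if v > 0)
    return {int(k): int(k) in on_edge for k in np.unique(labels) if k > 0}


def cell_foreground(
    foci: ChannelImage,
    labels: CellLabelMap | None = None,
    foreground_frac: float = 0.05,
) -> BinaryMask:
    """Mask of stained cell material (cytoplasm or nucleus).

    Pixels at or above ``foreground_frac`` of the foci-channel maximum are
    foreground; the complement is treated as extracellular.  A fraction of
    0 makes the whole field foreground, disabling extracellular filtering.
    """
    if not (0 <= foreground_frac < 1):
        raise ValueError(f"foreground_frac must be in [0, 1), got {foreground_frac}")
    if foreground_frac == 0:
        mask = np.ones_like(foci.pixels, dtype=bool)
    else:
        mx = float(foci.pixels.max()) if foci.pixels.size else 0.0
        mask = foci.pixels >= foreground_frac * mx
        mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(pixels=mask, pixel_size_um=foci.pixel_size_um)


def filter_small_cells(
    labels: CellLabelMap,
    min_cell_area_um2: float = 30.0,
    foreground: BinaryMask | None = None,
) -> CellLabelMap:
    """Drop cells whose stained area falls below ``min_cell_area_um2``.

    Small, irregular cells (partially attached or unhealthy) are excluded
    from analysis.  Area is measured over the basin intersected with the
    stained foreground when a foreground mask is supplied — basins
    tessellate the whole field, so raw basin area would overstate cell
    size — and over the whole basin otherwise.
    """
    if min_cell_area_um2 < 0:
        raise ValueError("min_cell_area_um2 must be >= 0")
    lab = labels.labels.copy()
    px_area = labels.pixel_size_um**2
    measured = lab if foreground is None else np.where(foreground.pixels, lab, 0)
    keep_areas: dict[int, float] = {}
    vals, counts = np.unique(measured[measured > 0], return_counts=True)
    fg_area = {int(v): float(c) * px_area for v, c in zip(vals, counts)}
    removed = []
    for cid in labels.cell_ids:
        area = fg_area.get(cid, 0.0)
        if area < min_cell_area_um2:
            lab[lab == cid] = 0
            removed.append(cid)
        else:
            keep_areas[cid] = area
    if removed:
        logger.info("filter_small_cells: removed %d cells %s", len(removed), removed)
    return CellLabelMap(
        labels=lab,
        pixel_size_um=labels.pixel_size_um,
        nucleus_centroids={
            k: v for k, v in labels.nucleus_centroids.items() if k in keep_areas
        },
        cell_areas_um2=keep_areas,
        border_touching={
            k: v for k, v in labels.border_touching.items() if k in keep_areas
        },
    )
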