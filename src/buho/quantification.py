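"""Per-cell counting, positivity, focus size and inter-object distances.

Combining the focus objects with the watershed label map yields per-cell
granule counts.  A cell is scored positive when it holds at least
``min_foci_for_positive`` foci (default 2: a single punctum is not treated
as a stress response).  Field summaries report cell number, focus number,
the percentage of positive cells, and mean foci per positive cell — the
quantities tracked in time-course and screening experiments.

Distances between object classes (e.g. synapse -> nearest mRNA-silencing
focus) use Euclidean distance-transform semantics: the distance from each
target's representative point to the nearest pixel of any focus object, so
a target overlapping a focus is at distance 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cell_segmentation import CellLabelMap
from .foci_detection import FocusObject


@dataclass
class CellRecord:
    """Focus tally for one cell."""

    cell_id: int
    n_foci: int
    positive: bool
    focus_ids: list[int] = field(default_factory=list)
    area_um2: float = float("nan")


@dataclass
class FieldSummary:
    """Per-field statistics over cells and foci.

    ``mean_foci_per_positive_cell`` follows the screening convention of
    averaging over positive cells only; ``mean_focus_area_um2`` uses
    size-reliable objects only.  Undefined means are NaN.
    """

    field_id: str
    n_cells: int
    n_foci: int
    n_positive_cells: int
    pct_positive: float
    mean_foci_per_positive_cell: float
    mean_focus_area_um2: float
    n_unassigned_foci: int = 0
    well_id: Optional[str] = None


@dataclass
class DistanceResult:
    """Nearest-focus distance per target and the within-radius fraction."""

    distances_um: np.ndarray
    radius_um: float
    fraction_within: float


def assign_foci_to_cells(
    foci: Sequence[FocusObject], labels: CellLabelMap
) -> list[FocusObject]:
    """Assign each focus to the cell whose basin contains its point.

    Foci whose representative point lands on a ridge or excluded pixel get
    ``cell_id`` 0 and are reported as unassigned rather than dropped
    silently.
    """
    for obj in foci:
        obj.cell_id = int(labels.labels[obj.point])
    return list(foci)


def tally_cells(
    foci: Sequence[FocusObject],
    labels: CellLabelMap,
    min_foci_for_positive: int = 2,
) -> list[CellRecord]:
    """Build per-cell records from assigned foci (every cell, even empty)."""
    by_cell: dict[int, list[FocusObject]] = {}
    for obj in foci:
        by_cell.setdefault(obj.cell_id, []).append(obj)
    records = []
    for cid in labels.cell_ids:
        cell_foci = by_cell.get(cid, [])
        records.append(
            CellRecord(
                cell_id=cid,
                n_foci=len(cell_foci),
                positive=len(cell_foci) >= min_foci_for_positive,
                focus_ids=[o.focus_id for o in cell_foci],
                area_um2=labels.cell_areas_um2.get(cid, float("nan")),
            )
        )
    return records


def summarize_field(
    cells: Sequence[CellRecord],
    min_foci_for_positive: int = 2,
    foci: Sequence[FocusObject] = (),
    field_id: str = "field",
    well_id: Optional[str] = None,
) -> FieldSummary:
    """Field-level tally: counts, % positive cells, foci per positive cell.

    A cell is positive when it contains ``min_foci_for_positive`` or more
    foci.  With zero cells all counts are 0 and the means are NaN.
    """
    if min_foci_for_positive < 1:
        raise ValueError("min_foci_for_positive must be >= 1")
    n_cells = len(cells)
    positive = [c for c in cells if c.n_foci >= min_foci_for_positive]
    n_foci_assigned = sum(c.n_foci for c in cells)
    foci_in_positive = sum(c.n_foci for c in positive)
    unassigned = sum(1 for o in foci if o.cell_id == 0)
    reliable_areas = [o.area_um2 for o in foci if o.size_reliable]
    return FieldSummary(
        field_id=field_id,
        well_id=well_id,
        n_cells=n_cells,
        n_foci=n_foci_assigned,
        n_positive_cells=len(positive),
        pct_positive=100.0 * len(positive) / n_cells if n_cells else 0.0,
        mean_foci_per_positive_cell=(
            foci_in_positive / len(positive) if positive else float("nan")
        ),
        mean_focus_area_um2=(
            float(np.mean(reliable_areas)) if reliable_areas else float("nan")
        ),
        n_unassigned_foci=unassigned,
    )


def _foci_mask(
    foci: Sequence[FocusObject], shape: tuple[int, int]
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for obj in foci:
        mask[obj.pixel_set[:, 0], obj.pixel_set[:, 1]] = True
    return mask


def nearest_object_distances(
    targets: Sequence[FocusObject],
    foci: Sequence[FocusObject],
    shape: tuple[int, int],
    pixel_size_um: float,
    radius_um: float = 0.5,
) -> DistanceResult:
    """Distance from each target point to the nearest focus pixel, in um.

    Computed as the Euclidean distance transform of the complement of the
    pooled focus mask, sampled at each target's representative point; a
    target overlapping a focus is at distance 0.  ``fraction_within`` is
    the share of targets closer than ``radius_um``.  With no foci at all,
    every distance is infinite and the fraction is 0.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be > 0")
    n_targets = len(targets)
    if n_targets == 0:
        return DistanceResult(np.array([]), radius_um, 0.0)
    if len(foci) == 0:
        return DistanceResult(np.full(n_targets, np.inf), radius_um, 0.0)
    mask = _foci_mask(foci, shape)
    dist_px = ndimage.distance_transform_edt(~mask)
    dists = np.array(
        [float(dist_px[t.point]) * pixel_size_um for t in targets]
    )
    fraction = float(np.mean(dists < radius_um))
    return DistanceResult(dists, radius_um, fraction)


def size_change_report(
    groups: Mapping[str, Sequence[FocusObject]],
    reference: str,
    reliable_only: bool = True,
) -> pd.DataFrame:
    """Per-group mean focus area and ratio versus a reference group.

    Used to quantify stress-induced focus enlargement (e.g. P-bodies
    growing severalfold under oxidative stress).  Only size-reliable
    objects enter by default; a group left with no usable object is
    flagged missing (NaN mean).
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups")
    rows = []
    means: dict[str, float] = {}
    for name, objs in groups.items():
        usable = [o for o in objs if o.size_reliable] if reliable_only else list(objs)
        means[name] = float(np.mean([o.area_um2 for o in usable])) if usable else float("nan")
        rows.append(
            {
                "group": name,
                "n_objects": len(objs),
                "n_used": len(usable),
                "mean_area_um2": means[name],
            }
        )
    ref_mean = means[reference]
    df = pd.DataFrame(rows).set_index("group")
    df["ratio_vs_reference"] = [
        m / ref_mean if (ref_mean and not math.isnan(ref_mean)) else float("nan")
        for m in df["mean_area_um2"]
    ]
    return df
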