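"""Well/plate aggregation and RNAi screen scoring.

A well is imaged as several fields; its percentage of foci-positive cells
is pooled over all cells in the well (cell-weighted), not averaged over
field percentages, because fields differ in cell count.  The screen score
of a well is the ratio of its percent-positive to the mean percent-positive
of the untreated control wells on the same plate, so control wells score
~1, knockdowns that impair focus formation score below 1 and enhancers
score above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .quantification import FieldSummary

logger = logging.getLogger(__name__)


@dataclass
class WellSummary:
    """Pooled per-well statistics over its imaged fields."""

    plate_id: str
    well_id: str
    treatment: str
    n_fields: int
    n_cells: int
    n_foci: int
    n_positive_cells: int
    pct_positive: float
    mean_foci_per_positive_cell: float
    is_control: bool = False
    valid: bool = True


@dataclass
class ScreenScore:
    """Control-normalised score for one well."""

    plate_id: str
    well_id: str
    score: float
    control_mean_pct: float
    n_control_wells: int


def aggregate_well(
    fields: Sequence[FieldSummary],
    plate_id: str = "plate",
    well_id: Optional[str] = None,
    treatment: str = "",
    is_control: bool = False,
) -> WellSummary:
    """Pool field summaries of one well into cell-weighted well statistics.

    Zero-cell fields contribute nothing; a well with no cells at all is
    flagged invalid (and warned about) rather than raising.
    """
    if not fields:
        raise ValueError("aggregate_well needs at least one field")
    wid = well_id if well_id is not None else (fields[0].well_id or "well")
    field_wells = {f.well_id for f in fields if f.well_id is not None}
    if len(field_wells) > 1:
        raise ValueError(f"fields from different wells: {field_wells}")
    n_cells = sum(f.n_cells for f in fields)
    n_pos = sum(f.n_positive_cells for f in fields)
    n_foci = sum(f.n_foci for f in fields)
    foci_in_positive = sum(
        f.mean_foci_per_positive_cell * f.n_positive_cells
        for f in fields
        if f.n_positive_cells > 0
    )
    valid = n_cells > 0
    if not valid:
        logger.warning("aggregate_well: well %s has zero cells", wid)
    return WellSummary(
        plate_id=plate_id,
        well_id=wid,
        treatment=treatment,
        n_fields=len(fields),
        n_cells=n_cells,
        n_foci=n_foci,
        n_positive_cells=n_pos,
        pct_positive=100.0 * n_pos / n_cells if valid else float("nan"),
        mean_foci_per_positive_cell=(
            foci_in_positive / n_pos if n_pos else float("nan")
        ),
        is_control=is_control,
        valid=valid,
    )


def rnai_score(well: WellSummary, controls: Sequence[WellSummary]) -> ScreenScore:
    """Score a well against the mean percent-positive of in-plate controls."""
    controls = [c for c in controls if c.valid]
    if not controls:
        raise ValueError(f"no valid control wells for plate {well.plate_id}")
    off_plate = [c.well_id for c in controls if c.plate_id != well.plate_id]
    if off_plate:
        raise ValueError(f"control wells {off_plate} are not on plate {well.plate_id}")
    control_mean = sum(c.pct_positive for c in controls) / len(controls)
    if control_mean <= 0:
        logger.warning(
            "rnai_score: zero control mean on plate %s; score undefined", well.plate_id
        )
        score = float("nan")
    else:
        score = well.pct_positive / control_mean
    return ScreenScore(
        plate_id=well.plate_id,
        well_id=well.well_id,
        score=score,
        control_mean_pct=control_mean,
        n_control_wells=len(controls),
    )


def plate_report(
    wells: Sequence[WellSummary], scores: Sequence[ScreenScore]
) -> pd.DataFrame:
    """One row per well with summary fields and score, sorted (plate, well)."""
    score_by_key = {(s.plate_id, s.well_id): s for s in scores}
    rows = []
    for w in wells:
        s = score_by_key.get((w.plate_id, w.well_id))
        rows.append(
            {
                "plate_id": w.plate_id,
                "well_id": w.well_id,
                "treatment": w.treatment,
                "is_control": w.is_control,
                "n_fields": w.n_fields,
                "n_cells": w.n_cells,
                "n_foci": w.n_foci,
                "pct_positive": w.pct_positive,
                "foci_per_positive_cell": w.mean_foci_per_positive_cell,
                "score": s.score if s else float("nan"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well_id",
            "treatment",
            "is_control",
            "n_fields",
            "n_cells",
            "n_foci",
            "pct_positive",
            "foci_per_positive_cell",
            "score",
        ],
    )
    return df.sort_values(["plate_id", "well_id"]).reset_index(drop=True)
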