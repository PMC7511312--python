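"""Evans-Blue dye-exclusion mortality: classification, fractions, aggregation.

A membrane-impermeable dye only enters cells whose plasma membrane has lost
integrity, so the stained ("blue") fraction of a counted population is the
mortality. Two entry points are supported:

* tabular mode — CSV-style count records (total cells, stained cells) per
  sample, the hemocytometer workflow; and
* image mode — an invented stand-in for visual scoring: a segmented cell is
  called dead when its mean blue intensity dominates the red and green
  channels by a configurable relative margin (the published assay scored
  by eye and states no colour threshold).

Aggregation reports mean mortality +/- s.e. across experimental series per
condition x timepoint, with a warning when fewer than 1,500 cells back a
summary (the assay's counting target).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imaging import CellRegion, as_micrograph

__all__ = [
    "CountRecord",
    "MortalitySummary",
    "mortality_fraction",
    "aggregate_mortality",
    "classify_stained",
    "records_from_frame",
]

#: Counting target per experiment; fewer pooled cells triggers a warning.
TARGET_CELLS_PER_EXPERIMENT = 1500


@dataclass(frozen=True)
class CountRecord:
    """One hemocytometer count: total and stained (dead) cells."""

    sample_id: str
    condition: str
    timepoint_h: float
    total_cells: int
    stained_cells: int

    def __post_init__(self) -> None:
        if self.total_cells <= 0:
            raise ValidationError("total_cells must be positive")
        if not (0 <= self.stained_cells <= self.total_cells):
            raise ValidationError("stained_cells must lie in [0, total_cells]")


@dataclass(frozen=True)
class MortalitySummary:
    """Mean mortality (%) +/- s.e. for one condition x timepoint."""

    condition: str
    timepoint_h: float
    mortality_pct: float
    se_pct: float
    n_cells: int
    n_records: int


def mortality_fraction(rec: CountRecord) -> float:
    """Mortality of one count record: 100 * stained / total (percent)."""
    return 100.0 * rec.stained_cells / rec.total_cells


def aggregate_mortality(records: Sequence[CountRecord]) -> List[MortalitySummary]:
    """Mean +/- s.e. of per-record mortality per condition x timepoint.

    Each record is treated as one experimental series; the s.e. spans
    records within a group (0 for a single record). Record order is
    irrelevant. Results carry one decimal of precision in percent when
    serialised by the CLI; full precision is kept here.
    """
    if not records:
        raise ValidationError("no count records to aggregate")
    frame = pd.DataFrame(
        {
            "condition": [r.condition for r in records],
            "timepoint_h": [r.timepoint_h for r in records],
            "pct": [mortality_fraction(r) for r in records],
            "total": [r.total_cells for r in records],
        }
    )
    out: List[MortalitySummary] = []
    for (cond, tp), grp in sorted(
        frame.groupby(["condition", "timepoint_h"]), key=lambda kv: (str(kv[0][0]), kv[0][1])
    ):
        n_cells = int(grp["total"].sum())
        if n_cells < TARGET_CELLS_PER_EXPERIMENT:
            warnings.warn(
                f"{cond} @ {tp} h: {n_cells} cells pooled, below the "
                f"{TARGET_CELLS_PER_EXPERIMENT}-cell counting target",
                stacklevel=2,
            )
        pcts = grp["pct"].to_numpy()
        se = float(np.std(pcts, ddof=1) / math.sqrt(len(pcts))) if len(pcts) > 1 else 0.0
        out.append(
            MortalitySummary(
                condition=str(cond),
                timepoint_h=float(tp),
                mortality_pct=float(pcts.mean()),
                se_pct=se,
                n_cells=n_cells,
                n_records=int(len(grp)),
            )
        )
    return out


def classify_stained(
    img: np.ndarray,
    regions: Sequence[CellRegion],
    *,
    margin: float = 0.4,
) -> np.ndarray:
    """Label segmented cells dead (True) or alive (False) by blue dominance.

    A cell is called dead when its mean blue intensity exceeds the larger
    of its mean red and green intensities by the relative ``margin``:
    ``B > (1 + margin) * max(R, G)``. In bright field an Evans-Blue-stained
    cell transmits blue while absorbing red and green, whereas the
    photosynthetic pigments of a live cell absorb blue at least as strongly
    as red/green, so blue never dominates a live cell by a large margin.
    The rule and margin are stand-ins for the visual scoring of the assay.
    """
    img = as_micrograph(img).astype(float)
    if margin < 0:
        raise ValidationError("margin must be non-negative")
    labels = np.empty(len(regions), dtype=bool)
    for i, region in enumerate(regions):
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        r, g, b = (img[rows, cols, c].mean() for c in range(3))
        labels[i] = b > (1.0 + margin) * max(r, g)
    return labels


def records_from_frame(frame: pd.DataFrame) -> List[CountRecord]:
    """Build validated count records from a tidy table.

    Expects columns ``sample_id``, ``condition``, ``timepoint_h``,
    ``total_cells``, ``stained_cells``.
    """
    required = ["sample_id", "condition", "timepoint_h", "total_cells", "stained_cells"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"count table missing columns: {missing}")
    return [
        CountRecord(
            sample_id=str(row.sample_id),
            condition=str(row.condition),
            timepoint_h=float(row.timepoint_h),
            total_cells=int(row.total_cells),
            stained_cells=int(row.stained_cells),
        )
        for row in frame.itertuples()
    ]
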