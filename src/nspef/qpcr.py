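"""Relative transcript quantification by the 2^(-ddCt) method.

Raw qPCR cycle-threshold (Ct) values are normalised in two steps: within
each sample against a housekeeping gene (actin by default), giving
``dCt = Ct_target - Ct_housekeeping``, and then against a reference sample
(untreated control at 18 h by default), giving
``ddCt = dCt_sample - mean dCt_reference`` and the fold change
``2^(-ddCt)``.

Replicate handling follows standard practice for a 3 biological x 3
technical design: technical replicates are collapsed first (arithmetic mean
Ct per biological replicate), fold changes are computed per biological
replicate, and the standard error spans biological replicates only. The
summary fold of a group is ``2^(-(mean dCt - mean dCt_ref))`` — the fold of
the mean ddCt — which makes the reference cell of the table exactly 1 by
construction. An ``se_across="measurements"`` option instead propagates all
technical measurements into the spread estimate.

Input is a tidy table with columns ``gene``, ``condition``, ``timepoint_h``,
``bio_rep``, ``tech_rep``, ``ct``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CT_COLUMNS",
    "ReferenceSpec",
    "validate_ct_table",
    "collapse_technical",
    "delta_ct",
    "fold_change",
    "expression_table",
]

CT_COLUMNS = ["gene", "condition", "timepoint_h", "bio_rep", "tech_rep", "ct"]

_SAMPLE_KEY = ["condition", "timepoint_h", "bio_rep"]


@dataclass(frozen=True)
class ReferenceSpec:
    """Normalisation anchors: housekeeping gene and baseline sample."""

    housekeeping_gene: str = "actin"
    baseline_condition: str = "control"
    baseline_timepoint_h: float = 18.0


def validate_ct_table(records: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, Ct range, and design completeness.

    Ct values must lie in (0, 45). An incomplete 3x3 replicate design per
    (gene, condition, timepoint) raises a warning, not an error.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    if records.empty:
        raise ValidationError("Ct table is empty")
    ct = records["ct"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ct)) or np.any((ct <= 0) | (ct >= 45)):
        raise ValidationError("Ct values must lie in the open interval (0, 45)")
    design = records.groupby(["gene", "condition", "timepoint_h"]).agg(
        n_bio=("bio_rep", "nunique"), n=("ct", "size")
    )
    incomplete = design[(design["n_bio"] != 3) | (design["n"] != 9)]
    if not incomplete.empty:
        warnings.warn(
            f"{len(incomplete)} (gene, condition, timepoint) groups deviate from the "
            "3 biological x 3 technical design",
            stacklevel=2,
        )
    return records


def collapse_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates, per biological replicate.

    Returns a table keyed by (gene, condition, timepoint_h, bio_rep) with a
    single ``ct`` column. Order of technical replicates is irrelevant.
    """
    validate_ct_table(records)
    out = (
        records.groupby(["gene"] + _SAMPLE_KEY, as_index=False, sort=True)["ct"]
        .mean()
    )
    return out


def delta_ct(collapsed: pd.DataFrame, housekeeping_gene: str = "actin") -> pd.DataFrame:
    """dCt = Ct_target - Ct_housekeeping, paired within each sample.

    ``collapsed`` is the output of :func:`collapse_technical`. Every sample
    (condition, timepoint, biological replicate) must carry a housekeeping
    measurement; target genes lacking their sample's housekeeping value
    raise a validation error.
    """
    if housekeeping_gene not in set(collapsed["gene"]):
        raise ConfigurationError(
            f"housekeeping gene {housekeeping_gene!r} absent from the Ct table"
        )
    hk = collapsed[collapsed["gene"] == housekeeping_gene].set_index(_SAMPLE_KEY)["ct"]
    targets = collapsed[collapsed["gene"] != housekeeping_gene].copy()
    idx = pd.MultiIndex.from_frame(targets[_SAMPLE_KEY])
    if not idx.isin(hk.index).all():
        raise ValidationError(
            "some samples lack a housekeeping Ct measurement; cannot pair dCt"
        )
    targets["delta_ct"] = targets["ct"].to_numpy() - hk.loc[idx].to_numpy()
    return targets.drop(columns="ct")


def fold_change(delta_ct_sample: float, delta_ct_reference: float, efficiency: float = 2.0) -> float:
    """Fold change ``efficiency^(-(dCt_sample - dCt_reference))``.

    The amplification efficiency defaults to 2 (perfect doubling per
    cycle); a Pfaffl-style efficiency can be supplied instead.
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    return float(efficiency ** -(delta_ct_sample - delta_ct_reference))


def expression_table(
    records: pd.DataFrame,
    refspec: ReferenceSpec = ReferenceSpec(),
    *,
    efficiency: float = 2.0,
    se_across: str = "biological",
) -> pd.DataFrame:
    """Full ddCt pipeline: tidy Ct records -> per-group fold changes.

    Returns one row per (gene, condition, timepoint_h) with:

    ``mean_fold``
        ``efficiency^(-(mean dCt - mean dCt_ref))``; exactly 1 at the
        reference cell.
    ``se_fold``
        Standard error of the per-biological-replicate fold changes
        (``se_across="biological"``, default) or of per-technical-
        measurement folds (``se_across="measurements"``).
    ``n_bio``, ``n_total``
        Replicate counts entering the row.

    The reference dCt per gene is the mean over biological replicates of
    the baseline condition/timepoint named by ``refspec``.
    """
    if se_across not in ("biological", "measurements"):
        raise ValidationError(f"unknown se_across mode {se_across!r}")
    collapsed = collapse_technical(records)
    d = delta_ct(collapsed, refspec.housekeeping_gene)

    ref_mask = (d["condition"] == refspec.baseline_condition) & (
        d["timepoint_h"] == refspec.baseline_timepoint_h
    )
    if not ref_mask.any():
        raise ConfigurationError(
            f"reference sample ({refspec.baseline_condition!r} at "
            f"{refspec.baseline_timepoint_h} h) absent from the Ct table"
        )
    ref_dct = d[ref_mask].groupby("gene")["delta_ct"].mean()
    missing_ref = set(d["gene"]) - set(ref_dct.index)
    if missing_ref:
        raise ConfigurationError(f"genes lack reference measurements: {sorted(missing_ref)}")

    d = d.assign(
        ddct=d["delta_ct"].to_numpy() - ref_dct.loc[d["gene"]].to_numpy(),
    )
    d["fold"] = efficiency ** (-d["ddct"])

    if se_across == "measurements":
        # per-technical-measurement folds against the same mean references
        per_meas = delta_ct(
            records.rename(columns={"tech_rep": "_tech"})
            .assign(bio_rep=lambda x: list(zip(x["bio_rep"], x["_tech"])))
            .groupby(["gene"] + _SAMPLE_KEY, as_index=False)["ct"]
            .mean(),
            refspec.housekeeping_gene,
        )
        per_meas["fold"] = efficiency ** (
            -(per_meas["delta_ct"].to_numpy() - ref_dct.loc[per_meas["gene"]].to_numpy())
        )
        spread_source = per_meas
    else:
        spread_source = d

    def _summarise(group: pd.DataFrame) -> pd.Series:
        # subtract the reference mean from the group mean (not per replicate)
        # so the reference cell comes out exactly 1
        gene = group.name[0]
        mean_ddct = group["delta_ct"].mean() - ref_dct.loc[gene]
        return pd.Series(
            {
                "mean_fold": float(efficiency**-mean_ddct),
                "n_bio": int(group["bio_rep"].nunique()),
            }
        )

    summary = (
        d.groupby(["gene", "condition", "timepoint_h"])
        .apply(_summarise, include_groups=False)
        .reset_index()
    )
    spread = (
        spread_source.groupby(["gene", "condition", "timepoint_h"])["fold"]
        .agg(se_fold=lambda x: float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0,
             n_total="size")
        .reset_index()
    )
    out = summary.merge(spread, on=["gene", "condition", "timepoint_h"])
    out["n_bio"] = out["n_bio"].astype(int)
    out["n_total"] = out["n_total"].astype(int)
    return out
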