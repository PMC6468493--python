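"""Double-normalized delta-delta-Ct quantitation of DNA cleavage.

Cutting destroys template across an amplicon, so qPCR on non-restricted
genomic DNA reports cleavage as a Ct increase.  Target Ct values are
first normalized to housekeeping amplicons within each condition
(delta-Ct), then to the untreated condition (delta-delta-Ct); fold
change = 2**(-ddCt) with untreated set to 1, and the percentage of
broken templates is (1 - fold) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DsbEstimate",
    "validate_ct_table",
    "delta_ct",
    "fold_change",
    "percent_dsb",
    "quantify_dsb",
]

REQUIRED_COLUMNS = ["amplicon_id", "role", "condition", "replicate", "ct"]
BASELINE_CONDITION = "untreated"


@dataclass
class DsbEstimate:
    """%DSB at one amplicon under one condition."""

    amplicon_id: str
    condition: str
    housekeeping_id: str
    fold_change: float
    percent_dsb: float
    sem: float  # SEM of fold change across replicates


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy Ct-table contract; returns the table unchanged."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycles")
    hk = table[table["role"] == "housekeeping"]
    for cond in table["condition"].unique():
        if hk[hk["condition"] == cond].empty:
            raise ValueError(f"no housekeeping amplicon in condition {cond!r}")
    return table


def delta_ct(table: pd.DataFrame, housekeeping_id: str | None = None) -> pd.DataFrame:
    """Normalize Ct values to housekeeping amplicons within each condition.

    ``delta_ct = ct - mean(housekeeping ct in the same condition)``.  With
    ``housekeeping_id=None`` the mean over all housekeeping amplicons is
    used (equivalent to averaging the per-housekeeping delta-Ct values);
    pass an amplicon id to normalize against a single housekeeping gene.

    Returns a copy of the table with ``delta_ct`` and ``housekeeping_id``
    columns added.
    """
    validate_ct_table(table)
    hk = table[table["role"] == "housekeeping"]
    if housekeeping_id is not None:
        hk = hk[hk["amplicon_id"] == housekeeping_id]
        if hk.empty:
            raise ValueError(f"housekeeping amplicon {housekeeping_id!r} not in table")
        label = housekeeping_id
    else:
        label = "+".join(sorted(hk["amplicon_id"].unique()))
    # mean of per-amplicon condition means, so unbalanced replicate counts
    # across housekeeping genes do not skew the reference
    ref = (
        hk.groupby(["condition", "amplicon_id"])["ct"]
        .mean()
        .groupby("condition")
        .mean()
    )
    missing = set(table["condition"].unique()) - set(ref.index)
    if missing:
        raise ValueError(f"housekeeping missing in conditions: {sorted(missing)}")
    out = table.copy()
    out["delta_ct"] = out["ct"] - out["condition"].map(ref)
    out["housekeeping_id"] = label
    return out


def fold_change(
    normalized: pd.DataFrame,
    baseline_condition: str = BASELINE_CONDITION,
) -> pd.DataFrame:
    """Fold change 2**(-ddCt) per amplicon and condition, untreated = 1.

    ddCt is computed per replicate, pairing treated and untreated
    replicates by index when the replicate sets match; otherwise each
    treated replicate is compared to the mean untreated delta-Ct.
    Replicate fold changes are averaged; their SEM is reported.
    """
    if "delta_ct" not in normalized.columns:
        raise ValueError("run delta_ct first")
    if baseline_condition not in set(normalized["condition"]):
        raise ValueError(f"baseline condition {baseline_condition!r} not in table")
    rows = []
    for (amp, role), grp in normalized.groupby(["amplicon_id", "role"], sort=False):
        base = grp[grp["condition"] == baseline_condition].set_index("replicate")[
            "delta_ct"
        ]
        hk_label = grp["housekeeping_id"].iloc[0]
        for cond, cgrp in grp.groupby("condition", sort=False):
            cvals = cgrp.set_index("replicate")["delta_ct"]
            if set(cvals.index) == set(base.index):
                ddct = cvals - base  # paired by replicate index
            else:
                ddct = cvals - base.mean()
            folds = np.power(2.0, -ddct.to_numpy(dtype=float))
            n = len(folds)
            sem = float(np.std(folds, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {
                    "amplicon_id": amp,
                    "role": role,
                    "condition": cond,
                    "housekeeping_id": hk_label,
                    "fold_change": float(folds.mean()),
                    "sem": sem,
                    "n_replicates": n,
                }
            )
    return pd.DataFrame(rows)


def percent_dsb(folds: pd.DataFrame) -> list[DsbEstimate]:
    """Convert fold changes into % of broken templates: (1 - fold) * 100.

    Values can be negative (signal gain) and are reported unclamped.
    """
    out = []
    for row in folds.itertuples(index=False):
        out.append(
            DsbEstimate(
                amplicon_id=row.amplicon_id,
                condition=row.condition,
                housekeeping_id=row.housekeeping_id,
                fold_change=row.fold_change,
                percent_dsb=(1.0 - row.fold_change) * 100.0,
                sem=row.sem,
            )
        )
    return out


def quantify_dsb(
    table: pd.DataFrame,
    housekeeping_id: str | None = None,
    baseline_condition: str = BASELINE_CONDITION,
) -> pd.DataFrame:
    """Full pipeline: delta-Ct -> fold change -> %DSB, as a tidy table.

    Alongside the default (housekeeping-averaged) estimate, one column
    set per individual housekeeping gene is *not* emitted here; call
    :func:`delta_ct` with an explicit ``housekeeping_id`` for
    per-housekeeping transparency.
    """
    estimates = percent_dsb(fold_change(delta_ct(table, housekeeping_id), baseline_condition))
    return pd.DataFrame(
        [
            {
                "amplicon_id": e.amplicon_id,
                "condition": e.condition,
                "housekeeping_id": e.housekeeping_id,
                "fold_change": e.fold_change,
                "percent_dsb": e.percent_dsb,
                "sem": e.sem,
            }
            for e in estimates
        ]
    )
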