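"""Volume-change reference standard and the type-I endoleak exclusion.

A sac is labeled ``expansion`` when its relative volume change
(V2 - V1) / V1 strictly exceeds 2% between the two follow-up scans;
otherwise it is ``non_expansion`` (stable or shrunken).  Type-I endoleaks —
attachment-site leaks that are an established expansion predictor on their
own — are removed before texture analysis.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "EXPANSION_THRESHOLD",
    "classify_volume_change",
    "apply_reference_standard",
    "exclude_type1",
]

EXPANSION_THRESHOLD = 0.02


def classify_volume_change(v1: float, v2: float, threshold: float = EXPANSION_THRESHOLD) -> str:
    """Label one volume pair. Strict inequality: a change of exactly 2% is stable."""
    if v1 <= 0:
        raise ValueError(f"V1 must be positive, got {v1}")
    if v2 < 0:
        raise ValueError(f"V2 must be non-negative, got {v2}")
    return "expansion" if (v2 - v1) / v1 > threshold else "non_expansion"


def apply_reference_standard(
    cohort: pd.DataFrame, threshold: float = EXPANSION_THRESHOLD
) -> pd.DataFrame:
    """Add ``relative_change`` and ``label`` columns to a cohort manifest.

    The label is scale invariant: multiplying V1 and V2 by any positive
    constant leaves it unchanged.  Volumes are used exactly as stored, with
    no rounding before the comparison.
    """
    if (cohort["V1"] <= 0).any():
        bad = cohort.loc[cohort["V1"] <= 0, "id"].tolist()
        raise ValueError(f"non-positive V1 for patients {bad}")
    out = cohort.copy()
    out["relative_change"] = (out["V2"] - out["V1"]) / out["V1"]
    out["label"] = (out["relative_change"] > threshold).map(
        {True: "expansion", False: "non_expansion"}
    )
    return out


def exclude_type1(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove every type-I endoleak record; return the filtered cohort and a report.

    The report lists removed patient ids and per-label counts before/after.
    Idempotent: re-applying to the output is the identity.
    """
    is_type1 = cohort["endoleak"] == "type_I"
    removed = cohort.loc[is_type1, "id"].tolist()
    kept = cohort.loc[~is_type1].reset_index(drop=True)

    def _counts(df: pd.DataFrame) -> dict:
        if "label" in df.columns:
            return df["label"].value_counts().to_dict()
        return df["group"].value_counts().to_dict()

    report = {
        "removed_ids": removed,
        "n_removed": len(removed),
        "n_before": len(cohort),
        "n_after": len(kept),
        "counts_before": _counts(cohort),
        "counts_after": _counts(kept),
    }
    if kept.empty:
        warnings.warn("type-I exclusion removed every record", UserWarning, stacklevel=2)
    return kept, report
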