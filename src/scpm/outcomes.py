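"""Outcome vectors from per-run subjective ratings.

Ratings (9-point stress / arousal / focus scales, one per run) are averaged
into the same two-run epochs used for connectivity, expressed relative to the
baseline epoch, and summarized either over all image epochs ("mean" outcomes)
or the late epoch only ("late" outcomes).  The chronic-stress questionnaire
score (PSS) passes through unchanged — it has no within-session baseline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .connectivity import EpochSpec

logger = logging.getLogger(__name__)

SCALES = ("stress", "arousal", "focus")

OUTCOME_LABELS = ("mean_stress", "late_stress", "mean_arousal", "late_arousal",
                  "mean_focus", "late_focus", "pss")


def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "condition", "run", *SCALES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratings table missing columns {sorted(missing)}")
    for s in SCALES:
        v = table[s]
        if not ((v >= 1) & (v <= 9)).all() or not (v == v.round()).all():
            raise ValueError(f"{s} ratings must be integers in [1, 9]")
    return table


def epoch_rating_means(table: pd.DataFrame, spec: EpochSpec | None = None
                       ) -> pd.DataFrame:
    """Mean rating per participant/condition/epoch for each scale.

    Each epoch averages its two runs; if one run is missing the epoch mean
    uses the available run (logged).
    """
    spec = spec or EpochSpec()
    table = validate_ratings(table)
    run_to_epoch = {r: name for name, runs in spec.mapping.items() for r in runs}
    sub = table[table["run"].isin(run_to_epoch)].copy()
    sub["epoch"] = sub["run"].map(run_to_epoch)
    counts = sub.groupby(["participant", "condition", "epoch"])["run"].count()
    short = counts[counts < 2]
    for key in short.index:
        logger.warning("epoch mean from a single run for %s", key)
    out = sub.groupby(["participant", "condition", "epoch"])[list(SCALES)].mean()
    return out


def relative_outcome(epoch_means: pd.DataFrame, label: str,
                     reference: str = "S-B",
                     pss: pd.Series | None = None,
                     spec: EpochSpec | None = None) -> pd.Series:
    """Build one outcome vector matched to the connectivity inputs.

    ``label`` is ``{mean,late}_{stress,arousal,focus}`` or ``pss``.  Mean
    outcomes are mean(early, mid, late) - baseline; late outcomes are
    late - baseline.  With reference ``(S-B)-(N-B)`` the Neutral-condition
    analogue is subtracted, mirroring the relative feature construction.
    PSS is absolute and ignores the reference.
    """
    spec = spec or EpochSpec()
    if label == "pss":
        if pss is None:
            raise ValueError("pss scores not provided")
        return pss.astype(float).rename("pss")
    try:
        window, scale = label.split("_", 1)
    except ValueError:
        raise ValueError(f"unknown outcome label {label!r}") from None
    if window not in ("mean", "late") or scale not in SCALES:
        raise ValueError(f"unknown outcome label {label!r}")
    if reference not in ("S-B", "(S-B)-(N-B)"):
        raise ValueError(f"unknown reference {reference!r}")

    wide = epoch_means[scale].unstack("epoch")

    def rel(cond: str) -> pd.Series:
        sub = wide.xs(cond, level="condition")
        base = sub[spec.baseline_epoch]
        if window == "late":
            return sub[spec.image_epochs[-1]] - base
        return sub[spec.image_epochs].mean(axis=1) - base

    out = rel("Stressor")
    if reference == "(S-B)-(N-B)":
        out = out - rel("Neutral")
    return out.rename(label)


def align_outcome(features: pd.DataFrame, outcome: pd.Series) -> pd.Series:
    """Reindex an outcome to the feature rows; any mismatch is a hard error."""
    missing = set(features.index) - set(outcome.index)
    if missing:
        raise ValueError(f"outcome missing participants {sorted(missing)}")
    return outcome.reindex(features.index)
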