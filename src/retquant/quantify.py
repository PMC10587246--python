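"""Per-field fractional lesion frequency and surface area.

A lesion's count contribution is split across fields in proportion to the
share of its (spherical) area falling in each field's assignment region,
so per-field frequencies are generally non-integer while the per-type
total over the seven fields plus the outside mass recovers the raw lesion
count exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FieldLayout, InvalidGeometryError, field_overlap
from .lesions import LESION_TYPES, NON_REPORTABLE_TYPES, EyeRecord

log = logging.getLogger(__name__)

FIELD_INDICES = (1, 2, 3, 4, 5, 6, 7)


@dataclass
class LesionMetrics:
    """Per eye x field x lesion-type fractional frequency and area (mm^2).

    ``table`` has one row per (field, lesion_type) cell with columns
    ``frequency`` and ``area_mm2``; ``outside`` holds the per-type count
    mass and area falling outside the seven-field union; ``raw_counts``
    the per-type raw lesion counts.  PFD/PFE cells are computed like any
    other but flagged non-reportable for summary output.
    """

    eye_id: str
    table: pd.DataFrame
    outside: pd.DataFrame  # index lesion_type, columns frequency/area_mm2
    raw_counts: dict[str, int] = field(default_factory=dict)
    dropped_lesions: int = 0

    def total(self, lesion_type: str, metric: str = "frequency") -> float:
        sel = self.table[self.table["lesion_type"] == lesion_type]
        return float(sel[metric].sum())

    def cell(self, field_index: int, lesion_type: str, metric: str = "frequency") -> float:
        sel = self.table[
            (self.table["field"] == field_index) & (self.table["lesion_type"] == lesion_type)
        ]
        return float(sel[metric].sum())


def quantify_eye(
    eye: EyeRecord,
    layout: FieldLayout,
    on_invalid: str = "drop",
) -> LesionMetrics:
    """Compute per-field fractional frequency and area for one eye.

    ``on_invalid`` controls handling of self-intersecting lesion polygons:
    ``"drop"`` (default) skips the lesion with a warning, ``"raise"``
    propagates the error with eye/lesion identifiers.
    """
    if eye.excluded_reason is not None:
        raise ValueError(f"eye {eye.eye_id} is excluded ({eye.excluded_reason})")
    freq = {(f, t): 0.0 for f in FIELD_INDICES for t in LESION_TYPES}
    area = {(f, t): 0.0 for f in FIELD_INDICES for t in LESION_TYPES}
    out_freq = {t: 0.0 for t in LESION_TYPES}
    out_area = {t: 0.0 for t in LESION_TYPES}
    raw = {t: 0 for t in LESION_TYPES}
    dropped = 0
    for k, lesion in enumerate(eye.lesions):
        try:
            ov = field_overlap(lesion.polygon, layout)
        except InvalidGeometryError as e:
            if on_invalid == "raise":
                raise InvalidGeometryError(
                    f"eye {eye.eye_id}, lesion #{k} ({lesion.lesion_type}): {e}"
                ) from e
            warnings.warn(
                f"eye {eye.eye_id}: dropping invalid {lesion.lesion_type} lesion #{k}"
            )
            log.warning("eye %s: dropped invalid lesion #%d (%s)", eye.eye_id, k, lesion.lesion_type)
            dropped += 1
            continue
        t = lesion.lesion_type
        raw[t] += 1
        for i, fi in enumerate(FIELD_INDICES):
            freq[(fi, t)] += float(ov.per_field_fraction[i])
            area[(fi, t)] += float(ov.per_field_area[i])
        out_freq[t] += ov.outside_fraction
        out_area[t] += ov.outside_area
    rows = [
        {
            "eye_id": eye.eye_id,
            "field": f,
            "lesion_type": t,
            "frequency": freq[(f, t)],
            "area_mm2": area[(f, t)],
        }
        for f in FIELD_INDICES
        for t in LESION_TYPES
    ]
    table = pd.DataFrame(rows)
    outside = pd.DataFrame(
        {"frequency": out_freq, "area_mm2": out_area}
    ).rename_axis("lesion_type")
    return LesionMetrics(
        eye_id=eye.eye_id, table=table, outside=outside, raw_counts=raw, dropped_lesions=dropped
    )


def metrics_frame(metrics: list[LesionMetrics]) -> pd.DataFrame:
    """Stack per-eye tables into one long DataFrame."""
    return pd.concat([m.table for m in metrics], ignore_index=True)


def totals_frame(metrics: list[LesionMetrics]) -> pd.DataFrame:
    """Per-eye, per-type totals over the seven fields (frequency and area)."""
    long = metrics_frame(metrics)
    return (
        long.groupby(["eye_id", "lesion_type"], sort=False)[["frequency", "area_mm2"]]
        .sum()
        .reset_index()
    )


def summarize_by_severity(
    metrics: list[LesionMetrics],
    grades: list,
    scale: str = "icdr",
    include_nonreportable: bool = False,
) -> pd.DataFrame:
    """Mean/SD/median/n of per-eye totals, grouped by severity level.

    ``grades`` are per-eye severity grades carrying ``eye_id`` and the
    requested scale attribute (``icdr`` or ``aa_level``).  Fibrous
    proliferation rows (PFD/PFE) are omitted from the summary unless
    explicitly requested; severity levels with no eyes are absent rather
    than zero-filled.
    """
    if scale not in ("icdr", "aa"):
        raise ValueError("scale must be 'icdr' or 'aa'")
    attr = "icdr" if scale == "icdr" else "aa_level"
    level_by_eye = {g.eye_id: getattr(g, attr) for g in grades}
    missing = [m.eye_id for m in metrics if m.eye_id not in level_by_eye]
    if missing:
        raise ValueError(f"no {scale} grade for eyes: {missing[:5]}")
    tot = totals_frame(metrics)
    tot["level"] = tot["eye_id"].map(level_by_eye)
    if not include_nonreportable:
        tot = tot[~tot["lesion_type"].isin(NON_REPORTABLE_TYPES)]
    long = tot.melt(
        id_vars=["eye_id", "lesion_type", "level"],
        value_vars=["frequency", "area_mm2"],
        var_name="metric",
        value_name="value",
    )
    summary = (
        long.groupby(["level", "lesion_type", "metric"], sort=False)["value"]
        .agg(mean="mean", sd="std", median="median", n="count")
        .reset_index()
    )
    summary["sd"] = summary["sd"].fillna(0.0)  # singleton groups
    return summary


def apply_exclusions(
    cohort: list[EyeRecord], grades: list | None = None
) -> tuple[list[EyeRecord], dict[str, int]]:
    """Filter flagged eyes and return the exclusion accounting.

    Removes eyes flagged poor-quality, RVO, or interfering-pathology; when
    grades are supplied, eyes graded "cannot grade" (levels 81/85/90) are
    counted under ``interfering`` as well.  The accounting always satisfies
    ``assessed == retained + sum(excluded)``.
    """
    ungradable_ids = set()
    if grades is not None:
        ungradable_ids = {g.eye_id for g in grades if not getattr(g, "gradable", True)}
    counts = {"poor_quality": 0, "rvo": 0, "interfering": 0}
    included = []
    for eye in cohort:
        reason = eye.excluded_reason
        if reason is None and eye.eye_id in ungradable_ids:
            reason = "interfering"
        if reason is None:
            included.append(eye)
        else:
            counts[reason] += 1
    accounting = {
        "assessed": len(cohort),
        "excluded_poor_quality": counts["poor_quality"],
        "excluded_rvo": counts["rvo"],
        "excluded_interfering": counts["interfering"],
        "retained": len(included),
    }
    return included, accounting
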