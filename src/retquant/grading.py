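"""Rule engines for ICDR (0-4) and DRCR Protocol AA severity levels.

The engines formalize the two clinical scales as explicit, deterministic
rule tables over an eye's lesion configuration.  The thresholds involved
(the 4-2-1 hemorrhage count, what counts as "prominent" IRMA, the
field-extent tiers of the NPDR Protocol AA levels) are configuration
constants with documented defaults — a simplified, reproducible stand-in
for the standard-photograph comparisons human graders perform, not a
claim about any particular grader's internal criteria.

ICDR rule order: proliferative disease (NVE / NVD / preretinal or
vitreous hemorrhage) scores 4; otherwise the 4-2-1 rule (more than 20
hemorrhages in each of the four fovea-centered quadrants, venous beading
in at least two, or prominent IRMA in at least one) scores 3;
microaneurysms only score 1 (questionable-DR eyes are graded 1 as well);
any other lesion scores 2; a clean eye scores 0.

Protocol AA levels are reported within the band consistent with the ICDR
category (Table-style mapping): 10/12 for no DR, 14/15/20 for
questionable or MA-only disease, 35/43/47 NPDR tiers keyed to the number
of involved fields 2-7, 53/53E keyed to how many 4-2-1 criteria are met,
and 60-71/75 PDR tiers keyed to NVD/NVE extent and preretinal/vitreous
hemorrhage.  High-risk PDR (71/75) and cannot-grade (81/85/90) sublevels
are collapsed to single reported tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .geometry import QUADRANTS, FieldLayout, field_overlap, quadrant_of, spherical_area_mm2
from .lesions import EyeRecord, LESION_TYPES

#: Protocol AA levels grouped by the ICDR category they imply.
AA_BANDS: dict[int, tuple[str, ...]] = {
    0: ("10", "12"),
    1: ("14", "15", "20"),
    2: ("35", "43", "47"),
    3: ("53", "53E"),
    4: ("60", "61", "65", "71/75"),
}

CANNOT_GRADE_LEVELS: tuple[str, ...] = ("81", "85", "90")

_EXCLUSION_TO_AA = {"poor_quality": "90", "interfering": "85", "rvo": "81"}

#: Lesion classes that define "active NPDR involvement" of a field.
_ACTIVE_NPDR_TYPES = ("H", "HE", "CWS", "IRMA", "VB", "VL")


class UngradableEyeError(ValueError):
    """Severity was requested for an eye flagged as ungradable."""


@dataclass
class GradingThresholds:
    """Configurable rule constants.

    hemorrhages_per_quadrant: the 4-2-1 hemorrhage criterion fires when the
        (half-up rounded) in-grid hemorrhage count strictly exceeds this in
        every quadrant.
    vb_quadrants: minimum quadrants with venous beading for the 4-2-1 rule.
    prominent_irma_area_mm2: an IRMA lesion with at least this much in-grid
        area counts as "prominent".
    field_presence_frequency: a field 2-7 counts as involved when any active
        NPDR lesion class reaches this fractional frequency there.
    npdr_moderate_fields / npdr_modsevere_fields: involved-field counts at
        which the Protocol AA NPDR tier steps from 35 to 43 and 43 to 47.
    nve_moderate_area_mm2: NVE area separating mild (61) from moderate (65) PDR.
    """

    hemorrhages_per_quadrant: int = 20
    vb_quadrants: int = 2
    prominent_irma_area_mm2: float = 0.10
    field_presence_frequency: float = 0.5
    npdr_moderate_fields: int = 2
    npdr_modsevere_fields: int = 4
    nve_moderate_area_mm2: float = 0.5


DEFAULT_THRESHOLDS = GradingThresholds()


@dataclass
class QuadrantSummary:
    """Per-quadrant lesion tallies within the seven-field union.

    Counts are in-grid fractional masses (a lesion contributes the share
    of its area inside the union) accumulated by lesion centroid quadrant
    and rounded half-up to whole lesions.
    """

    hemorrhage_count: dict[str, int] = field(default_factory=dict)
    ma_count: dict[str, int] = field(default_factory=dict)
    vb_present: dict[str, bool] = field(default_factory=dict)
    prominent_irma: dict[str, bool] = field(default_factory=dict)


@dataclass
class SeverityGrade:
    """Paired ICDR score and Protocol AA level with the fired-rule trace."""

    eye_id: str
    icdr: int | None
    aa_level: str
    gradable: bool
    rule_trace: list[str] = field(default_factory=list)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def quadrant_summary(
    eye: EyeRecord,
    layout: FieldLayout,
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
) -> QuadrantSummary:
    """Tally the 4-2-1 rule inputs by fovea-centered quadrant."""
    h_mass = {q: 0.0 for q in QUADRANTS}
    ma_mass = {q: 0.0 for q in QUADRANTS}
    vb = {q: False for q in QUADRANTS}
    irma = {q: False for q in QUADRANTS}
    union = layout.union
    prepared = layout.union_prepared
    for lesion in eye.lesions:
        t = lesion.lesion_type
        if t not in ("H", "MA", "VB", "IRMA"):
            continue
        poly = lesion.polygon
        if poly.is_empty or poly.area == 0.0:
            continue
        q = quadrant_of((poly.centroid.x, poly.centroid.y), layout)
        if prepared.disjoint(poly):
            continue
        if prepared.contains_properly(poly):
            frac, in_geom = 1.0, poly
        else:
            in_geom = poly.intersection(union)
            frac = in_geom.area / poly.area
        if t == "H":
            h_mass[q] += frac
        elif t == "MA":
            ma_mass[q] += frac
        elif t == "VB":
            if frac > 0:
                vb[q] = True
        elif t == "IRMA":
            if spherical_area_mm2(in_geom, layout.mm_per_degree) >= thresholds.prominent_irma_area_mm2:
                irma[q] = True
    return QuadrantSummary(
        hemorrhage_count={q: _round_half_up(h_mass[q]) for q in QUADRANTS},
        ma_count={q: _round_half_up(ma_mass[q]) for q in QUADRANTS},
        vb_present=vb,
        prominent_irma=irma,
    )


def _four_two_one(quads: QuadrantSummary, thresholds: GradingThresholds) -> list[str]:
    """Names of the 4-2-1 criteria satisfied by the quadrant tallies."""
    met = []
    if all(c > thresholds.hemorrhages_per_quadrant for c in quads.hemorrhage_count.values()):
        met.append("hemorrhages>20-in-4-quadrants")
    if sum(quads.vb_present.values()) >= thresholds.vb_quadrants:
        met.append("venous-beading-in-2-quadrants")
    if any(quads.prominent_irma.values()):
        met.append("prominent-irma")
    return met


def grade_icdr(
    eye: EyeRecord,
    quads: QuadrantSummary,
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[int, list[str]]:
    """ICDR score 0-4 for a gradable eye, with the fired-rule trace."""
    if eye.excluded_reason is not None:
        raise UngradableEyeError(f"eye {eye.eye_id} is ungradable ({eye.excluded_reason})")
    counts = {t: eye.count_of(t) for t in LESION_TYPES}
    if counts["NVE"] or counts["NVD"] or counts["PRH/VH"]:
        present = [t for t in ("NVE", "NVD", "PRH/VH") if counts[t]]
        return 4, [f"proliferative:{'+'.join(present)}"]
    met = _four_two_one(quads, thresholds)
    if met:
        return 3, [f"4-2-1:{c}" for c in met]
    non_ma = sum(v for t, v in counts.items() if t != "MA")
    if counts["MA"] and non_ma == 0:
        return 1, ["mild:microaneurysms-only"]
    if eye.questionable_dr:
        return 1, ["mild:questionable-dr"]
    if non_ma or counts["MA"]:
        return 2, ["moderate:lesions-beyond-ma"]
    return 0, ["no-dr:no-lesions"]


def _involved_fields(eye: EyeRecord, layout: FieldLayout, thresholds: GradingThresholds) -> int:
    """Number of fields 2-7 with active NPDR lesion presence."""
    per_field = {i: 0.0 for i in range(1, 8)}
    involved = set()
    for lesion in eye.lesions:
        if lesion.lesion_type not in _ACTIVE_NPDR_TYPES:
            continue
        ov = field_overlap(lesion.polygon, layout)
        for i in range(7):
            per_field[i + 1] += float(ov.per_field_fraction[i])
    for i in range(2, 8):
        if per_field[i] >= thresholds.field_presence_frequency:
            involved.add(i)
    return len(involved)


def grade_protocol_aa(
    eye: EyeRecord,
    layout: FieldLayout,
    quads: QuadrantSummary,
    icdr: int,
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[str, list[str]]:
    """Protocol AA level within the band implied by the ICDR category."""
    counts = {t: eye.count_of(t) for t in LESION_TYPES}
    if icdr == 0:
        if eye.non_dr_abnormality:
            return "12", ["aa:non-dr-abnormality"]
        return "10", ["aa:dr-absent"]
    if icdr == 1:
        if eye.questionable_dr and not counts["MA"]:
            return "14", ["aa:questionable"]
        return "20", ["aa:ma-only"]
    if icdr == 2:
        n = _involved_fields(eye, layout, thresholds)
        if n >= thresholds.npdr_modsevere_fields:
            return "47", [f"aa:npdr-fields={n}"]
        if n >= thresholds.npdr_moderate_fields:
            return "43", [f"aa:npdr-fields={n}"]
        return "35", [f"aa:npdr-fields={n}"]
    if icdr == 3:
        met = _four_two_one(quads, thresholds)
        if len(met) >= 2:
            return "53E", [f"aa:4-2-1-criteria={len(met)}"]
        return "53", [f"aa:4-2-1-criteria={len(met)}"]
    # proliferative band
    if counts["NVD"] or (counts["NVE"] and counts["PRH/VH"]):
        return "71/75", ["aa:high-risk-pdr"]
    if counts["PRH/VH"]:
        return "65", ["aa:prh-vh"]
    if counts["NVE"]:
        nve_area = sum(
            spherical_area_mm2(l.polygon, layout.mm_per_degree) for l in eye.lesions_of("NVE")
        )
        if nve_area >= thresholds.nve_moderate_area_mm2:
            return "65", [f"aa:nve-area={nve_area:.2f}"]
        return "61", [f"aa:nve-area={nve_area:.2f}"]
    return "60", ["aa:inactive-pdr"]


def grade_eye(
    eye: EyeRecord,
    layout: FieldLayout,
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
) -> SeverityGrade:
    """Full severity grade (ICDR + Protocol AA) for one eye."""
    if eye.excluded_reason is not None:
        return SeverityGrade(
            eye_id=eye.eye_id,
            icdr=None,
            aa_level=_EXCLUSION_TO_AA[eye.excluded_reason],
            gradable=False,
            rule_trace=[f"cannot-grade:{eye.excluded_reason}"],
        )
    quads = quadrant_summary(eye, layout, thresholds)
    icdr, trace = grade_icdr(eye, quads, thresholds)
    aa, aa_trace = grade_protocol_aa(eye, layout, quads, icdr, thresholds)
    return SeverityGrade(
        eye_id=eye.eye_id, icdr=icdr, aa_level=aa, gradable=True, rule_trace=trace + aa_trace
    )


@dataclass
class Concordance:
    """Contingency table between two graders plus the aligned label lists."""

    table: pd.DataFrame
    labels_a: list
    labels_b: list


def concordance(grades_a: list[SeverityGrade], grades_b: list[SeverityGrade], scale: str = "icdr") -> Concordance:
    """k x k contingency table over severity levels for two grade sets.

    Eyes are matched by ``eye_id``; mismatched eye sets are an error.  The
    aligned label lists are the input for Cohen's kappa.
    """
    attr = "icdr" if scale == "icdr" else "aa_level"
    by_a = {g.eye_id: getattr(g, attr) for g in grades_a}
    by_b = {g.eye_id: getattr(g, attr) for g in grades_b}
    if set(by_a) != set(by_b):
        raise ValueError("grade sets cover different eyes")
    ids = sorted(by_a)
    la = [by_a[i] for i in ids]
    lb = [by_b[i] for i in ids]
    levels = sorted(set(la) | set(lb), key=str)
    table = pd.crosstab(
        pd.Categorical(la, categories=levels),
        pd.Categorical(lb, categories=levels),
        dropna=False,
    )
    return Concordance(table=table, labels_a=la, labels_b=lb)
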