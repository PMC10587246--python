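"""Synthetic lesion-annotation cohorts for end-to-end testing.

Real ultra-widefield images behind clinical DR cohorts are not publicly
available, so this module generates per-eye lesion annotations whose
statistical behavior emulates such a cohort: per-severity lesion counts
are drawn negative-binomially (overdispersed, falling back to Poisson
when a configured cell is at or below Poisson dispersion), per-lesion
areas log-normally, and lesion centers follow an isotropic density that
decays exponentially with angular distance from the fovea (microaneurysms
and companions are more numerous centrally).  Default count/area
parameters per (ICDR level, lesion class) encode per-severity summary
distributions from a large multicenter clinical cohort.

Each eye is generated for a designed ICDR level; after sampling, an
optional constraint-repair pass adds, moves or resizes the minimum number
of lesions needed so the rule engine provably returns the designed grade
(e.g. a designed-severe eye satisfies the 4-2-1 rule, a designed-mild eye
carries microaneurysms only).  Repair guarantees usable truth labels for
grading-recovery tests but intentionally distorts the sampled count
distributions for grade-defining classes; distributional calibration is a
property of the pure sampling stage (``repair=False``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely import affinity
from shapely.geometry import Point, Polygon

from .geometry import (
    DEG,
    DEFAULT_FIELD_RADIUS_DEG,
    DEFAULT_MM_PER_DEGREE,
    QUADRANTS,
    FieldLayout,
    build_field_layout,
    quadrant_of,
)
from .grading import DEFAULT_THRESHOLDS, GradingThresholds, grade_icdr, quadrant_summary
from .lesions import LESION_TYPES, PROLIFERATIVE_TYPES, EyeRecord, LesionAnnotation

ICDR_LEVELS = (0, 1, 2, 3, 4)


class InvalidDispersionError(ValueError):
    """A count profile cannot be represented by a negative binomial."""


@dataclass(frozen=True)
class SeverityProfile:
    """Count/area sampling parameters for one (severity, lesion type) cell.

    ``mean_count``/``sd_count`` describe the lesion count within the
    seven-field grid; ``mean_area_per_lesion``/``sd_area_per_lesion`` the
    per-lesion spherical surface area in mm^2.
    """

    lesion_type: str
    mean_count: float
    sd_count: float
    mean_area_per_lesion: float
    sd_area_per_lesion: float

    def __post_init__(self) -> None:
        if min(self.mean_count, self.sd_count, self.mean_area_per_lesion) < 0:
            raise ValueError("profile parameters must be nonnegative")


# Default calibration: per-(ICDR level, class) count mean/SD and per-eye
# TOTAL area mean/SD (mm^2) within the seven-field grid; per-lesion area
# parameters are derived as total/count.  Level 0 ("no DR") is lesion-free
# by definition and every unlisted cell is zero.
_CALIBRATION: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "VL": {2: (0.01, 0.09, 0.01, 0.02), 3: (0.04, 0.25, 0.01, 0.05), 4: (0.19, 0.66, 0.03, 0.15)},
    "H": {2: (26.47, 27.57, 1.43, 1.64), 3: (78.67, 65.23, 5.45, 5.15), 4: (40.96, 40.97, 3.11, 5.75)},
    "MA": {
        1: (6.33, 6.51, 0.06, 0.06),
        2: (20.12, 21.90, 0.17, 0.22),
        3: (40.86, 36.30, 0.36, 0.42),
        4: (27.52, 26.76, 0.22, 0.27),
    },
    "HE": {2: (39.55, 87.89, 1.79, 6.03), 3: (65.80, 91.01, 1.79, 2.83), 4: (48.64, 99.46, 1.94, 5.28)},
    "CWS": {2: (2.21, 4.72, 0.59, 1.30), 3: (3.74, 6.21, 0.84, 1.43), 4: (1.23, 3.51, 0.85, 8.62)},
    "IRMA": {3: (0.82, 1.42, 0.19, 0.61), 4: (0.63, 1.51, 0.23, 1.17)},
    "PRH/VH": {4: (0.34, 1.40, 1.79, 6.95)},
    "NVE": {4: (1.79, 6.95, 3.28, 11.33)},
    "VB": {3: (0.29, 0.66, 0.19, 0.56), 4: (0.23, 0.72, 0.15, 0.55)},
    "NVD": {4: (0.35, 0.75, 6.05, 25.73)},
}


def default_profiles() -> dict[tuple[int, str], SeverityProfile]:
    """A profile for every (ICDR level, lesion type) pair."""
    profiles: dict[tuple[int, str], SeverityProfile] = {}
    for level in ICDR_LEVELS:
        for t in LESION_TYPES:
            cm, cs, am, asd = _CALIBRATION.get(t, {}).get(level, (0.0, 0.0, 0.0, 0.0))
            if cm > 0:
                per_mean = am / cm
                per_sd = asd / cm
            else:
                per_mean = per_sd = 0.0
            profiles[(level, t)] = SeverityProfile(
                lesion_type=t,
                mean_count=cm,
                sd_count=cs,
                mean_area_per_lesion=per_mean,
                sd_area_per_lesion=per_sd,
            )
    return profiles


@dataclass
class CohortConfig:
    """Generator configuration.

    spatial_concentration (1/deg) sets the exponential decay of lesion
    density with eccentricity; grader_error_rate is the probability that
    the simulated second grader's ICDR label is perturbed by one level;
    peripheral_fraction adds, per in-grid lesion, that expected fraction
    of extra lesions outside the seven-field union (present in the eye but
    not counted by the grid-restricted metrics); ``repair`` toggles the
    constraint-repair pass that guarantees the designed grade.
    """

    eyes_per_level: tuple[int, int, int, int, int] = (10, 10, 10, 10, 10)
    profiles: dict[tuple[int, str], SeverityProfile] = field(default_factory=default_profiles)
    spatial_concentration: float = 0.08
    seed: int = 0
    grader_error_rate: float = 0.05
    peripheral_fraction: float = 0.25
    repair: bool = True
    count_model: str = "auto"  # "auto": NB with Poisson fallback; "nbinom": strict
    field_radius_deg: float = DEFAULT_FIELD_RADIUS_DEG
    mm_per_degree: float = DEFAULT_MM_PER_DEGREE
    thresholds: GradingThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)

    def __post_init__(self) -> None:
        if len(self.eyes_per_level) != 5 or any(n < 0 for n in self.eyes_per_level):
            raise ValueError("eyes_per_level must be five nonnegative counts")
        if not 0.0 <= self.grader_error_rate <= 1.0:
            raise ValueError("grader_error_rate must be in [0, 1]")
        if self.spatial_concentration < 0:
            raise ValueError("spatial_concentration must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Designed severity labels for one synthetic eye."""

    eye_id: str
    designed_icdr: int
    designed_aa_level: str
    grader2_icdr: int


#: Protocol AA truth levels realizable for each designed ICDR level.
_AA_TRUTH_CHOICES: dict[int, tuple[str, ...]] = {
    0: ("10",),
    1: ("20",),
    2: ("35", "43", "47"),
    3: ("53", "53E"),
    4: ("61", "65", "71/75"),
}


# ---------------------------------------------------------------------------
# sampling primitives


def nbinom_params(mean: float, sd: float) -> tuple[float, float]:
    """(n, p) for numpy's negative binomial; raises if var <= mean."""
    var = sd * sd
    if var <= mean:
        raise InvalidDispersionError(
            f"negative binomial needs variance > mean (got mean={mean}, sd={sd})"
        )
    return mean * mean / (var - mean), mean / var


def sample_count(mean: float, sd: float, rng: np.random.Generator, count_model: str = "auto") -> int:
    """Draw a lesion count with the configured mean/SD.

    Overdispersed cells (var > mean) use the negative binomial; cells at
    or below Poisson dispersion fall back to Poisson in "auto" mode and
    raise :class:`InvalidDispersionError` in "nbinom" mode.
    """
    if mean <= 0:
        return 0
    var = sd * sd
    if var <= mean:
        if count_model == "nbinom":
            nbinom_params(mean, sd)  # raises
        return int(rng.poisson(mean))
    n, p = nbinom_params(mean, sd)
    return int(rng.negative_binomial(n, p))


def _sample_area(profile: SeverityProfile, rng: np.random.Generator) -> float:
    m, s = profile.mean_area_per_lesion, profile.sd_area_per_lesion
    if m <= 0:
        return 0.01  # nominal dot lesion
    if s <= 0:
        return m
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


_POLY_VERTICES = 16
_NGON_AREA_FACTOR = _POLY_VERTICES * math.sin(2 * math.pi / _POLY_VERTICES) / (2 * math.pi)
#: Pure sanity bound on a single lesion's chart extent (keeps even extreme
#: log-normal tail draws inside the imaging field); essentially never hit.
_MAX_SEMI_AXIS_DEG = 60.0
#: Lesions up to this nominal chart radius are required to sit wholly
#: inside the seven-field union when drawn as in-grid; larger ones (rare
#: proliferative membranes) only anchor their center in the grid and may
#: straddle its edge, as such lesions do on real images.
_WHOLLY_INSIDE_RADIUS_DEG = 8.0


def _ellipse_polygon(
    center: np.ndarray, area_mm2: float, rng: np.random.Generator, mm_per_degree: float
) -> Polygon:
    """A 16-gon ellipse of the requested spherical area at ``center`` (deg)."""
    eps = float(np.hypot(*center)) * DEG
    sinc = math.sin(eps) / eps if eps > 1e-9 else 1.0
    chart_area = area_mm2 / (mm_per_degree**2 * sinc)
    aspect = rng.uniform(0.55, 1.0)
    ab = chart_area / (math.pi * _NGON_AREA_FACTOR)
    a = math.sqrt(ab / aspect)
    b = aspect * a
    if a > _MAX_SEMI_AXIS_DEG:
        scale = _MAX_SEMI_AXIS_DEG / a
        a *= scale
        b *= scale
    theta = rng.uniform(0, 2 * math.pi)
    phi = np.linspace(0, 2 * math.pi, _POLY_VERTICES, endpoint=False)
    x = a * np.cos(phi)
    y = b * np.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    pts = np.column_stack([center[0] + ct * x - st * y, center[1] + st * x + ct * y])
    return Polygon(pts)


def _sample_center(rng: np.random.Generator, concentration: float, r_max: float = 90.0) -> np.ndarray:
    """Lesion center with density ~ exp(-concentration * eccentricity)."""
    while True:
        if concentration > 0:
            r = float(rng.gamma(2.0, 1.0 / concentration))
        else:
            r = r_max * math.sqrt(rng.random())
        if r <= r_max:
            break
    az = rng.uniform(0, 2 * math.pi)
    return np.array([r * math.cos(az), r * math.sin(az)])


def _place_lesion(
    lesion_type: str,
    area_mm2: float,
    layout: FieldLayout,
    rng: np.random.Generator,
    concentration: float,
    inside_union: bool,
) -> Polygon | None:
    """Sample a placement for a lesion of the given (exact) spherical area.

    Small in-grid lesions are placed wholly inside the seven-field union;
    large ones need only their center in the grid.  Peripheral lesions are
    the complement (small: disjoint from the union; large: center outside).
    """
    prepared = layout.union_prepared
    nominal_r = math.sqrt(area_mm2 / math.pi) / layout.mm_per_degree
    big = nominal_r > _WHOLLY_INSIDE_RADIUS_DEG
    r_max = 40.0 if big else 90.0
    for _ in range(80):
        center = _sample_center(rng, concentration, r_max=r_max)
        poly = _ellipse_polygon(center, area_mm2, rng, layout.mm_per_degree)
        center_pt = Point(center[0], center[1])
        if inside_union:
            if (big and prepared.contains(center_pt)) or (
                not big and prepared.contains_properly(poly)
            ):
                return poly
        else:
            if (big and not prepared.contains(center_pt)) or (
                not big and prepared.disjoint(poly)
            ):
                return poly
    if inside_union and not big:
        # fall back to a central placement that always fits
        center = _sample_center(rng, 1.0, r_max=4.0)
        poly = _ellipse_polygon(center, area_mm2, rng, layout.mm_per_degree)
        if layout.union_prepared.contains_properly(poly):
            return poly
    return None


# ---------------------------------------------------------------------------
# eye generation


def generate_eye(
    level: int,
    config: CohortConfig,
    rng: np.random.Generator,
    eye_id: str = "eye_00000",
) -> EyeRecord:
    """Generate one synthetic eye for the designed ICDR ``level``."""
    if level not in ICDR_LEVELS:
        raise ValueError(f"unknown ICDR level {level!r}")
    for t in LESION_TYPES:
        if (level, t) not in config.profiles:
            raise ValueError(f"no profile for level {level}, lesion type {t}")

    laterality = "OD" if rng.random() < 0.5 else "OS"
    sign = -1.0 if laterality == "OD" else 1.0
    disc = (sign * 15.5 + rng.normal(0, 0.5), 1.5 + rng.normal(0, 0.5))
    layout = build_field_layout(
        disc, (0.0, 0.0), laterality,
        field_radius_deg=config.field_radius_deg,
        mm_per_degree=config.mm_per_degree,
    )

    lesions: list[LesionAnnotation] = []
    for t in LESION_TYPES:
        profile = config.profiles[(level, t)]
        n = sample_count(profile.mean_count, profile.sd_count, rng, config.count_model)
        for _ in range(n):
            poly = _place_lesion(
                t, _sample_area(profile, rng), layout, rng, config.spatial_concentration, True
            )
            if poly is not None:
                lesions.append(LesionAnnotation(t, poly))
        if n and config.peripheral_fraction > 0:
            for _ in range(int(rng.poisson(config.peripheral_fraction * n))):
                poly = _place_lesion(
                    t, _sample_area(profile, rng), layout, rng, config.spatial_concentration, False
                )
                if poly is not None:
                    lesions.append(LesionAnnotation(t, poly))

    eye = EyeRecord(
        eye_id=eye_id, laterality=laterality, disc_center=disc, lesions=lesions
    )
    if config.repair:
        _repair_to_designed_grade(eye, layout, level, config, rng)
    return eye


def generate_cohort(config: CohortConfig) -> tuple[list[EyeRecord], list[TruthRecord]]:
    """Generate the full cohort plus its designed-truth records.

    Identical configuration (including seed) yields a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    eyes: list[EyeRecord] = []
    truths: list[TruthRecord] = []
    for level, n_eyes in zip(ICDR_LEVELS, config.eyes_per_level):
        for _ in range(n_eyes):
            eye_id = f"eye_{len(eyes):05d}"
            eye = generate_eye(level, config, rng, eye_id=eye_id)
            aa = str(rng.choice(_AA_TRUTH_CHOICES[level]))
            grader2 = level
            if rng.random() < config.grader_error_rate:
                delta = int(rng.choice([-1, 1]))
                if not 0 <= level + delta <= 4:
                    delta = -delta
                grader2 = level + delta
            eyes.append(eye)
            truths.append(
                TruthRecord(
                    eye_id=eye_id,
                    designed_icdr=level,
                    designed_aa_level=aa,
                    grader2_icdr=grader2,
                )
            )
    return eyes, truths


def inject_exclusions(
    cohort: list[EyeRecord],
    n_poor_quality: int,
    n_rvo: int,
    n_interfering: int,
    rng: np.random.Generator,
) -> list[EyeRecord]:
    """Flag randomly chosen eyes with the stated exclusion reasons."""
    total = n_poor_quality + n_rvo + n_interfering
    if total > len(cohort):
        raise ValueError("exclusion counts exceed cohort size")
    chosen = rng.choice(len(cohort), size=total, replace=False)
    reasons = (
        ["poor_quality"] * n_poor_quality + ["rvo"] * n_rvo + ["interfering"] * n_interfering
    )
    for idx, reason in zip(chosen, reasons):
        cohort[int(idx)].excluded_reason = reason
    return cohort


# ---------------------------------------------------------------------------
# constraint repair


def _quadrant_anchor(layout: FieldLayout, quadrant: str, rng: np.random.Generator) -> np.ndarray:
    """A point ~8 deg from the fovea in the requested quadrant (inside F2)."""
    t_hat, v_hat = layout.axes
    s = 1.0 if "temporal" in quadrant else -1.0
    h = 1.0 if quadrant.startswith("super") else -1.0
    base = (8.0 / math.sqrt(2.0)) * (s * t_hat + h * v_hat)
    return np.asarray(layout.fovea_center) + base + rng.normal(0, 0.8, 2)


def _relocate(
    lesion: LesionAnnotation, layout: FieldLayout, quadrant: str, rng: np.random.Generator
) -> None:
    """Move a lesion so its centroid sits at an in-grid quadrant anchor."""
    for _ in range(20):
        target = _quadrant_anchor(layout, quadrant, rng)
        c = lesion.polygon.centroid
        moved = affinity.translate(lesion.polygon, xoff=target[0] - c.x, yoff=target[1] - c.y)
        if layout.union_prepared.contains_properly(moved) and quadrant_of(
            (moved.centroid.x, moved.centroid.y), layout
        ) == quadrant:
            lesion.polygon = moved
            return
    # shrink stubborn lesions until they fit near the fovea-side anchor
    lesion.polygon = affinity.scale(lesion.polygon, 0.25, 0.25)
    _relocate(lesion, layout, quadrant, rng)


def _add_lesion(
    eye: EyeRecord,
    layout: FieldLayout,
    lesion_type: str,
    area_mm2: float,
    quadrant: str,
    rng: np.random.Generator,
) -> None:
    center = _quadrant_anchor(layout, quadrant, rng)
    poly = _ellipse_polygon(center, area_mm2, rng, layout.mm_per_degree)
    lesion = LesionAnnotation(lesion_type, poly)
    if not layout.union_prepared.contains_properly(poly):
        _relocate(lesion, layout, quadrant, rng)
    eye.lesions.append(lesion)


def _in_union_lesions(eye: EyeRecord, layout: FieldLayout, lesion_type: str) -> list[LesionAnnotation]:
    return [
        l
        for l in eye.lesions_of(lesion_type)
        if layout.union_prepared.contains_properly(l.polygon)
    ]


def _balance_hemorrhages(
    eye: EyeRecord, layout: FieldLayout, per_quadrant: int, rng: np.random.Generator
) -> None:
    """Relocate/add hemorrhages until every quadrant holds > per_quadrant."""
    need = per_quadrant + 1
    by_q: dict[str, list[LesionAnnotation]] = {q: [] for q in QUADRANTS}
    for l in _in_union_lesions(eye, layout, "H"):
        c = l.polygon.centroid
        by_q[quadrant_of((c.x, c.y), layout)].append(l)
    deficits = {q: need - len(by_q[q]) for q in QUADRANTS}
    for q in QUADRANTS:
        while deficits[q] > 0:
            donor = max(QUADRANTS, key=lambda d: len(by_q[d]) - need)
            if len(by_q[donor]) > need:
                lesion = by_q[donor].pop()
                _relocate(lesion, layout, q, rng)
            else:
                _add_lesion(eye, layout, "H", 0.05, q, rng)
                lesion = eye.lesions[-1]
            by_q[q].append(lesion)
            deficits[q] -= 1


def _cap_hemorrhage_quadrant(
    eye: EyeRecord, layout: FieldLayout, per_quadrant: int, rng: np.random.Generator
) -> None:
    """Demote the 4-2-1 hemorrhage criterion: empty one quadrant to <= cap."""
    by_q: dict[str, list[LesionAnnotation]] = {q: [] for q in QUADRANTS}
    for l in _in_union_lesions(eye, layout, "H"):
        c = l.polygon.centroid
        by_q[quadrant_of((c.x, c.y), layout)].append(l)
    q_min = min(QUADRANTS, key=lambda q: len(by_q[q]))
    q_max = max(QUADRANTS, key=lambda q: len(by_q[q]))
    while len(by_q[q_min]) > per_quadrant:
        lesion = by_q[q_min].pop()
        _relocate(lesion, layout, q_max, rng)
        by_q[q_max].append(lesion)


def _repair_to_designed_grade(
    eye: EyeRecord,
    layout: FieldLayout,
    level: int,
    config: CohortConfig,
    rng: np.random.Generator,
) -> None:
    """Minimal add/move/resize edits until the ICDR engine fires the designed level."""
    thr = config.thresholds
    if level == 0:
        eye.lesions.clear()
        return
    if level == 1:
        eye.lesions = [l for l in eye.lesions if l.lesion_type == "MA"]
        if not eye.lesions:
            _add_lesion(eye, layout, "MA", 0.01, "superotemporal", rng)
        return
    if level in (2, 3):
        eye.lesions = [l for l in eye.lesions if l.lesion_type not in PROLIFERATIVE_TYPES]

    for _ in range(8):
        quads = quadrant_summary(eye, layout, thr)
        got, _trace = grade_icdr(eye, quads, thr)
        if got == level:
            return
        if level == 2:
            if got in (0, 1):
                _add_lesion(eye, layout, "H", 0.05, "superotemporal", rng)
            else:  # got == 3: some 4-2-1 criterion fired
                if all(
                    c > thr.hemorrhages_per_quadrant for c in quads.hemorrhage_count.values()
                ):
                    _cap_hemorrhage_quadrant(eye, layout, thr.hemorrhages_per_quadrant, rng)
                if sum(quads.vb_present.values()) >= thr.vb_quadrants:
                    vb = [l for l in eye.lesions if l.lesion_type == "VB"]
                    for l in vb[1:]:
                        eye.lesions.remove(l)
                if any(quads.prominent_irma.values()):
                    for l in eye.lesions_of("IRMA"):
                        l.polygon = affinity.scale(l.polygon, 0.2, 0.2)
        elif level == 3:
            n_h = len(_in_union_lesions(eye, layout, "H"))
            vb = _in_union_lesions(eye, layout, "VB")
            irma = _in_union_lesions(eye, layout, "IRMA")
            if n_h >= 4 * (thr.hemorrhages_per_quadrant + 1):
                _balance_hemorrhages(eye, layout, thr.hemorrhages_per_quadrant, rng)
            elif len(vb) >= thr.vb_quadrants:
                for l, q in zip(vb, QUADRANTS):
                    _relocate(l, layout, q, rng)
            elif irma:
                lesion = irma[0]
                target = 1.5 * thr.prominent_irma_area_mm2
                from .geometry import spherical_area_mm2

                area = spherical_area_mm2(lesion.polygon, layout.mm_per_degree)
                if area < target and area > 0:
                    f = math.sqrt(target / area)
                    lesion.polygon = affinity.scale(lesion.polygon, f, f)
                _relocate(lesion, layout, "superotemporal", rng)
            else:
                _add_lesion(
                    eye, layout, "IRMA", 2.0 * thr.prominent_irma_area_mm2, "superotemporal", rng
                )
        elif level == 4:
            _add_lesion(eye, layout, "NVE", 1.0, "superotemporal", rng)
    quads = quadrant_summary(eye, layout, thr)
    got, _trace = grade_icdr(eye, quads, thr)
    if got != level:
        raise RuntimeError(
            f"constraint repair failed for eye {eye.eye_id}: designed {level}, graded {got}"
        )
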