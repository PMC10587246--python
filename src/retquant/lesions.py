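"""Lesion vocabulary and per-eye annotation records.

Coordinates throughout are eye-centered angular coordinates in degrees of
visual angle: the fovea sits at the origin, the abscissa runs along the
disc–fovea axis (temporal positive for right eyes, mirrored for left eyes)
and the ordinate is superior-positive.  This chart is azimuthal-equidistant
about the fovea, i.e. the Euclidean distance from the origin equals the
angular eccentricity on the model eye sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from shapely.geometry import Polygon

#: The twelve annotated diabetic-retinopathy lesion classes.
LESION_TYPES: tuple[str, ...] = (
    "H",       # intraretinal hemorrhage
    "MA",      # microaneurysm
    "HE",      # hard exudate
    "CWS",     # cotton wool spot
    "IRMA",    # intraretinal microvascular abnormality
    "VL",      # venous loop
    "VB",      # venous beading (zone of involvement)
    "NVE",     # neovascularization elsewhere
    "NVD",     # neovascularization of the disc
    "PRH/VH",  # preretinal / vitreous hemorrhage
    "PFD",     # fibrous proliferation of the disc
    "PFE",     # fibrous proliferation elsewhere
)

#: Classes quantified internally but suppressed from summary reports:
#: fibrous proliferation does not enter severity grading and its frequency
#: and area are not reported.
NON_REPORTABLE_TYPES: tuple[str, ...] = ("PFD", "PFE")

#: Neovascular / proliferative-disease defining classes.
PROLIFERATIVE_TYPES: tuple[str, ...] = ("NVE", "NVD", "PRH/VH")

#: Exclusion reasons an eye can carry.
EXCLUSION_REASONS: tuple[str, ...] = ("poor_quality", "rvo", "interfering")


class UnknownLesionTypeError(ValueError):
    """A lesion annotation carries a type outside the 12-class vocabulary."""


@dataclass
class LesionAnnotation:
    """One typed lesion polygon in retinal angular coordinates (degrees)."""

    lesion_type: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise UnknownLesionTypeError(
                f"unknown lesion type {self.lesion_type!r}; "
                f"expected one of {', '.join(LESION_TYPES)}"
            )


@dataclass
class EyeRecord:
    """An eye's landmarks, flags and lesion annotations.

    ``disc_center`` / ``fovea_center`` are (longitude, latitude) in degrees;
    the fovea is conventionally at the origin.  ``excluded_reason`` is None
    for analyzable eyes, otherwise one of :data:`EXCLUSION_REASONS`.
    """

    eye_id: str
    laterality: str  # "OD" or "OS"
    disc_center: tuple[float, float]
    fovea_center: tuple[float, float] = (0.0, 0.0)
    lesions: list[LesionAnnotation] = field(default_factory=list)
    excluded_reason: Optional[str] = None
    questionable_dr: bool = False
    non_dr_abnormality: bool = False

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        if self.excluded_reason is not None and self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded_reason!r}")

    def lesions_of(self, lesion_type: str) -> list[LesionAnnotation]:
        return [l for l in self.lesions if l.lesion_type == lesion_type]

    def count_of(self, lesion_type: str) -> int:
        return sum(1 for l in self.lesions if l.lesion_type == lesion_type)
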