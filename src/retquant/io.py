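"""Readers and writers for annotations, landmarks, truth tables and config.

Annotation interchange is GeoJSON: one FeatureCollection per eye, each
lesion a Polygon feature with a ``lesion_type`` property.  Coordinates
are retinal angular degrees, not geographic; files carry an explicit
``"crs": "retinal-degrees"`` marker in their metadata to prevent any
geographic interpretation.  Landmarks travel in a JSON sidecar per eye;
designed-truth labels in a single CSV per cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import Polygon, shape

from .geometry import DEFAULT_FIELD_RADIUS_DEG, DEFAULT_MM_PER_DEGREE
from .grading import GradingThresholds
from .lesions import LESION_TYPES, EyeRecord, LesionAnnotation, UnknownLesionTypeError
from .simulate import TruthRecord

CRS_MARKER = "retinal-degrees"


def eye_to_geojson(eye: EyeRecord) -> dict:
    features = []
    for lesion in eye.lesions:
        features.append(
            {
                "type": "Feature",
                "properties": {"lesion_type": lesion.lesion_type},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[float(x), float(y)] for x, y in lesion.polygon.exterior.coords]
                    ],
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "metadata": {"crs": CRS_MARKER, "eye_id": eye.eye_id},
        "features": features,
    }


def landmarks_to_json(eye: EyeRecord) -> dict:
    return {
        "eye_id": eye.eye_id,
        "disc_center": [float(eye.disc_center[0]), float(eye.disc_center[1])],
        "fovea_center": [float(eye.fovea_center[0]), float(eye.fovea_center[1])],
        "laterality": eye.laterality,
        "excluded_reason": eye.excluded_reason,
        "questionable_dr": eye.questionable_dr,
        "non_dr_abnormality": eye.non_dr_abnormality,
    }


def write_eye(eye: EyeRecord, annotation_path: str | Path, landmarks_path: str | Path) -> None:
    Path(annotation_path).write_text(json.dumps(eye_to_geojson(eye), indent=1))
    Path(landmarks_path).write_text(json.dumps(landmarks_to_json(eye), indent=1))


def read_eye(annotation_path: str | Path, landmarks_path: str | Path) -> EyeRecord:
    """Load and validate one eye from its GeoJSON + landmarks pair."""
    try:
        gj = json.loads(Path(annotation_path).read_text())
        lm = json.loads(Path(landmarks_path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed JSON in {annotation_path} / {landmarks_path}: {e}") from e
    for key in ("disc_center", "fovea_center", "laterality"):
        if key not in lm:
            raise ValueError(f"landmarks file {landmarks_path} missing {key!r}")
    lesions = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties", {})
        ltype = props.get("lesion_type")
        if ltype not in LESION_TYPES:
            raise UnknownLesionTypeError(
                f"{annotation_path} feature #{k}: unknown lesion type {ltype!r}"
            )
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError(f"{annotation_path} feature #{k}: geometry must be a Polygon")
        lesions.append(LesionAnnotation(ltype, geom))
    return EyeRecord(
        eye_id=lm.get("eye_id", gj.get("metadata", {}).get("eye_id", Path(annotation_path).stem)),
        laterality=lm["laterality"],
        disc_center=tuple(lm["disc_center"]),
        fovea_center=tuple(lm["fovea_center"]),
        lesions=lesions,
        excluded_reason=lm.get("excluded_reason"),
        questionable_dr=bool(lm.get("questionable_dr", False)),
        non_dr_abnormality=bool(lm.get("non_dr_abnormality", False)),
    )


def write_cohort(
    eyes: list[EyeRecord], out_dir: str | Path, truths: list[TruthRecord] | None = None
) -> None:
    """One GeoJSON + landmarks pair per eye, plus an optional truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for eye in eyes:
        write_eye(eye, out / f"{eye.eye_id}.geojson", out / f"{eye.eye_id}.landmarks.json")
    if truths is not None:
        pd.DataFrame([asdict(t) for t in truths]).to_csv(out / "truth.csv", index=False)


def read_cohort(in_dir: str | Path) -> tuple[list[EyeRecord], list[TruthRecord] | None]:
    in_dir = Path(in_dir)
    eyes = []
    for ann in sorted(in_dir.glob("*.geojson")):
        lm = ann.with_name(ann.stem + ".landmarks.json")
        if not lm.exists():
            raise FileNotFoundError(f"no landmarks sidecar for {ann}")
        eyes.append(read_eye(ann, lm))
    truths = None
    truth_path = in_dir / "truth.csv"
    if truth_path.exists():
        df = pd.read_csv(truth_path, dtype={"designed_aa_level": str})
        truths = [
            TruthRecord(
                eye_id=r.eye_id,
                designed_icdr=int(r.designed_icdr),
                designed_aa_level=str(r.designed_aa_level),
                grader2_icdr=int(r.grader2_icdr),
            )
            for r in df.itertuples()
        ]
    return eyes, truths


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration (YAML-serializable).

    ``exclusions`` are (poor-quality, RVO, interfering-pathology) counts
    injected into a simulated cohort before filtering; ``input_dir`` reads
    an existing annotation directory instead of simulating.
    """

    seed: int = 0
    out_dir: str = "retquant_out"
    input_dir: str | None = None
    eyes_per_level: tuple[int, int, int, int, int] = (10, 10, 10, 10, 10)
    spatial_concentration: float = 0.08
    grader_error_rate: float = 0.05
    peripheral_fraction: float = 0.25
    repair: bool = True
    exclusions: tuple[int, int, int] = (0, 0, 0)
    mm_per_degree: float = DEFAULT_MM_PER_DEGREE
    field_radius_deg: float = DEFAULT_FIELD_RADIUS_DEG
    alpha: float = 0.05
    thresholds: GradingThresholds = field(default_factory=GradingThresholds)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mm_per_degree <= 0 or self.field_radius_deg <= 0:
            raise ValueError("geometry constants must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = GradingThresholds(**raw.pop("thresholds", {}))
        for key in ("eyes_per_level", "exclusions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["eyes_per_level"] = list(self.eyes_per_level)
        d["exclusions"] = list(self.exclusions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        import hashlib

        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
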