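"""Geometric scores for semicircular canals.

Eccentricity of a canal's elliptical outline, the radius of curvature used
for body-mass allometry, and the orthogonality-deviation score summarising
how far a vestibular system departs from mutually perpendicular canals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import CanalmorphError, MissingDataError
from .measurements_io import CANAL_IDS, CanalId, SpecimenRecord

VERTICAL_CANALS: tuple[CanalId, CanalId] = ("anterior", "posterior")


@dataclass(frozen=True)
class EccentricityResult:
    """Per-canal eccentricities and the vertical-canal mean of one specimen."""

    specimen_id: str
    per_canal: Mapping[CanalId, float]
    vertical_mean: float


@dataclass(frozen=True)
class RadiusResult:
    """Per-canal radii of curvature (mm) and their specimen-level mean."""

    specimen_id: str
    per_canal: Mapping[CanalId, float]
    mean_radius: float
    log10_mean_radius: float


def eccentricity(major_d: float, minor_d: float) -> float:
    """Eccentricity of an ellipse given its major and minor axis diameters.

    e = sqrt(1 - (minor/major)^2), 0 for a circle and approaching 1 as the
    outline degenerates into a line.
    """
    if major_d <= 0 or minor_d <= 0:
        raise CanalmorphError(
            f"diameters must be positive, got major={major_d}, minor={minor_d}"
        )
    if minor_d > major_d:
        raise CanalmorphError(
            f"minor diameter {minor_d} exceeds major diameter {major_d}; "
            "axes are mis-ordered"
        )
    return math.sqrt(1.0 - (minor_d / major_d) ** 2)


def canal_eccentricities(rec: SpecimenRecord) -> dict[CanalId, float]:
    """Eccentricity of every measured canal of the specimen."""
    return {
        cid: eccentricity(c.major_d, c.minor_d) for cid, c in rec.canals.items()
    }


def vertical_mean_eccentricity(rec: SpecimenRecord) -> float:
    """Mean eccentricity over the anterior and posterior (vertical) canals.

    This is the specimen-level score reported alongside the diameter tables;
    the horizontal canal is excluded by convention.
    """
    values = []
    for cid in VERTICAL_CANALS:
        if cid not in rec.canals:
            raise MissingDataError(f"{rec.specimen_id}: no {cid} canal measured")
        c = rec.canals[cid]
        values.append(eccentricity(c.major_d, c.minor_d))
    return sum(values) / len(values)


def eccentricity_result(rec: SpecimenRecord) -> EccentricityResult:
    return EccentricityResult(
        specimen_id=rec.specimen_id,
        per_canal=canal_eccentricities(rec),
        vertical_mean=vertical_mean_eccentricity(rec),
    )


def canal_radius(major_d: float, minor_d: float) -> float:
    """Radius of curvature R = (major + minor diameter) / 4 in mm.

    Half the mean semi-diameter: the effective loop radius convention used by
    comparative datasets relating canal size to body mass.
    """
    if major_d <= 0 or minor_d <= 0:
        raise CanalmorphError(
            f"diameters must be positive, got major={major_d}, minor={minor_d}"
        )
    return (major_d + minor_d) / 4.0


def mean_canal_radius(rec: SpecimenRecord) -> RadiusResult:
    """Arithmetic mean radius of curvature over the three canals."""
    per_canal: dict[CanalId, float] = {}
    for cid in CANAL_IDS:
        if cid not in rec.canals:
            raise MissingDataError(f"{rec.specimen_id}: no {cid} canal measured")
        c = rec.canals[cid]
        per_canal[cid] = canal_radius(c.major_d, c.minor_d)
    mean_r = sum(per_canal.values()) / len(per_canal)
    return RadiusResult(
        specimen_id=rec.specimen_id,
        per_canal=per_canal,
        mean_radius=mean_r,
        log10_mean_radius=math.log10(mean_r),
    )


def orthogonality_deviation(mean_angles: Sequence[float]) -> float:
    """Sum of squared deviations from 90 degrees, in degrees squared.

    Takes the per-specimen mean inter-canal angles (one mean per specimen and
    angle pair) and returns 0 only for a perfectly orthogonal system.
    """
    angles = list(mean_angles)
    if not angles:
        raise CanalmorphError("orthogonality_deviation needs at least one angle")
    return sum((a - 90.0) ** 2 for a in angles)
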