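"""Quadrant and macular-zone geometry for a single-field 45-degree image.

The image is partitioned into four quadrants by two crossing lines: the
"horizontal" line through disc center and fovea, and its perpendicular
through the disc center.  Axes are anatomical (defined by the two
landmarks), not image axes, so arbitrarily rotated photographs partition
consistently.  Three concentric macular zones are bounded by circles of
radius 1DD and 2DD around the fovea center.

Quadrant id convention (fixed by this module, laterality-aware):
1 = superior-temporal, 2 = inferior-temporal,
3 = superior-nasal,   4 = inferior-nasal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .grading import (
    LOCALIZABLE_LESIONS,
    EyeGradingForm,
    Laterality,
    LesionType,
    MacularFindings,
    MacularZone,
    QuadrantFindings,
    VisualAcuity,
    ZoneFindings,
)

__all__ = [
    "Point2D",
    "FundusLandmarks",
    "AnnotatedLesion",
    "GeometryError",
    "quadrant_of",
    "macular_zone_of",
    "build_form",
]

#: Relative tolerance (in units of DD) for deciding a point lies on a line.
ON_LINE_TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate landmark geometry (e.g. fovea coincides with disc center)."""


@dataclass(frozen=True)
class Point2D:
    """Image pixel coordinates: origin top-left, x rightward, y downward.

    Coordinates are continuous; sub-pixel positions are allowed.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class FundusLandmarks:
    """Fovea, disc, disc diameter (DD, in pixels) and laterality."""

    fovea_center: Point2D
    disc_center: Point2D
    disc_diameter: float
    laterality: Laterality
    image_width: Optional[int] = None
    image_height: Optional[int] = None

    def __post_init__(self) -> None:
        if self.disc_diameter <= 0:
            raise GeometryError(f"disc_diameter must be positive, got {self.disc_diameter}")
        if (
            self.fovea_center.x == self.disc_center.x
            and self.fovea_center.y == self.disc_center.y
        ):
            raise GeometryError("fovea_center must differ from disc_center")


@dataclass(frozen=True)
class AnnotatedLesion:
    """One lesion annotation; global lesion types carry no location."""

    lesion_type: LesionType
    location: Optional[Point2D] = None
    microaneurysm: bool = False  # meaningful only for RED_DOTS_BLOTS
    prominent: bool = False  # meaningful only for IRMA


def _axes(lm: FundusLandmarks) -> tuple[tuple[float, float], tuple[float, float]]:
    """Unit axes (u, v): u disc->fovea (temporal), v toward anatomical superior."""
    dx = lm.fovea_center.x - lm.disc_center.x
    dy = lm.fovea_center.y - lm.disc_center.y
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        raise GeometryError("fovea_center must differ from disc_center")
    ux, uy = dx / norm, dy / norm
    # y grows downward, so the two perpendiculars swap superior/inferior
    # between eyes; flip for OS so mirrored OD/OS images label identically.
    if lm.laterality is Laterality.OD:
        vx, vy = uy, -ux
    else:
        vx, vy = -uy, ux
    return (ux, uy), (vx, vy)


def quadrant_of(p: Point2D, lm: FundusLandmarks) -> int:
    """Assign ``p`` to a quadrant id (1..4) under the anatomical convention.

    Signed coordinates (a, b) of ``p - disc_center`` on the (temporal,
    superior) axes select the quadrant.  Tie rule: points on a dividing
    line (|a| or |b| <= 1e-9*DD) go to the temporal / superior side.
    """
    (ux, uy), (vx, vy) = _axes(lm)
    px = p.x - lm.disc_center.x
    py = p.y - lm.disc_center.y
    a = px * ux + py * uy
    b = px * vx + py * vy
    tol = ON_LINE_TOL * lm.disc_diameter
    temporal = a >= -tol
    superior = b >= -tol
    if temporal and superior:
        return 1
    if temporal:
        return 2
    if superior:
        return 3
    return 4


def macular_zone_of(p: Point2D, lm: FundusLandmarks) -> MacularZone:
    """Zone by distance r from fovea center: [0,1DD) INNER, [1DD,2DD) MID, else OUTER."""
    r = math.hypot(p.x - lm.fovea_center.x, p.y - lm.fovea_center.y)
    dd = lm.disc_diameter
    if r < dd:
        return MacularZone.INNER
    if r < 2 * dd:
        return MacularZone.MID
    return MacularZone.OUTER


def build_form(
    lesions: Sequence[AnnotatedLesion],
    lm: FundusLandmarks,
    va: Optional[VisualAcuity] = None,
) -> EyeGradingForm:
    """Aggregate point annotations into a per-eye grading form.

    Quadrant and macular-zone bookkeeping are independent: a localizable
    lesion contributes to its quadrant and, for red dots and hard
    exudates, also to its macular zone.
    """
    counts = {i: 0 for i in (1, 2, 3, 4)}
    all_ma = {i: True for i in (1, 2, 3, 4)}
    flags: dict[int, dict[str, bool]] = {
        i: dict.fromkeys(
            ("hard_exudates", "cotton_wool", "venous_beading", "irma_present",
             "irma_prominent", "nvd", "nve"),
            False,
        )
        for i in (1, 2, 3, 4)
    }
    zone_flags = {
        z: {"hard_exudates": False, "red_dots_blots": False} for z in MacularZone
    }
    vit = False
    detached = False

    for lesion in lesions:
        if lesion.lesion_type in LOCALIZABLE_LESIONS:
            if lesion.location is None:
                raise ValueError(
                    f"lesion {lesion.lesion_type.value} requires a location"
                )
            qid = quadrant_of(lesion.location, lm)
            zone = macular_zone_of(lesion.location, lm)
            lt = lesion.lesion_type
            if lt is LesionType.RED_DOTS_BLOTS:
                counts[qid] += 1
                if not lesion.microaneurysm:
                    all_ma[qid] = False
                zone_flags[zone]["red_dots_blots"] = True
            elif lt is LesionType.HARD_EXUDATES:
                flags[qid]["hard_exudates"] = True
                zone_flags[zone]["hard_exudates"] = True
            elif lt is LesionType.COTTON_WOOL_SPOTS:
                flags[qid]["cotton_wool"] = True
            elif lt is LesionType.VENOUS_ABNORMALITY:
                flags[qid]["venous_beading"] = True
            elif lt is LesionType.IRMA:
                flags[qid]["irma_present"] = True
                if lesion.prominent:
                    flags[qid]["irma_prominent"] = True
            elif lt is LesionType.NVD:
                flags[qid]["nvd"] = True
            elif lt is LesionType.NVE:
                flags[qid]["nve"] = True
        elif lesion.lesion_type is LesionType.VITREOUS_PRERETINAL_HEMORRHAGE:
            vit = True
        elif lesion.lesion_type is LesionType.DETACHED_RETINA:
            detached = True

    quadrants = tuple(
        QuadrantFindings(
            quadrant_id=i,
            red_dot_count=counts[i],
            microaneurysms_only=counts[i] > 0 and all_ma[i],
            **flags[i],
        )
        for i in (1, 2, 3, 4)
    )
    macula = MacularFindings(
        inner=ZoneFindings(**zone_flags[MacularZone.INNER]),
        mid=ZoneFindings(**zone_flags[MacularZone.MID]),
        outer=ZoneFindings(**zone_flags[MacularZone.OUTER]),
    )
    return EyeGradingForm(
        laterality=lm.laterality,
        quadrants=quadrants,  # type: ignore[arg-type]
        macula=macula,
        vitreous_preretinal_hemorrhage=vit,
        detached_retina=detached,
        visual_acuity=va,
    )
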