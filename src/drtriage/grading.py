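"""Domain vocabulary for single-field fundus grading.

Defines the lesion taxonomy, the ordered referral categories, the
international-style severity scale, and the per-eye grading form that the
triage engine consumes.  Validation never raises: :func:`validate_form`
reports violations as strings so callers can surface all problems at once.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Any, Iterable, Optional

__all__ = [
    "LesionType",
    "ReferralCategory",
    "SeverityLevel",
    "Laterality",
    "MacularZone",
    "QuadrantFindings",
    "ZoneFindings",
    "MacularFindings",
    "VisualAcuity",
    "EyeGradingForm",
    "validate_form",
    "va_worse_than_20_40",
    "empty_form",
]


class LesionType(enum.Enum):
    """The nine lesion headings a grader can record."""

    RED_DOTS_BLOTS = "red_dots_blots"
    HARD_EXUDATES = "hard_exudates"
    COTTON_WOOL_SPOTS = "cotton_wool_spots"
    VENOUS_ABNORMALITY = "venous_abnormality"
    IRMA = "irma"
    NVD = "nvd"
    NVE = "nve"
    VITREOUS_PRERETINAL_HEMORRHAGE = "vitreous_preretinal_hemorrhage"
    DETACHED_RETINA = "detached_retina"


#: Lesions that carry an image location; the remaining two are global flags.
LOCALIZABLE_LESIONS = frozenset(
    {
        LesionType.RED_DOTS_BLOTS,
        LesionType.HARD_EXUDATES,
        LesionType.COTTON_WOOL_SPOTS,
        LesionType.VENOUS_ABNORMALITY,
        LesionType.IRMA,
        LesionType.NVD,
        LesionType.NVE,
    }
)


class ReferralCategory(enum.IntEnum):
    """Ordered triage outcome; larger value means more urgent referral."""

    GREEN_REVIEW_1_YEAR = 1
    YELLOW_REVIEW_6_MONTHS = 2
    RED_IMMEDIATE = 3

    @property
    def token(self) -> str:
        """Short lower-case token used in CSV files (``green``/``yellow``/``red``)."""
        return {1: "green", 2: "yellow", 3: "red"}[int(self)]

    @classmethod
    def from_token(cls, token: str) -> "ReferralCategory":
        t = token.strip().lower()
        mapping = {
            "green": cls.GREEN_REVIEW_1_YEAR,
            "yellow": cls.YELLOW_REVIEW_6_MONTHS,
            "red": cls.RED_IMMEDIATE,
        }
        if t not in mapping:
            raise ValueError(f"unknown referral token {token!r}")
        return mapping[t]


class SeverityLevel(enum.IntEnum):
    """Five-level severity scale; ordered by disease progression."""

    NO_DR = 0
    MILD_NPDR = 1
    MODERATE_NPDR = 2
    SEVERE_NPDR = 3
    PDR = 4


class Laterality(enum.Enum):
    OD = "OD"  # right eye
    OS = "OS"  # left eye


class MacularZone(enum.Enum):
    """Concentric macular zones: <1DD, 1-2DD, and >2DD from the fovea center."""

    INNER = "INNER"
    MID = "MID"
    OUTER = "OUTER"


@dataclass(frozen=True)
class QuadrantFindings:
    """Findings recorded for a single quadrant.

    ``red_dot_count`` pools microaneurysms, dot-blot and flame hemorrhages;
    ``microaneurysms_only`` is the grader's assertion that every red dot in
    the quadrant is a microaneurysm (carries the mild-vs-moderate split).
    """

    quadrant_id: int
    red_dot_count: int = 0
    microaneurysms_only: bool = False
    hard_exudates: bool = False
    cotton_wool: bool = False
    venous_beading: bool = False
    irma_present: bool = False
    irma_prominent: bool = False
    nvd: bool = False
    nve: bool = False


@dataclass(frozen=True)
class ZoneFindings:
    """Presence flags for one macular zone."""

    hard_exudates: bool = False
    red_dots_blots: bool = False


@dataclass(frozen=True)
class MacularFindings:
    """Findings in the three concentric macular zones."""

    inner: ZoneFindings = field(default_factory=ZoneFindings)
    mid: ZoneFindings = field(default_factory=ZoneFindings)
    outer: ZoneFindings = field(default_factory=ZoneFindings)

    def zone(self, zone: MacularZone) -> ZoneFindings:
        return {
            MacularZone.INNER: self.inner,
            MacularZone.MID: self.mid,
            MacularZone.OUTER: self.outer,
        }[zone]


@dataclass(frozen=True)
class VisualAcuity:
    """Snellen acuity as a fraction; compared on the decimal scale.

    The decimal scale makes metric and imperial notations equivalent:
    6/12 and 20/40 both have decimal value 0.5.
    """

    snellen_numerator: int
    snellen_denominator: int

    @property
    def decimal(self) -> float:
        return self.snellen_numerator / self.snellen_denominator

    def as_fraction(self) -> Fraction:
        return Fraction(self.snellen_numerator, self.snellen_denominator)


@dataclass(frozen=True)
class EyeGradingForm:
    """Self-contained per-eye grading record; the triage engine's input."""

    laterality: Laterality
    quadrants: tuple[QuadrantFindings, QuadrantFindings, QuadrantFindings, QuadrantFindings]
    macula: MacularFindings = field(default_factory=MacularFindings)
    vitreous_preretinal_hemorrhage: bool = False
    detached_retina: bool = False
    visual_acuity: Optional[VisualAcuity] = None

    def quadrant(self, quadrant_id: int) -> QuadrantFindings:
        for q in self.quadrants:
            if q.quadrant_id == quadrant_id:
                return q
        raise KeyError(f"no quadrant with id {quadrant_id}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "laterality": self.laterality.value,
            "quadrants": [
                {
                    "quadrant_id": q.quadrant_id,
                    "red_dot_count": q.red_dot_count,
                    "microaneurysms_only": q.microaneurysms_only,
                    "hard_exudates": q.hard_exudates,
                    "cotton_wool": q.cotton_wool,
                    "venous_beading": q.venous_beading,
                    "irma_present": q.irma_present,
                    "irma_prominent": q.irma_prominent,
                    "nvd": q.nvd,
                    "nve": q.nve,
                }
                for q in self.quadrants
            ],
            "macula": {
                zone: {
                    "hard_exudates": zf.hard_exudates,
                    "red_dots_blots": zf.red_dots_blots,
                }
                for zone, zf in (
                    ("inner", self.macula.inner),
                    ("mid", self.macula.mid),
                    ("outer", self.macula.outer),
                )
            },
            "vitreous_preretinal_hemorrhage": self.vitreous_preretinal_hemorrhage,
            "detached_retina": self.detached_retina,
        }
        if self.visual_acuity is not None:
            d["visual_acuity"] = {
                "snellen_numerator": self.visual_acuity.snellen_numerator,
                "snellen_denominator": self.visual_acuity.snellen_denominator,
            }
        else:
            d["visual_acuity"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EyeGradingForm":
        quads = tuple(
            QuadrantFindings(
                quadrant_id=int(q["quadrant_id"]),
                red_dot_count=int(q.get("red_dot_count", 0)),
                microaneurysms_only=bool(q.get("microaneurysms_only", False)),
                hard_exudates=bool(q.get("hard_exudates", False)),
                cotton_wool=bool(q.get("cotton_wool", False)),
                venous_beading=bool(q.get("venous_beading", False)),
                irma_present=bool(q.get("irma_present", False)),
                irma_prominent=bool(q.get("irma_prominent", False)),
                nvd=bool(q.get("nvd", False)),
                nve=bool(q.get("nve", False)),
            )
            for q in d["quadrants"]
        )
        mac = d.get("macula", {})

        def zone(name: str) -> ZoneFindings:
            z = mac.get(name, {})
            return ZoneFindings(
                hard_exudates=bool(z.get("hard_exudates", False)),
                red_dots_blots=bool(z.get("red_dots_blots", False)),
            )

        va = d.get("visual_acuity")
        return cls(
            laterality=Laterality(d["laterality"]),
            quadrants=quads,  # type: ignore[arg-type]
            macula=MacularFindings(inner=zone("inner"), mid=zone("mid"), outer=zone("outer")),
            vitreous_preretinal_hemorrhage=bool(d.get("vitreous_preretinal_hemorrhage", False)),
            detached_retina=bool(d.get("detached_retina", False)),
            visual_acuity=(
                VisualAcuity(int(va["snellen_numerator"]), int(va["snellen_denominator"]))
                if va
                else None
            ),
        )


def empty_form(laterality: Laterality = Laterality.OD) -> EyeGradingForm:
    """A well-formed form with no findings (quadrant ids 1..4)."""
    return EyeGradingForm(
        laterality=laterality,
        quadrants=tuple(QuadrantFindings(quadrant_id=i) for i in (1, 2, 3, 4)),  # type: ignore[arg-type]
    )


def _validate_quadrant(q: QuadrantFindings) -> Iterable[str]:
    if not isinstance(q.quadrant_id, int) or not 1 <= q.quadrant_id <= 4:
        yield f"quadrant_id: must be an integer in 1..4, got {q.quadrant_id!r}"
    if q.red_dot_count < 0:
        yield f"quadrant {q.quadrant_id}: red_dot_count must be non-negative, got {q.red_dot_count}"
    if q.irma_prominent and not q.irma_present:
        yield f"quadrant {q.quadrant_id}: irma_prominent implies irma_present"
    if q.microaneurysms_only and q.red_dot_count <= 0:
        yield f"quadrant {q.quadrant_id}: microaneurysms_only implies red_dot_count > 0"


def validate_form(form: EyeGradingForm) -> list[str]:
    """Check every grading-form invariant; return violation descriptions.

    Returns an empty list iff the form is well-formed.  Never raises.
    """
    violations: list[str] = []
    if len(form.quadrants) != 4:
        violations.append(f"quadrants: exactly 4 required, got {len(form.quadrants)}")
    ids = [q.quadrant_id for q in form.quadrants]
    seen: set[int] = set()
    for qid in ids:
        if qid in seen:
            violations.append(f"quadrants: duplicate quadrant_id {qid}")
        seen.add(qid)
    for q in form.quadrants:
        violations.extend(_validate_quadrant(q))
    va = form.visual_acuity
    if va is not None:
        if va.snellen_numerator <= 0 or va.snellen_denominator <= 0:
            violations.append(
                "visual_acuity: numerator and denominator must be positive, "
                f"got {va.snellen_numerator}/{va.snellen_denominator}"
            )
        elif not 0 < va.decimal <= 2.5:
            violations.append(
                f"visual_acuity: decimal value must be in (0, 2.5], got {va.decimal:g}"
            )
    return violations


def va_worse_than_20_40(va: VisualAcuity) -> bool:
    """True iff acuity is strictly worse than 20/40 on the decimal scale.

    20/40 itself (decimal 0.5) is *not* worse; 6/12 is equivalent to 20/40.
    """
    if va.snellen_numerator <= 0 or va.snellen_denominator <= 0:
        raise ValueError(
            f"invalid visual acuity {va.snellen_numerator}/{va.snellen_denominator}"
        )
    return va.as_fraction() < Fraction(1, 2)


# convenience re-export for callers building modified forms
__all__.append("replace")
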