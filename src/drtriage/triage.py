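"""Rule engine mapping a grading form to color marks, severity and referral.

The decision matrix is a single declarative table (``RULES`` plus the
``DEFAULT_COLOR_MATRIX`` name->color map), so an alternate reconstruction
of the color assignments is a configuration swap, not a code change.

Referral logic: any RED box -> immediate referral; else any YELLOW box ->
review in 6 months, escalated to immediate if acuity is worse than 20/40;
else review in 1 year.  Two eyes combine by taking the worse referral.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .grading import (
    EyeGradingForm,
    ReferralCategory,
    SeverityLevel,
    validate_form,
    va_worse_than_20_40,
)

__all__ = [
    "BoxColor",
    "ColorMark",
    "TriageResult",
    "FormValidationError",
    "DEFAULT_COLOR_MATRIX",
    "load_color_matrix",
    "mark_boxes",
    "classify_severity",
    "eye_referral",
    "patient_referral",
]


class BoxColor(enum.IntEnum):
    """Color of a marked box; ordered by urgency."""

    GREEN = 1
    YELLOW = 2
    RED = 3

    @property
    def referral(self) -> ReferralCategory:
        return ReferralCategory(int(self))


class FormValidationError(ValueError):
    """Raised when a triage operation receives an invalid form."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class ColorMark:
    """One marked box with an audit trail of why it was marked."""

    color: BoxColor
    rule: str
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("every mark must carry at least one source")


@dataclass(frozen=True)
class TriageResult:
    marks: tuple[ColorMark, ...]
    severity: SeverityLevel
    dme_present: bool
    referral: ReferralCategory
    va_escalated: bool
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Decision matrix.  Each rule returns the list of sources if it fires, else
# an empty list; its color comes from the (overridable) color matrix.
# ---------------------------------------------------------------------------

def _r_hemorrhages_all_quadrants(form: EyeGradingForm) -> list[str]:
    if all(q.red_dot_count > 20 for q in form.quadrants):
        return [
            f"RED_DOTS_BLOTS x{q.red_dot_count} in quadrant {q.quadrant_id}"
            for q in form.quadrants
        ]
    return []


def _r_venous_beading_2plus(form: EyeGradingForm) -> list[str]:
    qs = [q.quadrant_id for q in form.quadrants if q.venous_beading]
    if len(qs) >= 2:
        return [f"VENOUS_ABNORMALITY in quadrant {qid}" for qid in qs]
    return []


def _r_prominent_irma(form: EyeGradingForm) -> list[str]:
    return [
        f"IRMA (prominent) in quadrant {q.quadrant_id}"
        for q in form.quadrants
        if q.irma_prominent
    ]


def _r_neovascularization(form: EyeGradingForm) -> list[str]:
    out = []
    for q in form.quadrants:
        if q.nvd:
            out.append(f"NVD in quadrant {q.quadrant_id}")
        if q.nve:
            out.append(f"NVE in quadrant {q.quadrant_id}")
    return out


def _r_vitreous_hemorrhage(form: EyeGradingForm) -> list[str]:
    return ["VITREOUS_PRERETINAL_HEMORRHAGE"] if form.vitreous_preretinal_hemorrhage else []


def _r_detached_retina(form: EyeGradingForm) -> list[str]:
    return ["DETACHED_RETINA"] if form.detached_retina else []


def _r_macula_inner(form: EyeGradingForm) -> list[str]:
    out = []
    if form.macula.inner.hard_exudates:
        out.append("HARD_EXUDATES in macular zone INNER")
    if form.macula.inner.red_dots_blots:
        out.append("RED_DOTS_BLOTS in macular zone INNER")
    return out


def _r_macula_mid(form: EyeGradingForm) -> list[str]:
    out = []
    if form.macula.mid.hard_exudates:
        out.append("HARD_EXUDATES in macular zone MID")
    if form.macula.mid.red_dots_blots:
        out.append("RED_DOTS_BLOTS in macular zone MID")
    return out


def _r_red_dots_not_ma_only(form: EyeGradingForm) -> list[str]:
    # suppressed when the all-4-quadrant hemorrhage rule covers the finding
    if _r_hemorrhages_all_quadrants(form):
        return []
    return [
        f"RED_DOTS_BLOTS x{q.red_dot_count} in quadrant {q.quadrant_id}"
        for q in form.quadrants
        if q.red_dot_count > 0 and not q.microaneurysms_only
    ]


def _r_hard_exudates(form: EyeGradingForm) -> list[str]:
    return [
        f"HARD_EXUDATES in quadrant {q.quadrant_id}"
        for q in form.quadrants
        if q.hard_exudates
    ]


def _r_cotton_wool(form: EyeGradingForm) -> list[str]:
    return [
        f"COTTON_WOOL_SPOTS in quadrant {q.quadrant_id}"
        for q in form.quadrants
        if q.cotton_wool
    ]


def _r_venous_beading_single(form: EyeGradingForm) -> list[str]:
    qs = [q.quadrant_id for q in form.quadrants if q.venous_beading]
    if len(qs) == 1:
        return [f"VENOUS_ABNORMALITY in quadrant {qs[0]}"]
    return []


def _r_irma_not_prominent(form: EyeGradingForm) -> list[str]:
    return [
        f"IRMA in quadrant {q.quadrant_id}"
        for q in form.quadrants
        if q.irma_present and not q.irma_prominent
    ]


def _r_microaneurysms_only(form: EyeGradingForm) -> list[str]:
    if _r_hemorrhages_all_quadrants(form):
        return []
    affected = [q for q in form.quadrants if q.red_dot_count > 0]
    if affected and all(q.microaneurysms_only for q in affected):
        return [
            f"RED_DOTS_BLOTS (microaneurysms only) x{q.red_dot_count}"
            f" in quadrant {q.quadrant_id}"
            for q in affected
        ]
    return []


#: Rule name -> predicate.  Order is RED rules, YELLOW rules, GREEN rules.
RULES: dict[str, Callable[[EyeGradingForm], list[str]]] = {
    "hemorrhages_over_20_all_4_quadrants": _r_hemorrhages_all_quadrants,
    "venous_beading_2plus_quadrants": _r_venous_beading_2plus,
    "prominent_irma_any_quadrant": _r_prominent_irma,
    "neovascularization": _r_neovascularization,
    "vitreous_preretinal_hemorrhage": _r_vitreous_hemorrhage,
    "detached_retina": _r_detached_retina,
    "macula_inner_lesions": _r_macula_inner,
    "macula_mid_lesions": _r_macula_mid,
    "red_dots_not_microaneurysms_only": _r_red_dots_not_ma_only,
    "hard_exudates_any_quadrant": _r_hard_exudates,
    "cotton_wool_any_quadrant": _r_cotton_wool,
    "venous_beading_single_quadrant": _r_venous_beading_single,
    "irma_not_prominent": _r_irma_not_prominent,
    "microaneurysms_only": _r_microaneurysms_only,
}

#: Default color for each rule; override via `load_color_matrix`.
DEFAULT_COLOR_MATRIX: dict[str, BoxColor] = {
    "hemorrhages_over_20_all_4_quadrants": BoxColor.RED,
    "venous_beading_2plus_quadrants": BoxColor.RED,
    "prominent_irma_any_quadrant": BoxColor.RED,
    "neovascularization": BoxColor.RED,
    "vitreous_preretinal_hemorrhage": BoxColor.RED,
    "detached_retina": BoxColor.RED,
    "macula_inner_lesions": BoxColor.RED,
    "macula_mid_lesions": BoxColor.YELLOW,
    "red_dots_not_microaneurysms_only": BoxColor.YELLOW,
    "hard_exudates_any_quadrant": BoxColor.YELLOW,
    "cotton_wool_any_quadrant": BoxColor.YELLOW,
    "venous_beading_single_quadrant": BoxColor.YELLOW,
    "irma_not_prominent": BoxColor.YELLOW,
    "microaneurysms_only": BoxColor.GREEN,
}

#: Severe-NPDR criteria (4-2-1 rule) within the matrix.
SEVERE_NPDR_RULES = (
    "hemorrhages_over_20_all_4_quadrants",
    "venous_beading_2plus_quadrants",
    "prominent_irma_any_quadrant",
)

#: Rules indicating proliferative disease.
PDR_RULES = (
    "neovascularization",
    "vitreous_preretinal_hemorrhage",
    "detached_retina",
)

#: Rules indicating moderate NPDR (more than microaneurysms, less than severe).
MODERATE_NPDR_RULES = (
    "red_dots_not_microaneurysms_only",
    "hard_exudates_any_quadrant",
    "cotton_wool_any_quadrant",
    "venous_beading_single_quadrant",
    "irma_not_prominent",
    "macula_mid_lesions",
)


def load_color_matrix(path: str) -> dict[str, BoxColor]:
    """Load a color-matrix override (JSON rule-name -> green|yellow|red)."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    matrix = dict(DEFAULT_COLOR_MATRIX)
    for name, color in raw.items():
        if name not in RULES:
            raise ValueError(f"unknown rule name in color matrix: {name!r}")
        try:
            matrix[name] = BoxColor[str(color).upper()]
        except KeyError:
            raise ValueError(f"unknown color {color!r} for rule {name!r}") from None
    return matrix


def _check(form: EyeGradingForm) -> None:
    violations = validate_form(form)
    if violations:
        raise FormValidationError(violations)


def mark_boxes(
    form: EyeGradingForm,
    matrix: Optional[dict[str, BoxColor]] = None,
) -> list[ColorMark]:
    """Evaluate the decision matrix; return all marked boxes with sources.

    A form with no red or yellow findings yields a single GREEN mark
    (either "microaneurysms only" or "no findings").
    """
    _check(form)
    matrix = matrix or DEFAULT_COLOR_MATRIX
    marks: list[ColorMark] = []
    for name, rule in RULES.items():
        sources = rule(form)
        if sources:
            marks.append(ColorMark(color=matrix[name], rule=name, sources=tuple(sources)))
    if not marks:
        marks.append(
            ColorMark(color=BoxColor.GREEN, rule="no_findings", sources=("no DR lesions",))
        )
    return marks


def classify_severity(form: EyeGradingForm) -> tuple[SeverityLevel, bool]:
    """Severity on the five-level scale plus a macular-edema flag.

    PDR if any proliferative finding; severe NPDR on the 4-2-1 criteria;
    moderate NPDR on any lesser finding beyond microaneurysms; mild NPDR
    when every affected quadrant has microaneurysms only; else no DR.
    ``dme_present`` is driven by inner-zone macular findings.
    """
    _check(form)
    dme = bool(form.macula.inner.hard_exudates or form.macula.inner.red_dots_blots)
    fired = {name for name in RULES if RULES[name](form)}
    if fired & set(PDR_RULES):
        return SeverityLevel.PDR, dme
    if fired & set(SEVERE_NPDR_RULES):
        return SeverityLevel.SEVERE_NPDR, dme
    if fired & set(MODERATE_NPDR_RULES):
        return SeverityLevel.MODERATE_NPDR, dme
    if "microaneurysms_only" in fired:
        return SeverityLevel.MILD_NPDR, dme
    return SeverityLevel.NO_DR, dme


def eye_referral(
    form: EyeGradingForm,
    matrix: Optional[dict[str, BoxColor]] = None,
) -> TriageResult:
    """Full single-eye triage: marks, severity, and referral category.

    Acuity worse than 20/40 escalates a YELLOW eye to immediate referral;
    a GREEN eye with poor acuity stays GREEN but a warning is recorded.
    """
    marks = mark_boxes(form, matrix)
    severity, dme = classify_severity(form)
    best = max(m.color for m in marks)
    warnings: list[str] = []
    va_escalated = False
    va = form.visual_acuity
    poor_va = va is not None and va_worse_than_20_40(va)
    if best is BoxColor.YELLOW and poor_va:
        referral = ReferralCategory.RED_IMMEDIATE
        va_escalated = True
    else:
        referral = best.referral
        if best is BoxColor.GREEN and poor_va:
            warnings.append(
                "visual acuity worse than 20/40 with only green boxes; "
                "not escalated, consider non-DR causes"
            )
    return TriageResult(
        marks=tuple(marks),
        severity=severity,
        dme_present=dme,
        referral=referral,
        va_escalated=va_escalated,
        warnings=tuple(warnings),
    )


def patient_referral(od: TriageResult, os_: TriageResult) -> ReferralCategory:
    """Patient-level referral: the worse of the two eyes."""
    return max(od.referral, os_.referral)
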