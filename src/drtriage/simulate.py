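"""Synthetic reader studies and fundus annotation sets with known truth.

Readers are conditionally independent given the gold label: each reader
has a 3x3 row-stochastic confusion matrix P(response | gold) plus a
missing-response probability.  Fundus cases are constructed from the
decision matrix so that the expected referral is a certificate of the
construction, not a re-run of the triage engine.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import AnnotatedLesion, FundusLandmarks, Point2D, macular_zone_of, quadrant_of
from .grading import LesionType, MacularZone, ReferralCategory
from .stats import MISSING, StudyDataset

__all__ = [
    "ReaderProfile",
    "SimulationConfig",
    "CaseCertificate",
    "simulate_reader_study",
    "simulate_fundus_case",
    "uniform_profiles",
    "DEFAULT_GOLD_PROPORTIONS",
]

#: Category order used for confusion-matrix rows/columns.
CATEGORY_ORDER = (
    ReferralCategory.GREEN_REVIEW_1_YEAR,
    ReferralCategory.YELLOW_REVIEW_6_MONTHS,
    ReferralCategory.RED_IMMEDIATE,
)

#: Gold mix (green, yellow, red) inferred from the 4780-response one-vs-rest
#: margins (1138, 1241, 2401); the true per-image mix is not published.
DEFAULT_GOLD_PROPORTIONS = (1138 / 4780, 1241 / 4780, 2401 / 4780)


@dataclass(frozen=True)
class ReaderProfile:
    """Reader behavior: response distribution per gold category + missingness."""

    confusion: np.ndarray  # 3x3 row-stochastic, rows/cols in CATEGORY_ORDER
    missing_rate: float = 0.0
    group: str = "working"
    prior_grading: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.confusion, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"confusion must be 3x3, got shape {m.shape}")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "confusion", m)


@dataclass(frozen=True)
class SimulationConfig:
    n_images: int
    gold_proportions: tuple[float, float, float] = DEFAULT_GOLD_PROPORTIONS
    readers: Sequence[ReaderProfile] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        p = np.asarray(self.gold_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("gold_proportions must be a 3-vector summing to 1")
        if not self.readers:
            raise ValueError("at least one reader profile is required")


def uniform_profiles(
    n_readers: int,
    confusion: np.ndarray,
    missing_rate: float = 0.0,
    group: str = "working",
    prior_grading: bool = False,
) -> list[ReaderProfile]:
    """n identical reader profiles (convenience for pooled-recovery studies)."""
    return [
        ReaderProfile(
            confusion=confusion,
            missing_rate=missing_rate,
            group=group,
            prior_grading=prior_grading,
        )
        for _ in range(n_readers)
    ]


def simulate_reader_study(cfg: SimulationConfig) -> StudyDataset:
    """Draw a full study: gold labels, per-reader responses, missingness.

    Fully reproducible from ``cfg.seed``; readers are processed in order
    with a single generator stream.
    """
    rng = np.random.default_rng(cfg.seed)
    n_img = cfg.n_images
    width = max(3, len(str(n_img)))
    image_ids = np.array([f"img{i + 1:0{width}d}" for i in range(n_img)])
    gold_idx = rng.choice(3, size=n_img, p=np.asarray(cfg.gold_proportions, dtype=float))
    tokens = np.array([c.token for c in CATEGORY_ORDER])
    gold = pd.Series(tokens[gold_idx], index=image_ids, name="referral")

    rwidth = max(3, len(str(len(cfg.readers))))
    frames = []
    attr_rows = []
    for r, profile in enumerate(cfg.readers):
        reader_id = f"r{r + 1:0{rwidth}d}"
        rows = profile.confusion[gold_idx]  # (n_img, 3)
        cum = np.cumsum(rows, axis=1)
        u = rng.random(n_img)
        resp_idx = (u[:, None] > cum).sum(axis=1).clip(0, 2)
        resp = tokens[resp_idx].astype(object)
        if profile.missing_rate > 0:
            resp[rng.random(n_img) < profile.missing_rate] = MISSING
        frames.append(
            pd.DataFrame(
                {"reader_id": reader_id, "image_id": image_ids, "response": resp}
            )
        )
        attr_rows.append(
            {
                "reader_id": reader_id,
                "group": profile.group,
                "prior_grading": profile.prior_grading,
            }
        )
    responses = pd.concat(frames, ignore_index=True)
    reader_attrs = pd.DataFrame(attr_rows).set_index("reader_id")
    return StudyDataset(gold=gold, responses=responses, reader_attrs=reader_attrs)


# ---------------------------------------------------------------------------
# fundus cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseCertificate:
    """Why a constructed lesion set must triage to ``referral``."""

    referral: ReferralCategory
    rule: str


def _point_in(
    rng: np.random.Generator,
    lm: FundusLandmarks,
    quadrant: Optional[int] = None,
    zone: Optional[MacularZone] = None,
) -> Point2D:
    """Rejection-sample a point in the requested quadrant and/or macular zone."""
    dd = lm.disc_diameter
    fx, fy = lm.fovea_center.x, lm.fovea_center.y
    for _ in range(10_000):
        if zone is MacularZone.INNER:
            r = rng.uniform(0.05, 0.95) * dd
        elif zone is MacularZone.MID:
            r = rng.uniform(1.05, 1.95) * dd
        else:
            r = rng.uniform(2.1, 6.0) * dd
        theta = rng.uniform(0, 2 * math.pi)
        p = Point2D(fx + r * math.cos(theta), fy + r * math.sin(theta))
        if zone is not None and macular_zone_of(p, lm) is not zone:
            continue
        if quadrant is not None and quadrant_of(p, lm) != quadrant:
            continue
        return p
    raise RuntimeError("rejection sampling failed to place a lesion")


def simulate_fundus_case(
    target: ReferralCategory,
    lm: FundusLandmarks,
    seed: int,
) -> tuple[list[AnnotatedLesion], CaseCertificate]:
    """Construct a lesion set whose triage provably yields ``target``.

    One of several constructions is drawn at random per target; the
    returned certificate names the decision-matrix rule it exercises.
    """
    rng = np.random.default_rng(seed)
    outer = MacularZone.OUTER
    if target is ReferralCategory.GREEN_REVIEW_1_YEAR:
        if rng.random() < 0.5:
            return [], CaseCertificate(target, "no_findings")
        lesions = [
            AnnotatedLesion(
                LesionType.RED_DOTS_BLOTS,
                _point_in(rng, lm, zone=outer),
                microaneurysm=True,
            )
            for _ in range(int(rng.integers(1, 4)))
        ]
        return lesions, CaseCertificate(target, "microaneurysms_only")

    if target is ReferralCategory.YELLOW_REVIEW_6_MONTHS:
        choice = int(rng.integers(0, 4))
        if choice == 0:
            lesions = [
                AnnotatedLesion(LesionType.COTTON_WOOL_SPOTS, _point_in(rng, lm, zone=outer))
            ]
            rule = "cotton_wool_any_quadrant"
        elif choice == 1:
            lesions = [
                AnnotatedLesion(
                    LesionType.RED_DOTS_BLOTS,
                    _point_in(rng, lm, zone=outer),
                    microaneurysm=False,
                )
            ]
            rule = "red_dots_not_microaneurysms_only"
        elif choice == 2:
            lesions = [
                AnnotatedLesion(LesionType.HARD_EXUDATES, _point_in(rng, lm, zone=outer))
            ]
            rule = "hard_exudates_any_quadrant"
        else:
            lesions = [
                AnnotatedLesion(LesionType.VENOUS_ABNORMALITY, _point_in(rng, lm, zone=outer))
            ]
            rule = "venous_beading_single_quadrant"
        return lesions, CaseCertificate(target, rule)

    # RED constructions
    choice = int(rng.integers(0, 6))
    if choice == 0:
        lesions = [
            AnnotatedLesion(LesionType.RED_DOTS_BLOTS, _point_in(rng, lm, quadrant=q, zone=outer))
            for q in (1, 2, 3, 4)
            for _ in range(21)
        ]
        rule = "hemorrhages_over_20_all_4_quadrants"
    elif choice == 1:
        q1, q2 = rng.choice([1, 2, 3, 4], size=2, replace=False)
        lesions = [
            AnnotatedLesion(LesionType.VENOUS_ABNORMALITY, _point_in(rng, lm, quadrant=int(q1), zone=outer)),
            AnnotatedLesion(LesionType.VENOUS_ABNORMALITY, _point_in(rng, lm, quadrant=int(q2), zone=outer)),
        ]
        rule = "venous_beading_2plus_quadrants"
    elif choice == 2:
        lesions = [
            AnnotatedLesion(LesionType.IRMA, _point_in(rng, lm, zone=outer), prominent=True)
        ]
        rule = "prominent_irma_any_quadrant"
    elif choice == 3:
        lt = LesionType.NVD if rng.random() < 0.5 else LesionType.NVE
        lesions = [AnnotatedLesion(lt, _point_in(rng, lm, zone=outer))]
        rule = "neovascularization"
    elif choice == 4:
        lt = (
            LesionType.VITREOUS_PRERETINAL_HEMORRHAGE
            if rng.random() < 0.5
            else LesionType.DETACHED_RETINA
        )
        lesions = [AnnotatedLesion(lt)]
        rule = (
            "vitreous_preretinal_hemorrhage"
            if lt is LesionType.VITREOUS_PRERETINAL_HEMORRHAGE
            else "detached_retina"
        )
    else:
        lesions = [
            AnnotatedLesion(LesionType.HARD_EXUDATES, _point_in(rng, lm, zone=MacularZone.INNER))
        ]
        rule = "macula_inner_lesions"
    return lesions, CaseCertificate(ReferralCategory.RED_IMMEDIATE, rule)
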