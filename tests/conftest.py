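"""Shared fixtures: reference landmarks, independent oracles, form generators."""
from __future__ import annotations

import math
import random

import numpy as np
import pytest

from drtriage.geometry import FundusLandmarks, Point2D
from drtriage.grading import (
    EyeGradingForm,
    Laterality,
    MacularFindings,
    QuadrantFindings,
    VisualAcuity,
    ZoneFindings,
)


@pytest.fixture
def landmarks_od() -> FundusLandmarks:
    """Upright right-eye landmarks: disc (100,100), fovea (200,100), DD=50."""
    return FundusLandmarks(
        fovea_center=Point2D(200.0, 100.0),
        disc_center=Point2D(100.0, 100.0),
        disc_diameter=50.0,
        laterality=Laterality.OD,
        image_width=768,
        image_height=576,
    )


def brute_force_quadrant(p: Point2D, lm: FundusLandmarks) -> int:
    """Independent half-plane oracle for the quadrant assignment.

    Temporal iff the point and the fovea are on the same (closed) side of
    the perpendicular line through the disc center.  Superior iff the
    point lies on the upper side of the disc-fovea line, where "upper" is
    resolved by the cross-product sign in y-down coordinates with the
    laterality flip.  Tie rule: on-line points count as temporal/superior.
    """
    dx = lm.fovea_center.x - lm.disc_center.x
    dy = lm.fovea_center.y - lm.disc_center.y
    px = p.x - lm.disc_center.x
    py = p.y - lm.disc_center.y
    tol = 1e-9 * lm.disc_diameter * math.hypot(dx, dy)
    # half-plane test vs the perpendicular line: sign of the dot product
    temporal = dx * px + dy * py >= -tol
    # half-plane test vs the disc-fovea line: sign of the cross product;
    # in y-down coordinates positive cross means "below" for OD
    cross = dx * py - dy * px
    if lm.laterality is Laterality.OD:
        superior = cross <= tol
    else:
        superior = cross >= -tol
    if temporal and superior:
        return 1
    if temporal:
        return 2
    if superior:
        return 3
    return 4


def random_valid_form(rng: random.Random) -> EyeGradingForm:
    """A random well-formed grading form."""
    quads = []
    for qid in (1, 2, 3, 4):
        count = rng.choice([0, 0, 0, 1, 3, 21, 25])
        irma_present = rng.random() < 0.2
        quads.append(
            QuadrantFindings(
                quadrant_id=qid,
                red_dot_count=count,
                microaneurysms_only=count > 0 and rng.random() < 0.4,
                hard_exudates=rng.random() < 0.2,
                cotton_wool=rng.random() < 0.2,
                venous_beading=rng.random() < 0.2,
                irma_present=irma_present,
                irma_prominent=irma_present and rng.random() < 0.4,
                nvd=rng.random() < 0.1,
                nve=rng.random() < 0.1,
            )
        )

    def zone() -> ZoneFindings:
        return ZoneFindings(
            hard_exudates=rng.random() < 0.15, red_dots_blots=rng.random() < 0.15
        )

    va = None
    if rng.random() < 0.5:
        va = VisualAcuity(20, rng.choice([20, 30, 40, 60, 100, 200]))
    return EyeGradingForm(
        laterality=rng.choice([Laterality.OD, Laterality.OS]),
        quadrants=tuple(quads),  # type: ignore[arg-type]
        macula=MacularFindings(inner=zone(), mid=zone(), outer=zone()),
        vitreous_preretinal_hemorrhage=rng.random() < 0.1,
        detached_retina=rng.random() < 0.05,
        visual_acuity=va,
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20160923)


@pytest.fixture
def nprng() -> np.random.Generator:
    return np.random.default_rng(20160923)
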