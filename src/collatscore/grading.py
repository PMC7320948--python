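"""Whole-brain collateral vessel scoring from CT-angiography grades.

The grading sheet assigns each intracranial vessel (or vessel segment) an
integer code read off the admission CT-angiogram:

* graded vessels (VA, BAS, PCA segments P1-P3, Pcom, ICA, ACA segments
  A1-A2, Acom, MCA segments M1-M3) use codes
  ``-4`` occluded, ``-3`` visible stenosis, ``-2`` hypoplastic,
  ``-1`` diameter variations, ``0`` not assessable, ``1`` normal;
* assessability-only vessels (PICA, AICA, SCA, ophthalmic artery, middle
  meningeal artery) score ``1`` if assessable, ``0`` otherwise;
* pial (leptomeningeal) collaterals are counted: cortical pial arteries map
  to a 0-2 score (0 for 0-8 visible, 1 for 9-11, 2 for more than 11) and
  cerebellar pial arteries map to 0-2 (0 none visible, 1 for one or two,
  2 for more than two).

The whole-brain score sums left and right grades into one value per vessel,
weights ACA/MCA/PCA segments proximal-to-distal (proximal atherosclerosis
being the more devastating lesion): ``ACA = 2*A1 + A2``,
``MCA = 4*M1 + 2*M2 + M3``, ``PCA = 4*P1 + 2*P2 + P3``, summarises the
internal carotid in a single side-summed ICA factor, and adds the
assessability points and both pial scores.  Higher is better collateral
supply; the all-normal sheet scores 56.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Side",
    "Vessel",
    "VesselGrade",
    "PialCounts",
    "PatientVasculature",
    "ScoreBreakdown",
    "GradingError",
    "side_sum",
    "weighted_segment_score",
    "pial_scores",
    "whole_brain_score",
    "pial_only_score",
    "SLOTS",
    "SLOT_WEIGHTS",
    "MAX_WHOLE_BRAIN_SCORE",
    "MIN_WHOLE_BRAIN_SCORE",
]


class GradingError(ValueError):
    """Invalid grade code, side, or an incomplete/duplicated grading sheet."""


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


class Vessel(str, Enum):
    VA = "VA"
    BAS = "BAS"
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    PCOM = "Pcom"
    ICA = "ICA"
    A1 = "A1"
    A2 = "A2"
    ACOM = "Acom"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    PICA = "PICA"
    AICA = "AICA"
    SCA = "SCA"
    OPHTHALMIC = "ophthalmic"
    MMA = "MMA"


#: paired vessels carrying the full -4..1 grade code
PAIRED_GRADED: tuple[Vessel, ...] = (
    Vessel.VA,
    Vessel.PCOM,
    Vessel.ICA,
    Vessel.A1,
    Vessel.A2,
    Vessel.M1,
    Vessel.M2,
    Vessel.M3,
    Vessel.P1,
    Vessel.P2,
    Vessel.P3,
)
#: anatomically unpaired vessels; a single midline grade, full code set
MIDLINE_GRADED: tuple[Vessel, ...] = (Vessel.BAS, Vessel.ACOM)
#: vessels scored only for assessability (1 assessable / 0 not)
ASSESSABILITY: tuple[Vessel, ...] = (
    Vessel.PICA,
    Vessel.AICA,
    Vessel.SCA,
    Vessel.OPHTHALMIC,
    Vessel.MMA,
)

GRADED_CODES = frozenset(range(-4, 2))
ASSESS_CODES = frozenset((0, 1))

#: segment weights for the three weighted territories
SEGMENT_WEIGHTS: dict[str, dict[Vessel, int]] = {
    "ACA": {Vessel.A1: 2, Vessel.A2: 1},
    "MCA": {Vessel.M1: 4, Vessel.M2: 2, Vessel.M3: 1},
    "PCA": {Vessel.P1: 4, Vessel.P2: 2, Vessel.P3: 1},
}

_SEGMENT_TO_TERRITORY = {
    seg: terr for terr, w in SEGMENT_WEIGHTS.items() for seg in w
}


def _build_slots() -> tuple[tuple[Vessel, Side], ...]:
    slots: list[tuple[Vessel, Side]] = []
    for v in PAIRED_GRADED:
        slots.append((v, Side.LEFT))
        slots.append((v, Side.RIGHT))
    for v in MIDLINE_GRADED:
        slots.append((v, Side.MIDLINE))
    for v in ASSESSABILITY:
        slots.append((v, Side.LEFT))
        slots.append((v, Side.RIGHT))
    return tuple(slots)


#: canonical slot ordering of a complete sheet (34 entries)
SLOTS: tuple[tuple[Vessel, Side], ...] = _build_slots()

#: aggregation weight of each slot in the whole-brain sum
SLOT_WEIGHTS: dict[tuple[Vessel, Side], int] = {
    (v, s): SEGMENT_WEIGHTS[_SEGMENT_TO_TERRITORY[v]][v]
    if v in _SEGMENT_TO_TERRITORY
    else 1
    for (v, s) in SLOTS
}

MAX_WHOLE_BRAIN_SCORE = 56
MIN_WHOLE_BRAIN_SCORE = -168


def allowed_codes(vessel: Vessel) -> frozenset[int]:
    """Grade codes the sheet accepts for *vessel*."""
    return ASSESS_CODES if vessel in ASSESSABILITY else GRADED_CODES


def allowed_sides(vessel: Vessel) -> tuple[Side, ...]:
    if vessel in MIDLINE_GRADED:
        return (Side.MIDLINE,)
    return (Side.LEFT, Side.RIGHT)


@dataclass(frozen=True)
class VesselGrade:
    """One graded vessel/segment observation."""

    vessel: Vessel
    side: Side
    grade: int

    def __post_init__(self) -> None:
        vessel = Vessel(self.vessel)
        side = Side(self.side)
        object.__setattr__(self, "vessel", vessel)
        object.__setattr__(self, "side", side)
        if side not in allowed_sides(vessel):
            raise GradingError(
                f"{vessel.value}: side must be one of "
                f"{[s.value for s in allowed_sides(vessel)]}, got {side.value!r}"
            )
        if self.grade not in allowed_codes(vessel):
            raise GradingError(
                f"{vessel.value} ({side.value}): grade {self.grade!r} outside "
                f"allowed codes {sorted(allowed_codes(vessel))}"
            )


@dataclass(frozen=True)
class PialCounts:
    """Counts of visible pial (leptomeningeal) arteries on CTA."""

    cortical_count: int
    cerebellar_count: int

    def __post_init__(self) -> None:
        for name in ("cortical_count", "cerebellar_count"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise GradingError(f"pial {name} must be an integer, got {value!r}")
            if value < 0:
                raise GradingError(f"pial {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class PatientVasculature:
    """A complete per-patient grading sheet: one grade per slot plus pial counts."""

    grades: tuple[VesselGrade, ...]
    pial: PialCounts

    def __post_init__(self) -> None:
        seen: dict[tuple[Vessel, Side], int] = {}
        for g in self.grades:
            key = (g.vessel, g.side)
            if key in seen:
                raise GradingError(
                    f"duplicate grade for {g.vessel.value} ({g.side.value})"
                )
            seen[key] = g.grade
        missing = [k for k in SLOTS if k not in seen]
        if missing:
            names = ", ".join(f"{v.value} ({s.value})" for v, s in missing)
            raise GradingError(f"incomplete grading sheet; missing slots: {names}")
        extra = set(seen) - set(SLOTS)
        if extra:
            names = ", ".join(f"{v.value} ({s.value})" for v, s in sorted(extra))
            raise GradingError(f"unknown slots on sheet: {names}")

    def grade_of(self, vessel: Vessel, side: Side) -> int:
        for g in self.grades:
            if g.vessel is vessel and g.side is side:
                return g.grade
        raise KeyError((vessel, side))

    def as_dict(self) -> dict[tuple[Vessel, Side], int]:
        return {(g.vessel, g.side): g.grade for g in self.grades}

    @classmethod
    def from_mapping(
        cls,
        grades: Mapping[tuple[Vessel | str, Side | str], int],
        pial: PialCounts,
    ) -> "PatientVasculature":
        entries = tuple(
            VesselGrade(Vessel(v), Side(s), g) for (v, s), g in grades.items()
        )
        return cls(entries, pial)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Additive decomposition of the whole-brain collateral score.

    ``whole_brain_score`` is exactly the sum of: the side-summed VA, Pcom
    and ICA values, the midline BAS and Acom grades, the weighted ACA, MCA
    and PCA territory scores, the assessability points and both pial scores.
    """

    side_sums: dict[str, int] = field(repr=False)
    aca: int = 0
    mca: int = 0
    pca: int = 0
    ica: int = 0
    assessability_points: int = 0
    pial_cortical: int = 0
    pial_cerebellar: int = 0
    whole_brain_score: int = 0
    pial_only_score: int = 0

    @property
    def components(self) -> dict[str, int]:
        """Named summands of ``whole_brain_score``."""
        return {
            "VA": self.side_sums["VA"],
            "BAS": self.side_sums["BAS"],
            "Pcom": self.side_sums["Pcom"],
            "ICA": self.ica,
            "Acom": self.side_sums["Acom"],
            "ACA": self.aca,
            "MCA": self.mca,
            "PCA": self.pca,
            "assessability": self.assessability_points,
            "pial_cortical": self.pial_cortical,
            "pial_cerebellar": self.pial_cerebellar,
        }


def side_sum(left_grade: int, right_grade: int) -> int:
    """Add the left and right grade of a paired vessel into one value.

    Midline vessels (BAS, Acom) carry a single grade and never pass through
    this function; their grade enters the score unchanged.
    """
    return left_grade + right_grade


def weighted_segment_score(
    territory: str, segments: Mapping[str | Vessel, int]
) -> int:
    """Proximal-weighted territory score from side-summed segment values.

    ``ACA = 2*A1 + A2``; ``MCA = 4*M1 + 2*M2 + M3``; ``PCA = 4*P1 + 2*P2 + P3``.
    """
    territory = str(territory).upper()
    if territory not in SEGMENT_WEIGHTS:
        raise GradingError(
            f"unknown weighted territory {territory!r}; expected one of "
            f"{sorted(SEGMENT_WEIGHTS)}"
        )
    weights = SEGMENT_WEIGHTS[territory]
    normalized = {Vessel(k): v for k, v in segments.items()}
    missing = [seg.value for seg in weights if seg not in normalized]
    if missing:
        raise GradingError(
            f"{territory}: missing segment value(s) for {', '.join(missing)}"
        )
    return sum(w * normalized[seg] for seg, w in weights.items())


def pial_scores(pial: PialCounts) -> tuple[int, int]:
    """Map pial artery counts to the (cortical, cerebellar) 0-2 scores.

    Cortical: 0 for 0-8 visible arteries, 1 for 9-11, 2 above 11.
    Cerebellar: 0 for none visible (or not assessable), 1 for fewer than
    three, 2 for more than two.
    """
    if not isinstance(pial, PialCounts):
        pial = PialCounts(*pial)
    c = pial.cortical_count
    cortical = 0 if c <= 8 else (1 if c <= 11 else 2)
    b = pial.cerebellar_count
    cerebellar = 0 if b == 0 else (1 if b < 3 else 2)
    return cortical, cerebellar


def whole_brain_score(v: PatientVasculature) -> ScoreBreakdown:
    """Aggregate a complete grading sheet into the whole-brain score.

    All components enter an unweighted sum (beyond the proximal segment
    weights): side-summed single vessels, midline grades, weighted ACA/MCA/
    PCA territories, one point per assessable accessory vessel and side,
    and the two pial scores.
    """
    g = v.as_dict()

    def ss(vessel: Vessel) -> int:
        return side_sum(g[(vessel, Side.LEFT)], g[(vessel, Side.RIGHT)])

    side_sums = {
        "VA": ss(Vessel.VA),
        "Pcom": ss(Vessel.PCOM),
        "BAS": g[(Vessel.BAS, Side.MIDLINE)],
        "Acom": g[(Vessel.ACOM, Side.MIDLINE)],
    }
    ica = ss(Vessel.ICA)
    aca = weighted_segment_score("ACA", {s: ss(s) for s in SEGMENT_WEIGHTS["ACA"]})
    mca = weighted_segment_score("MCA", {s: ss(s) for s in SEGMENT_WEIGHTS["MCA"]})
    pca = weighted_segment_score("PCA", {s: ss(s) for s in SEGMENT_WEIGHTS["PCA"]})
    assessability = sum(ss(vessel) for vessel in ASSESSABILITY)
    cortical, cerebellar = pial_scores(v.pial)

    total = (
        side_sums["VA"]
        + side_sums["BAS"]
        + side_sums["Pcom"]
        + ica
        + side_sums["Acom"]
        + aca
        + mca
        + pca
        + assessability
        + cortical
        + cerebellar
    )
    return ScoreBreakdown(
        side_sums=side_sums,
        aca=aca,
        mca=mca,
        pca=pca,
        ica=ica,
        assessability_points=assessability,
        pial_cortical=cortical,
        pial_cerebellar=cerebellar,
        whole_brain_score=total,
        pial_only_score=cortical + cerebellar,
    )


def pial_only_score(v: PatientVasculature) -> int:
    """Pial collateral score alone: cortical + cerebellar, range 0-4."""
    cortical, cerebellar = pial_scores(v.pial)
    return cortical + cerebellar


def all_normal_sheet(
    cortical_count: int = 12, cerebellar_count: int = 3
) -> PatientVasculature:
    """Sheet with every vessel normal/assessable — the score ceiling (56)."""
    grades = tuple(
        VesselGrade(v, s, 1) for v, s in SLOTS
    )
    return PatientVasculature(grades, PialCounts(cortical_count, cerebellar_count))


def sheet_from_codes(
    codes: Iterable[int], pial: PialCounts
) -> PatientVasculature:
    """Build a sheet from grade codes in canonical ``SLOTS`` order."""
    codes = tuple(codes)
    if len(codes) != len(SLOTS):
        raise GradingError(
            f"expected {len(SLOTS)} grade codes in slot order, got {len(codes)}"
        )
    grades = tuple(
        VesselGrade(v, s, int(c)) for (v, s), c in zip(SLOTS, codes)
    )
    return PatientVasculature(grades, pial)
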