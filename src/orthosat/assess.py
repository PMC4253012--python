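"""Interspecies ortholog assessment: range classes, ROS, and retention criteria.

For each marker the chimpanzee and human observed PCR-fragment-length ranges
are compared (disjoint / identical / one subsumed / partial overlap with a
shift direction), and the two reference (in-silico) fragment lengths are
placed relative to the intersection and union of the ranges.  A marker is
retained as an ortholog when

  (i)   both reference lengths lie within the intersection of the ranges, or
  (ii)  a reference length falls outside its own species' range but within
        the union of the two ranges, or
  (iii) a reference length falls outside the union, the range overlap score
        (ROS) of the two ranges is at least the threshold, and the offending
        length is no more than ``slack`` bp outside the union.

ROS is the intersection-over-union of the two closed bp intervals, counting
integer lengths inclusively (0 when disjoint, 1 when identical).  The default
threshold 0.289 is the data-driven value of the original panel (the lowest
ROS among markers passing criterion i); :func:`derive_ros_threshold`
recomputes it for any panel.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .types import LengthRange

DEFAULT_ROS_THRESHOLD = 0.289
DEFAULT_SLACK_BP = 6

RANGE_DISJOINT = "disjoint"
RANGE_IDENTICAL = "identical"
RANGE_CHIMP_SUBSUMED = "chimp_subsumed"
RANGE_HUMAN_SUBSUMED = "human_subsumed"
RANGE_PARTIAL_CHIMP_LOWER = "partial_chimp_lower"
RANGE_PARTIAL_CHIMP_HIGHER = "partial_chimp_higher"


@dataclass(frozen=True)
class OrthologAssessment:
    marker: str
    range_class: str
    criterion: str            # 'i', 'ii', 'iii', or 'fail'
    ros: Optional[float]      # present iff criterion iii was evaluated
    retained: bool
    reason: str = ""

    def __post_init__(self):
        if self.retained and self.criterion not in ("i", "ii", "iii"):
            raise ValueError("retained markers must pass a criterion")


def classify_ranges(chimp: LengthRange, human: LengthRange) -> str:
    """Classify the relationship of the two species' observed length ranges."""
    if chimp.hi < human.lo or human.hi < chimp.lo:
        return RANGE_DISJOINT
    if chimp.lo == human.lo and chimp.hi == human.hi:
        return RANGE_IDENTICAL
    if human.lo <= chimp.lo and chimp.hi <= human.hi:
        return RANGE_CHIMP_SUBSUMED
    if chimp.lo <= human.lo and human.hi <= chimp.hi:
        return RANGE_HUMAN_SUBSUMED
    if chimp.lo < human.lo:
        return RANGE_PARTIAL_CHIMP_LOWER
    return RANGE_PARTIAL_CHIMP_HIGHER


def range_overlap_score(r1: LengthRange, r2: LengthRange) -> float:
    """Intersection-over-union of two closed bp intervals, counted inclusively."""
    inter = min(r1.hi, r2.hi) - max(r1.lo, r2.lo) + 1
    if inter <= 0:
        return 0.0
    union = r1.width + r2.width - inter
    return inter / union


def assess_lengths(marker: str, x_c: int, x_h: int,
                   chimp: LengthRange, human: LengthRange,
                   ros_threshold: float = DEFAULT_ROS_THRESHOLD,
                   slack: int = DEFAULT_SLACK_BP) -> OrthologAssessment:
    """Evaluate retention criteria (i), (ii), (iii) in order for one marker."""
    range_class = classify_ranges(chimp, human)
    if range_class == RANGE_DISJOINT:
        return OrthologAssessment(marker, range_class, "fail", None, False,
                                  "disjoint ranges: possible regression/non-ortholog")

    inter_lo, inter_hi = max(chimp.lo, human.lo), min(chimp.hi, human.hi)
    union_lo, union_hi = min(chimp.lo, human.lo), max(chimp.hi, human.hi)

    if inter_lo <= x_c <= inter_hi and inter_lo <= x_h <= inter_hi:
        return OrthologAssessment(marker, range_class, "i", None, True,
                                  "both reference lengths within the range intersection")

    in_union_c = union_lo <= x_c <= union_hi
    in_union_h = union_lo <= x_h <= union_hi
    if in_union_c and in_union_h:
        return OrthologAssessment(marker, range_class, "ii", None, True,
                                  "reference length(s) outside own range but within the union")

    ros = range_overlap_score(chimp, human)
    offenders = []
    if not in_union_c:
        offenders.append(max(union_lo - x_c, x_c - union_hi))
    if not in_union_h:
        offenders.append(max(union_lo - x_h, x_h - union_hi))
    within_slack = all(d <= slack for d in offenders)
    if ros >= ros_threshold and within_slack:
        return OrthologAssessment(marker, range_class, "iii", ros, True,
                                  f"ROS {ros:.3f} >= {ros_threshold} and offending length "
                                  f"within {slack} bp of the union")
    return OrthologAssessment(marker, range_class, "fail", ros, False,
                              f"reference length outside the union (ROS {ros:.3f})")


def derive_ros_threshold(assessments: list[OrthologAssessment],
                         ranges: dict[str, tuple[LengthRange, LengthRange]]) -> float:
    """Minimum ROS among markers whose reference lengths both lie in the intersection.

    ``ranges`` maps marker -> (chimp range, human range); the ROS of every
    criterion-i marker is computed from it.
    """
    values = [range_overlap_score(*ranges[a.marker])
              for a in assessments if a.criterion == "i"]
    if not values:
        raise ValueError("no criterion-i markers: threshold cannot be derived")
    return min(values)
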