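"""Grade assignment from the RDHP and RLDS indexes.

Three appearance grades are defined by interval bands on each index
(defaults below).  When the two indexes disagree — including the case of
an RDHP above every band — the stalk index RLDS prevails: stalk
slenderness is the commercially decisive trait for this mushroom.

Default bands::

    grade    RDHP           RLDS
    1        [1.5, 2.5)     [0,   1.5)
    2        [1.0, 1.5)     [1.5, 2.5)
    3        [0,   1.0)     [2.5, inf)

Bands are half-open ``[lo, hi)`` so boundary ownership is deterministic:
a value on a shared bound belongs to the band it opens.

Broken specimens (missing or fragmented cap/stalk) bypass grading
entirely and are flagged ``BROKEN``; on the sorting line they ride the
belt to the terminal collection box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .errors import InvalidCriteriaError
from .mask import CAP, STALK, LabelMask
from .morphometry import MushroomMeasurement

_GRADES = (1, 2, 3)


class Grade(Enum):
    FIRST = 1
    SECOND = 2
    THIRD = 3
    BROKEN = "BROKEN"

    def __str__(self) -> str:
        return str(self.value)


#: Band layout: grade -> (lo, hi), half-open [lo, hi).
Bands = dict[int, tuple[float, float]]

DEFAULT_RDHP_BANDS: Bands = {1: (1.5, 2.5), 2: (1.0, 1.5), 3: (0.0, 1.0)}
DEFAULT_RLDS_BANDS: Bands = {1: (0.0, 1.5), 2: (1.5, 2.5), 3: (2.5, math.inf)}


def _validate_bands(bands: Bands, name: str, require_cover: bool) -> None:
    if set(bands) != set(_GRADES):
        raise InvalidCriteriaError(f"{name}: bands must be defined for grades 1, 2, 3")
    intervals = sorted(bands.values())
    for lo, hi in intervals:
        if not lo < hi:
            raise InvalidCriteriaError(f"{name}: empty interval [{lo}, {hi})")
    if intervals[0][0] != 0.0:
        raise InvalidCriteriaError(f"{name}: bands must start at 0")
    for (_, hi_prev), (lo_next, _) in zip(intervals, intervals[1:]):
        if hi_prev > lo_next:
            raise InvalidCriteriaError(f"{name}: bands overlap at {lo_next}")
        if hi_prev < lo_next:
            raise InvalidCriteriaError(f"{name}: gap between {hi_prev} and {lo_next}")
    if require_cover and not math.isinf(intervals[-1][1]):
        raise InvalidCriteriaError(f"{name}: bands must cover (0, inf)")


@dataclass(frozen=True)
class GradeCriteria:
    """Per-grade RDHP and RLDS interval bands.

    RLDS bands must tile ``(0, inf)`` — every specimen needs an RLDS grade
    because RLDS settles conflicts.  RDHP bands may stop short (the
    default top band ends at 2.5); values beyond fall to ``rdhp_grade =
    None`` and the RLDS decides.
    """

    rdhp_bands: Bands
    rlds_bands: Bands

    def __post_init__(self) -> None:
        _validate_bands(self.rdhp_bands, "RDHP", require_cover=False)
        _validate_bands(self.rlds_bands, "RLDS", require_cover=True)

    @classmethod
    def default(cls) -> "GradeCriteria":
        return cls(rdhp_bands=dict(DEFAULT_RDHP_BANDS), rlds_bands=dict(DEFAULT_RLDS_BANDS))

    def to_dict(self) -> dict:
        """Serializable form (inf encoded as the string '.inf'-compatible float)."""
        return {
            "rdhp": {g: [lo, hi] for g, (lo, hi) in sorted(self.rdhp_bands.items())},
            "rlds": {g: [lo, hi] for g, (lo, hi) in sorted(self.rlds_bands.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GradeCriteria":
        def parse(bands: dict) -> Bands:
            return {int(g): (float(lo), float(hi)) for g, (lo, hi) in bands.items()}

        return cls(rdhp_bands=parse(d["rdhp"]), rlds_bands=parse(d["rlds"]))


def classify_index(value: float, bands: Bands) -> int | None:
    """Grade whose half-open band contains ``value``, or ``None`` if no band does."""
    if not value > 0:
        raise ValueError(f"index value must be positive, got {value}")
    for grade, (lo, hi) in bands.items():
        if lo <= value < hi:
            return grade
    return None


@dataclass(frozen=True)
class GradeResult:
    """Outcome of grading one specimen."""

    grade: Grade
    rdhp_grade: int | None
    rlds_grade: int | None
    conflict: bool
    measurement: MushroomMeasurement | None
    reason: str = ""

    @property
    def is_broken(self) -> bool:
        return self.grade is Grade.BROKEN


def assign_grade(m: MushroomMeasurement, criteria: GradeCriteria | None = None) -> GradeResult:
    """Grade a measured specimen; on index disagreement the RLDS prevails."""
    criteria = criteria or GradeCriteria.default()
    rdhp_grade = classify_index(m.RDHP, criteria.rdhp_bands)
    rlds_grade = classify_index(m.RLDS, criteria.rlds_bands)
    assert rlds_grade is not None  # RLDS bands tile (0, inf) by construction
    conflict = rdhp_grade != rlds_grade
    return GradeResult(
        grade=Grade(rlds_grade),
        rdhp_grade=rdhp_grade,
        rlds_grade=rlds_grade,
        conflict=conflict,
        measurement=m,
    )


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def detect_broken(mask: LabelMask, min_fragment_fraction: float = 0.10) -> tuple[bool, str]:
    """Decide whether a specimen is broken, with the reason.

    A specimen is broken when the cap class is absent, the stalk class is
    absent, or either class splits into more than one connected component
    with at least two fragments each holding ``min_fragment_fraction`` of
    that class's pixels (smaller satellites are segmentation speckle, not
    breakage).
    """
    for class_id, part in ((CAP, "cap"), (STALK, "stalk")):
        binary = mask.binary(class_id)
        total = int(np.count_nonzero(binary))
        if total == 0:
            return True, f"{part} absent"
        labeled, n_comp = ndimage.label(binary, structure=_EIGHT_CONN)
        if n_comp > 1:
            sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n_comp + 1))
            big = int(np.count_nonzero(sizes / total >= min_fragment_fraction))
            if big > 1:
                return True, f"{part} fragmented ({big} major fragments)"
    return False, ""
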