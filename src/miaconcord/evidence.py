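"""Evidence-strength grading and the diagnostic-certainty lookup matrix.

Each autopsy arm grades its findings on two ordinal 0-4 scales — one for the
severity of the pathological findings, one for the distribution and type of
the microorganisms identified — plus a Y/N flag recording whether the
organisms found are concordant with the histological lesions.  The certainty
of the resulting cause-of-death diagnosis (no diagnosis / low / moderate /
high / very high) is then read off a fixed lookup matrix over the 45 valid
(pathology, microbiology, flag) combinations.  The matrix is stored as
explicit data, cell for cell: it is an expert consensus table, not the
product of a formula.

One adjustment rule applies before lookup: histological identification of a
microorganism associated with inflammatory changes raises the pathology
score by one (capped at 4).
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "CertaintyLevel",
    "EvidenceGrade",
    "EvidenceError",
    "adjust_pathology",
    "certainty",
    "certainty_matrix_rows",
    "VALID_GRADE_CELLS",
]


class EvidenceError(ValueError):
    """Invalid evidence grade or an inapplicable/missing concordance flag."""


@functools.total_ordering
class CertaintyLevel(enum.Enum):
    """Certainty of a cause-of-death diagnosis (total order, low to high)."""

    NO_DIAGNOSIS = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3
    VERY_HIGH = 4

    def __lt__(self, other):
        if not isinstance(other, CertaintyLevel):
            return NotImplemented
        return self.value < other.value

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "CertaintyLevel":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise EvidenceError(f"unknown certainty level {label!r}") from None


@dataclass(frozen=True)
class EvidenceGrade:
    """Per-arm evidence strengths.

    Parameters
    ----------
    pathology, microbiology : int
        Ordinal 0-4 evidence levels (0 = none ... 4 = strong).
    micro_concordant : bool, optional
        Whether the microorganisms identified are in concordance with the
        histological lesions observed.  Not applicable — and required to be
        ``None`` — when either score is 0.
    histo_organism_with_inflammation : bool
        Histological identification of a microorganism associated with
        inflammatory changes; triggers the +1 pathology adjustment.
    """

    pathology: int
    microbiology: int
    micro_concordant: Optional[bool] = None
    histo_organism_with_inflammation: bool = False

    def __post_init__(self):
        for name in ("pathology", "microbiology"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 4:
                raise EvidenceError(f"{name} level must be an integer in 0..4, got {v!r}")
        if self.micro_concordant is not None and (
                self.pathology == 0 or self.microbiology == 0):
            raise EvidenceError(
                "micro_concordant is not applicable when either evidence level is 0")


def adjust_pathology(grade: EvidenceGrade) -> EvidenceGrade:
    """Apply the +1 pathology adjustment for histologically seen organisms.

    If the grade records a microorganism identified histologically in
    association with inflammatory changes, the pathology score is increased
    by one (never beyond 4) and the flag is cleared, so the adjustment is
    applied exactly once.
    """
    if not grade.histo_organism_with_inflammation:
        return grade
    new_path = min(grade.pathology + 1, 4)
    conc = grade.micro_concordant
    if conc is None and new_path >= 1 and grade.microbiology >= 1:
        # flag was structurally absent at pathology 0; it stays unknown and
        # certainty() will demand it explicitly
        conc = None
    return replace(grade, pathology=new_path,
                   micro_concordant=conc,
                   histo_organism_with_inflammation=False)


_ND = CertaintyLevel.NO_DIAGNOSIS
_L = CertaintyLevel.LOW
_M = CertaintyLevel.MODERATE
_H = CertaintyLevel.HIGH
_VH = CertaintyLevel.VERY_HIGH

# Certainty matrix, row = pathology level, column = microbiology level.
# Each cell for microbiology >= 1 is an (N, Y) pair on the organism/lesion
# concordance flag; microbiology 0 has a single value.  At pathology 0 the
# flag is not applicable and N = Y.
_MATRIX: dict[int, tuple] = {
    0: (_ND, (_ND, _ND), (_ND, _ND), (_L, _L), (_M, _M)),
    1: (_L, (_L, _L), (_L, _L), (_M, _M), (_M, _M)),
    2: (_L, (_L, _L), (_L, _M), (_M, _M), (_M, _H)),
    3: (_M, (_M, _M), (_M, _H), (_H, _H), (_H, _VH)),
    4: (_H, (_H, _H), (_H, _H), (_H, _VH), (_VH, _VH)),
}


def certainty(grade: EvidenceGrade) -> CertaintyLevel:
    """Look up the diagnostic certainty for a (post-adjustment) evidence grade.

    Raises
    ------
    EvidenceError
        If both levels are >= 1 but the organism/lesion concordance flag is
        absent, or the adjustment flag is still pending.
    """
    if grade.histo_organism_with_inflammation:
        raise EvidenceError(
            "apply adjust_pathology() before looking up certainty")
    p, m = grade.pathology, grade.microbiology
    cell = _MATRIX[p][m]
    if m == 0:
        return cell
    if p == 0:
        return cell[0]  # N == Y, flag not applicable
    if grade.micro_concordant is None:
        raise EvidenceError(
            f"micro_concordant flag required for pathology {p}, microbiology {m}")
    return cell[1] if grade.micro_concordant else cell[0]


def _valid_cells() -> tuple[tuple[int, int, Optional[bool]], ...]:
    cells = []
    for p in range(5):
        for m in range(5):
            if p == 0 or m == 0:
                cells.append((p, m, None))
            else:
                cells.append((p, m, False))
                cells.append((p, m, True))
    return tuple(cells)


#: All 45 valid (pathology, microbiology, micro_concordant) combinations.
VALID_GRADE_CELLS = _valid_cells()


def certainty_matrix_rows() -> list[dict]:
    """The full certainty matrix as flat rows, for audit/export.

    One row per valid cell: pathology, microbiology, micro_concordant
    ("Y"/"N"/"" when not applicable) and the certainty label.
    """
    rows = []
    for p, m, conc in VALID_GRADE_CELLS:
        level = certainty(EvidenceGrade(p, m, conc))
        rows.append({
            "pathology": p,
            "microbiology": m,
            "micro_concordant": "" if conc is None else ("Y" if conc else "N"),
            "certainty": level.label,
        })
    return rows
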