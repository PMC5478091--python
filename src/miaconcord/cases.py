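"""Case-level data model and construction of the analysis tables.

A *paired case* is one death examined by both methods: the minimally
invasive autopsy (MIA, needle-biopsy sampling) and the complete diagnostic
autopsy (CDA, the gold standard).  Each arm delivers a verdict: a main
cause-of-death ICD-10 code (or a nonconclusive sentinel), an optional chain
of up to four conditions, underlying and other significant conditions, an
evidence grade, and the diagnostic certainty derived from it.

This module reads and writes the wide one-row-per-case CSV, selects the main
cause of death (the direct cause, never the underlying disease), and builds
the two analysis tables everything downstream consumes: the K x K
category confusion matrix (MIA rows vs CDA columns) and the per-category
tabulation of ICD-10 coincidence levels among category-concordant cases.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evidence import CertaintyLevel, EvidenceError, EvidenceGrade, adjust_pathology, certainty
from .icd10 import (
    BlockTable,
    CategoryMap,
    CoincidenceLevel,
    DiseaseCategory,
    ICD10Code,
    categorize,
    coincidence,
    default_block_table,
    default_category_map,
    locate,
    parse_code,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NONCONCLUSIVE",
    "CoDVerdict",
    "PairedCase",
    "ConfusionMatrix",
    "CoincidenceTable",
    "CaseValidationError",
    "select_main_cod",
    "read_cases",
    "write_cases",
    "build_confusion_matrix",
    "coincidence_table",
    "example_cases_path",
]


class _Nonconclusive:
    """Sentinel for a verdict with no attributable cause of death."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NONCONCLUSIVE"


NONCONCLUSIVE = _Nonconclusive()


class CaseValidationError(ValueError):
    """One or more case rows failed validation; carries per-row messages."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("case validation failed:\n  " + "\n  ".join(self.messages))


@dataclass(frozen=True)
class CoDVerdict:
    """One arm's cause-of-death verdict.

    ``main_cod`` is the direct cause of death, or :data:`NONCONCLUSIVE` when
    no diagnosis could be reached — which must coincide with a certainty of
    ``NO_DIAGNOSIS``, and only then.
    """

    main_cod: Union[ICD10Code, _Nonconclusive]
    certainty: CertaintyLevel
    grade: EvidenceGrade
    chain: tuple[ICD10Code, ...] = ()
    underlying: tuple[ICD10Code, ...] = ()
    other_significant: tuple[ICD10Code, ...] = ()

    def __post_init__(self):
        if len(self.chain) > 4:
            raise ValueError(f"condition chain has {len(self.chain)} entries; at most 4 allowed")
        nonconclusive = self.main_cod is NONCONCLUSIVE
        no_dx = self.certainty == CertaintyLevel.NO_DIAGNOSIS
        if nonconclusive != no_dx:
            raise ValueError(
                "main_cod must be NONCONCLUSIVE exactly when certainty is no_diagnosis "
                f"(got main_cod={self.main_cod!r}, certainty={self.certainty.label})")

    @property
    def is_nonconclusive(self) -> bool:
        return self.main_cod is NONCONCLUSIVE


@dataclass(frozen=True)
class PairedCase:
    """One death with both the MIA and the CDA verdict."""

    case_id: str
    mia: CoDVerdict
    cda: CoDVerdict
    age_months: Optional[float] = None
    sex: str = "unknown"
    postmortem_interval_hours: Optional[float] = None

    def __post_init__(self):
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"sex must be M, F or unknown, got {self.sex!r}")
        if self.age_months is not None and self.age_months < 0:
            raise ValueError("age_months must be non-negative")
        if (self.postmortem_interval_hours is not None
                and self.postmortem_interval_hours < 0):
            raise ValueError("postmortem_interval_hours must be non-negative")

    def validate_age_range(self) -> None:
        """Strict check: post-neonatal pediatric range (1 month to 15 years)."""
        if self.age_months is None:
            raise CaseValidationError([f"case {self.case_id}: age_months missing"])
        if not 1 <= self.age_months <= 15 * 12:
            raise CaseValidationError(
                [f"case {self.case_id}: age {self.age_months} months outside 1..180"])


def select_main_cod(direct: ICD10Code,
                    underlying: Sequence[ICD10Code] = ()) -> ICD10Code:
    """Select the main cause of death: always the direct cause.

    Underlying conditions (HIV, malnutrition, ...) never displace the direct
    cause — bacterial pneumonia in a malnourished toddler is coded as
    pneumonia, lymphoma in an HIV-infected child as lymphoma.
    """
    if direct is None:
        raise ValueError("direct cause of death is required")
    return direct


# ------------------------------------------------------------------ CSV I/O

_ARM_COLUMNS = ("code", "chain", "underlying", "other",
                "path_level", "micro_level", "micro_concordant", "histo_org_inflam")
_MANDATORY = ["case_id"] + [f"{arm}_{c}" for arm in ("mia", "cda")
                            for c in ("code", "path_level", "micro_level")]


def _parse_bool(value: str, what: str) -> bool:
    v = value.strip().upper()
    if v in ("Y", "YES", "1", "TRUE"):
        return True
    if v in ("N", "NO", "0", "FALSE"):
        return False
    raise ValueError(f"{what}: expected Y/N, got {value!r}")


def _parse_code_list(value: str) -> tuple[ICD10Code, ...]:
    if not value or not value.strip():
        return ()
    return tuple(parse_code(part) for part in value.split(";") if part.strip())


def _read_verdict(row: dict, arm: str, table: BlockTable,
                  strict: bool) -> CoDVerdict:
    def col(name: str) -> str:
        return str(row.get(f"{arm}_{name}", "") or "").strip()

    path_level = int(col("path_level"))
    micro_level = int(col("micro_level"))
    conc_raw = col("micro_concordant")
    conc = None if conc_raw == "" else _parse_bool(conc_raw, f"{arm}_micro_concordant")
    histo_raw = col("histo_org_inflam")
    histo = False if histo_raw == "" else _parse_bool(histo_raw, f"{arm}_histo_org_inflam")
    grade = adjust_pathology(EvidenceGrade(path_level, micro_level, conc, histo))
    level = certainty(grade)

    supplied = col("certainty")
    if supplied:
        expected = CertaintyLevel.from_label(supplied)
        if expected != level:
            msg = (f"{arm}_certainty {supplied!r} disagrees with the grade-derived "
                   f"level {level.label!r}")
            if strict:
                raise ValueError(msg)
            logger.warning("%s", msg)

    code_raw = col("code")
    if code_raw == "":
        main: Union[ICD10Code, _Nonconclusive] = NONCONCLUSIVE
    else:
        main = parse_code(code_raw)
        locate(main, table)  # fail early on codes outside every range
    return CoDVerdict(
        main_cod=main,
        certainty=level,
        grade=grade,
        chain=_parse_code_list(col("chain")),
        underlying=_parse_code_list(col("underlying")),
        other_significant=_parse_code_list(col("other")),
    )


def read_cases(path: Union[str, Path],
               block_table: Optional[BlockTable] = None,
               category_map: Optional[CategoryMap] = None,
               strict: bool = True) -> list[PairedCase]:
    """Read paired cases from a wide, one-row-per-case CSV.

    Mandatory columns: ``case_id`` and, for each arm prefix ``mia_``/``cda_``:
    ``code`` (empty = nonconclusive), ``path_level``, ``micro_level``.
    Optional per-arm columns: ``chain``, ``underlying``, ``other``
    (semicolon-separated code lists), ``micro_concordant`` (Y/N),
    ``histo_org_inflam`` (Y/N), ``certainty`` (cross-checked against the
    level recomputed from the evidence columns).  Optional case columns:
    ``age_months``, ``sex``, ``postmortem_hours``.

    Row-level failures are collected and reported together in a single
    :class:`CaseValidationError`.
    """
    block_table = block_table or default_block_table()
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CaseValidationError([f"{path}: file is empty"]) from None
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise CaseValidationError(
            [f"{path}: missing mandatory columns {missing}"])
    if frame.empty:
        raise CaseValidationError([f"{path}: no case rows"])

    cases: list[PairedCase] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        rowd = row.to_dict()
        case_id = str(rowd.get("case_id", "")).strip() or f"row{idx + 2}"
        try:
            mia = _read_verdict(rowd, "mia", block_table, strict)
            cda = _read_verdict(rowd, "cda", block_table, strict)
            age = rowd.get("age_months", "").strip()
            pmi = rowd.get("postmortem_hours", "").strip()
            case = PairedCase(
                case_id=case_id,
                mia=mia,
                cda=cda,
                age_months=float(age) if age else None,
                sex=rowd.get("sex", "").strip() or "unknown",
                postmortem_interval_hours=float(pmi) if pmi else None,
            )
            if strict and age:
                case.validate_age_range()
            cases.append(case)
        except (ValueError, EvidenceError, KeyError) as exc:
            errors.append(f"case {case_id}: {exc}")
    if errors:
        raise CaseValidationError(errors)
    return cases


def _verdict_columns(v: CoDVerdict) -> dict:
    g = v.grade
    return {
        "code": "" if v.is_nonconclusive else v.main_cod.full,
        "chain": ";".join(c.full for c in v.chain),
        "underlying": ";".join(c.full for c in v.underlying),
        "other": ";".join(c.full for c in v.other_significant),
        "path_level": g.pathology,
        "micro_level": g.microbiology,
        "micro_concordant": "" if g.micro_concordant is None else ("Y" if g.micro_concordant else "N"),
        "histo_org_inflam": "Y" if g.histo_organism_with_inflammation else "N",
        "certainty": v.certainty.label,
    }


def write_cases(cases: Sequence[PairedCase], path: Union[str, Path]) -> None:
    """Write cases to the standard wide CSV (round-trips with read_cases)."""
    rows = []
    for case in cases:
        row = {
            "case_id": case.case_id,
            "age_months": "" if case.age_months is None else case.age_months,
            "sex": case.sex,
            "postmortem_hours": ("" if case.postmortem_interval_hours is None
                                 else case.postmortem_interval_hours),
        }
        for arm, verdict in (("mia", case.mia), ("cda", case.cda)):
            for k, v in _verdict_columns(verdict).items():
                row[f"{arm}_{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def example_cases_path() -> Path:
    """Path of the packaged 54-case example dataset (synthetic per-case codes
    constructed to reproduce the published category and coincidence margins)."""
    from importlib import resources
    ref = resources.files("miaconcord.data") / "example_cases_synthetic.csv"
    with resources.as_file(ref) as p:
        return Path(p)


# ------------------------------------------------------- analysis tables

@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K category cross-tabulation; rows = MIA, columns = CDA."""

    categories: tuple[DiseaseCategory, ...]
    counts: np.ndarray  # shape (K, K), non-negative ints

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.categories)
        if k < 2:
            raise ValueError("confusion matrix needs at least 2 categories")
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        labels = [c.value for c in self.categories]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def _category_of(verdict: CoDVerdict, mapping: CategoryMap,
                 table: BlockTable) -> DiseaseCategory:
    if verdict.is_nonconclusive:
        return DiseaseCategory.NONCONCLUSIVE
    return categorize(verdict.main_cod, mapping, table)


def build_confusion_matrix(cases: Sequence[PairedCase],
                           category_map: Optional[CategoryMap] = None,
                           block_table: Optional[BlockTable] = None,
                           ) -> ConfusionMatrix:
    """Cross-tabulate MIA vs CDA disease categories over the fixed 5-category order."""
    if not cases:
        raise ValueError("no cases supplied")
    category_map = category_map or default_category_map()
    block_table = block_table or default_block_table()
    cats = DiseaseCategory.ordered()
    index = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for case in cases:
        i = index[_category_of(case.mia, category_map, block_table)]
        j = index[_category_of(case.cda, category_map, block_table)]
        counts[i, j] += 1
    return ConfusionMatrix(categories=cats, counts=counts)


@dataclass(frozen=True)
class CoincidenceTable:
    """Coincidence-level counts among category-concordant cases.

    ``per_category`` maps each disease category to a Counter over
    :class:`CoincidenceLevel`; ``overall`` is their sum.  The denominator
    ``n`` equals the confusion-matrix diagonal (category-discordant cases are
    excluded).  Concordant-nonconclusive pairs carry no codes to compare and
    are excluded as well (counted in ``n_nonconclusive_pairs``).
    """

    per_category: dict[DiseaseCategory, Counter]
    n_nonconclusive_pairs: int = 0

    @property
    def overall(self) -> Counter:
        total: Counter = Counter()
        for counter in self.per_category.values():
            total.update(counter)
        return total

    @property
    def n(self) -> int:
        return sum(self.overall.values()) + self.n_nonconclusive_pairs

    def merged_counts(self, counter: Optional[Counter] = None) -> dict[str, int]:
        """Counts with perfect and almost-perfect reported merged and separately."""
        c = self.overall if counter is None else counter
        return {
            "perfect": c[CoincidenceLevel.PERFECT],
            "almost_perfect": c[CoincidenceLevel.ALMOST_PERFECT],
            "perfect_or_almost_perfect": c[CoincidenceLevel.PERFECT]
                                         + c[CoincidenceLevel.ALMOST_PERFECT],
            "moderate": c[CoincidenceLevel.MODERATE],
            "low": c[CoincidenceLevel.LOW],
            "none": c[CoincidenceLevel.NONE],
        }


def coincidence_table(cases: Sequence[PairedCase],
                      category_map: Optional[CategoryMap] = None,
                      block_table: Optional[BlockTable] = None,
                      ) -> CoincidenceTable:
    """Tabulate ICD-10 coincidence levels for category-concordant cases only."""
    if not cases:
        raise ValueError("no cases supplied")
    category_map = category_map or default_category_map()
    block_table = block_table or default_block_table()
    per_category: dict[DiseaseCategory, Counter] = {
        c: Counter() for c in DiseaseCategory.ordered()}
    n_ncl = 0
    for case in cases:
        cat_mia = _category_of(case.mia, category_map, block_table)
        cat_cda = _category_of(case.cda, category_map, block_table)
        if cat_mia != cat_cda:
            continue
        if case.mia.is_nonconclusive or case.cda.is_nonconclusive:
            n_ncl += 1
            continue
        level = coincidence(case.mia.main_cod, case.cda.main_cod, block_table)
        per_category[cat_cda][level] += 1
    return CoincidenceTable(per_category=per_category, n_nonconclusive_pairs=n_ncl)
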