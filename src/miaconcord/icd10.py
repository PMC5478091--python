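"""ICD-10 code hierarchy: parsing, chapter/block lookup, and coincidence grading.

The ICD-10 classification nests diagnoses in chapters (e.g. chapter I,
A00-B99), blocks (e.g. A30-A49, "Other bacterial diseases"), three-character
categories (A41) and four-character codes (A41.5).  Two independently coded
diagnoses for the same death can then be compared by how deep in this
hierarchy they agree, from ``perfect`` (identical four-character codes) down
to ``none`` (different chapters).  This module provides the code model, the
packaged WHO chapter/block reference table, the five-level coincidence
classification, and the mapping of codes onto major disease categories.
"""

from __future__ import annotations

import csv
import enum
import functools
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ICD10Code",
    "ICD10ParseError",
    "UnmappedCodeError",
    "Block",
    "Chapter",
    "BlockTable",
    "CoincidenceLevel",
    "DiseaseCategory",
    "CategoryMap",
    "parse_code",
    "locate",
    "coincidence",
    "categorize",
    "default_block_table",
    "default_category_map",
]


class ICD10ParseError(ValueError):
    """Raised when a string cannot be interpreted as a valid ICD-10 code."""


class UnmappedCodeError(KeyError):
    """Raised when a syntactically valid code falls outside every known range."""

    def __init__(self, code: "ICD10Code", context: str = "block table"):
        self.code = code
        super().__init__(f"ICD-10 code {code.raw!r} (category {code.category3}) "
                         f"is not covered by any range in the {context}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


# letter + 2 digits, optional "." separator, optional 1-digit subdivision;
# whitespace is stripped before matching
_CODE_RE = re.compile(r"^([A-Z])(\d{2})\.?(\d)?$")


@dataclass(frozen=True, order=True)
class ICD10Code:
    """A validated ICD-10 code, decomposed into its hierarchical coordinates.

    Ordering and equality use the normalized (category3, subcode) form, so
    ``A41.5`` parsed from ``"a41 . 5"`` and from ``"A415"`` compare equal.
    """

    category3: str
    subcode: Optional[str] = None
    raw: str = field(default="", compare=False)

    @property
    def letter(self) -> str:
        return self.category3[0]

    @property
    def full(self) -> str:
        """Normalized display form, e.g. ``A41.5`` or ``N10``."""
        return self.category3 if self.subcode is None else f"{self.category3}.{self.subcode}"

    def __str__(self) -> str:
        return self.full


def parse_code(text: str) -> ICD10Code:
    """Parse and normalize an ICD-10 code string.

    Accepts upper or lower case and an optional "." (or spaced) separator
    before the fourth character: ``"a41 . 5"`` -> ``A41.5``.  U codes
    (chapter XXII) and dagger/asterisk-suffixed codes are rejected: they do
    not occur in cause-of-death main codes.

    Raises
    ------
    ICD10ParseError
        If the text is empty or does not match letter + two digits +
        optional one-digit subdivision.
    """
    if text is None:
        raise ICD10ParseError("ICD-10 code is missing (None)")
    cleaned = re.sub(r"\s+", "", str(text)).upper()
    if not cleaned:
        raise ICD10ParseError("ICD-10 code is empty")
    m = _CODE_RE.match(cleaned)
    if not m:
        raise ICD10ParseError(f"malformed ICD-10 code: {text!r}")
    letter, digits, sub = m.groups()
    if letter == "U":
        raise ICD10ParseError(f"chapter XXII (U) codes are not supported: {text!r}")
    return ICD10Code(category3=letter + digits, subcode=sub, raw=str(text))


def _as_category3(text: str, what: str) -> str:
    t = text.strip().upper()
    if not re.match(r"^[A-Z]\d{2}$", t):
        raise ValueError(f"{what} {text!r} is not a three-character ICD-10 category")
    return t


@dataclass(frozen=True)
class Block:
    """One ICD-10 block: a closed range of three-character categories."""

    chapter_id: str
    start: str
    end: str
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "start", _as_category3(self.start, "block start"))
        object.__setattr__(self, "end", _as_category3(self.end, "block end"))
        if self.start > self.end:
            raise ValueError(f"block range reversed: {self.start}-{self.end}")

    @property
    def block_id(self) -> str:
        return f"{self.start}-{self.end}"

    def __contains__(self, category3: str) -> bool:
        # uppercase letter + 2 digits sorts correctly as a plain string
        return self.start <= category3 <= self.end


@dataclass(frozen=True)
class Chapter:
    """An ICD-10 chapter: the closed envelope of its blocks' ranges."""

    chapter_id: str
    start: str
    end: str

    def __contains__(self, category3: str) -> bool:
        return self.start <= category3 <= self.end


class BlockTable:
    """The ICD-10 chapter/block reference table.

    Chapters are derived as the envelope of their blocks, in file order.
    Validated on construction: block ranges must not overlap, and chapter
    envelopes must not overlap either (so any category resolves to at most
    one block and one chapter).
    """

    def __init__(self, blocks: Iterable[Block]):
        self.blocks: list[Block] = list(blocks)
        if not self.blocks:
            raise ValueError("block table is empty")
        ordered = sorted(self.blocks, key=lambda b: b.start)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping blocks: {prev.block_id} and {cur.block_id}")
        chapters: dict[str, list[Block]] = {}
        for b in self.blocks:
            chapters.setdefault(b.chapter_id, []).append(b)
        self.chapters: list[Chapter] = [
            Chapter(cid, min(b.start for b in bs), max(b.end for b in bs))
            for cid, bs in chapters.items()
        ]
        ch_sorted = sorted(self.chapters, key=lambda c: c.start)
        for prev, cur in zip(ch_sorted, ch_sorted[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping chapters: {prev.chapter_id} and {cur.chapter_id}")
        self._by_block_id = {b.block_id: b for b in self.blocks}

    def __len__(self) -> int:
        return len(self.blocks)

    def block_of(self, category3: str) -> Optional[Block]:
        for b in self.blocks:
            if category3 in b:
                return b
        return None

    def chapter_of(self, category3: str) -> Optional[Chapter]:
        for c in self.chapters:
            if category3 in c:
                return c
        return None

    def block(self, block_id: str) -> Block:
        return self._by_block_id[block_id]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "BlockTable":
        """Load a tab-delimited table with header chapter/block_start/block_end/block_label."""
        blocks = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"chapter", "block_start", "block_end"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"block table {path} must have columns {sorted(required)}")
            for row in reader:
                blocks.append(Block(
                    chapter_id=row["chapter"].strip(),
                    start=row["block_start"],
                    end=row["block_end"],
                    label=(row.get("block_label") or "").strip(),
                ))
        return cls(blocks)


@functools.lru_cache(maxsize=1)
def default_block_table() -> BlockTable:
    """The packaged WHO ICD-10 (2016) chapter/block ranges (chapters I-XXI)."""
    ref = resources.files("miaconcord.data") / "icd10_blocks.tsv"
    with resources.as_file(ref) as path:
        return BlockTable.from_file(path)


def locate(code: ICD10Code, table: Optional[BlockTable] = None) -> tuple[str, str]:
    """Resolve a code to its ``(chapter_id, block_id)`` coordinates.

    Raises :class:`UnmappedCodeError` when the category falls outside every
    block range (e.g. in a deliberate gap such as A10-A14).
    """
    table = table or default_block_table()
    block = table.block_of(code.category3)
    if block is None:
        raise UnmappedCodeError(code)
    return block.chapter_id, block.block_id


@functools.total_ordering
class CoincidenceLevel(enum.Enum):
    """Depth of agreement of two ICD-10 codes in the hierarchy (total order)."""

    NONE = 0
    LOW = 1
    MODERATE = 2
    ALMOST_PERFECT = 3
    PERFECT = 4

    def __lt__(self, other):
        if not isinstance(other, CoincidenceLevel):
            return NotImplemented
        return self.value < other.value

    @property
    def label(self) -> str:
        return self.name.lower()


def coincidence(a: ICD10Code, b: ICD10Code,
                table: Optional[BlockTable] = None) -> CoincidenceLevel:
    """Grade how deeply two codes agree in the ICD-10 hierarchy.

    * ``PERFECT`` — identical full codes (including any fourth character);
    * ``ALMOST_PERFECT`` — same three-character category, different full code;
    * ``MODERATE`` — same block, different category;
    * ``LOW`` — same chapter, different block;
    * ``NONE`` — different chapters.

    Symmetric, and ``coincidence(a, a)`` is always ``PERFECT``.
    """
    table = table or default_block_table()
    ch_a, bl_a = locate(a, table)
    ch_b, bl_b = locate(b, table)
    if a.category3 == b.category3:
        if a.subcode == b.subcode:
            return CoincidenceLevel.PERFECT
        return CoincidenceLevel.ALMOST_PERFECT
    if bl_a == bl_b:
        return CoincidenceLevel.MODERATE
    if ch_a == ch_b:
        return CoincidenceLevel.LOW
    return CoincidenceLevel.NONE


class DiseaseCategory(enum.Enum):
    """The five major cause-of-death categories used for concordance analysis."""

    INFECTIOUS = "infectious_diseases"
    MALIGNANT = "malignant_tumors"
    CONGENITAL = "congenital_malformations"
    OTHER = "other_diseases"
    NONCONCLUSIVE = "nonconclusive"

    @classmethod
    def ordered(cls) -> tuple["DiseaseCategory", ...]:
        """Fixed analysis order (rows/columns of the confusion matrix)."""
        return (cls.INFECTIOUS, cls.MALIGNANT, cls.CONGENITAL, cls.OTHER,
                cls.NONCONCLUSIVE)

    @classmethod
    def from_label(cls, label: str) -> "DiseaseCategory":
        try:
            return cls(label.strip().lower())
        except ValueError:
            raise ValueError(f"unknown disease category {label!r}; expected one of "
                             f"{[c.value for c in cls]}") from None


_RANGE_KEY_RE = re.compile(r"^([A-Z]\d{2})-([A-Z]\d{2})$")
_CAT3_KEY_RE = re.compile(r"^[A-Z]\d{2}$")


class CategoryMap:
    """Mapping from ICD-10 coordinates to the five disease categories.

    Keys may be chapter ids (Roman numerals), category ranges (block ids such
    as ``A30-A49`` or broader spans such as ``C00-C97``), or three-character
    categories.  Resolution order for a code: exact category entry, then the
    narrowest matching range entry, then the chapter entry, then the fallback
    category.  With ``strict=True`` a code matching nothing (not even a
    chapter) raises; otherwise it falls back with a warning.
    """

    def __init__(self, entries: Mapping[str, Union[str, DiseaseCategory]],
                 fallback: Union[str, DiseaseCategory] = DiseaseCategory.OTHER,
                 strict: bool = False):
        self.strict = strict
        self.fallback = (fallback if isinstance(fallback, DiseaseCategory)
                         else DiseaseCategory.from_label(fallback))
        self._by_cat3: dict[str, DiseaseCategory] = {}
        self._ranges: list[tuple[str, str, DiseaseCategory]] = []
        self._by_chapter: dict[str, DiseaseCategory] = {}
        for key, value in entries.items():
            cat = (value if isinstance(value, DiseaseCategory)
                   else DiseaseCategory.from_label(str(value)))
            k = str(key).strip().upper()
            m = _RANGE_KEY_RE.match(k)
            if m:
                lo, hi = m.groups()
                if lo > hi:
                    raise ValueError(f"category range reversed in map key {key!r}")
                self._ranges.append((lo, hi, cat))
            elif _CAT3_KEY_RE.match(k):
                self._by_cat3[k] = cat
            elif re.match(r"^[IVX]+$", k):
                self._by_chapter[k] = cat
            else:
                raise ValueError(
                    f"category-map key {key!r} is neither a chapter id, a "
                    f"category range, nor a three-character category")
        # narrowest range first so the first match wins
        self._ranges.sort(key=lambda r: (ord(r[1][0]) * 100 + int(r[1][1:])) -
                                        (ord(r[0][0]) * 100 + int(r[0][1:])))

    @classmethod
    def from_file(cls, path: Union[str, Path], strict: bool = False) -> "CategoryMap":
        """Load a YAML file with keys ``categories`` (mapping) and ``fallback``."""
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "categories" not in doc:
            raise ValueError(f"category map {path} must contain a 'categories' mapping")
        return cls(doc["categories"],
                   fallback=doc.get("fallback", DiseaseCategory.OTHER),
                   strict=strict)


@functools.lru_cache(maxsize=1)
def default_category_map() -> CategoryMap:
    """The packaged default disease-category mapping."""
    ref = resources.files("miaconcord.data") / "category_map.yaml"
    with resources.as_file(ref) as path:
        return CategoryMap.from_file(path)


def categorize(code: ICD10Code, mapping: Optional[CategoryMap] = None,
               table: Optional[BlockTable] = None) -> DiseaseCategory:
    """Assign a code to one of the five major disease categories."""
    mapping = mapping or default_category_map()
    table = table or default_block_table()
    cat3 = code.category3
    if cat3 in mapping._by_cat3:
        return mapping._by_cat3[cat3]
    for lo, hi, cat in mapping._ranges:
        if lo <= cat3 <= hi:
            return cat
    chapter = table.chapter_of(cat3)
    if chapter is not None and chapter.chapter_id in mapping._by_chapter:
        return mapping._by_chapter[chapter.chapter_id]
    if chapter is None and mapping.strict:
        raise UnmappedCodeError(code, context="category map / block table")
    if chapter is None:
        logger.warning("code %s not covered by any chapter; using fallback %s",
                       code.full, mapping.fallback.value)
    return mapping.fallback
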