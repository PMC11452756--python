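"""ICD-10-CM code domain model.

An ICD-10-CM code is a 3-7 character alphanumeric string whose leading
letter+digits category places it in one of 21 classification chapters
(I-XXI).  The first three characters designate the diagnostic category, the
next three the etiology, and an optional seventh character an extension.
This module validates codes structurally, resolves chapters from a
block-range table, and models labeled code sets (one principal/main code
plus secondary/other codes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "CodeValidationError",
    "IcdCode",
    "CodeSet",
    "ChapterTable",
    "default_chapter_table",
    "parse_code",
    "chapter_of",
    "block_letter_of",
]


class CodeValidationError(ValueError):
    """Raised when a raw string is not a structurally valid ICD-10-CM code."""


_CODE_RE = re.compile(r"^[A-Z][A-Z0-9]{2,6}$")


@dataclass(frozen=True)
class ChapterTable:
    """Ordered, non-overlapping (block_start, block_end, chapter) ranges.

    Ranges compare 3-character categories lexicographically, which is exact
    for the letter+digit layout of ICD-10-CM categories.
    """

    ranges: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        prev_end = None
        for start, end, _chapter in self.ranges:
            if not (len(start) == len(end) == 3) or start > end:
                raise ValueError(f"malformed block range {start}-{end}")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"overlapping/unsorted range {start}-{end}")
            prev_end = end

    @classmethod
    def from_tsv(cls, path) -> "ChapterTable":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["block_start", "block_end", "chapter"]:
                raise ValueError(f"unexpected chapter table header: {header}")
            for line in fh:
                line = line.strip()
                if line:
                    start, end, chapter = line.split("\t")
                    rows.append((start.upper(), end.upper(), chapter))
        return cls(tuple(rows))

    def chapter_of_category(self, category: str) -> Optional[str]:
        """Chapter containing the 3-character category, or None."""
        for start, end, chapter in self.ranges:
            if start <= category <= end:
                return chapter
        return None


_DEFAULT_TABLE: Optional[ChapterTable] = None


def default_chapter_table() -> ChapterTable:
    """The packaged 2014 ICD-10-CM chapter/block table (21 chapters)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        path = resources.files("autoicd.data") / "chapter_blocks.tsv"
        _DEFAULT_TABLE = ChapterTable.from_tsv(path)
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class IcdCode:
    """A validated ICD-10-CM code with its resolved chapter."""

    code: str
    chapter: str

    @property
    def block_letter(self) -> str:
        return self.code[0]

    @property
    def category(self) -> str:
        return self.code[:3]

    def __str__(self) -> str:
        return self.code


def parse_code(
    raw: str,
    table: Optional[ChapterTable] = None,
    dictionary: Optional[Iterable[str]] = None,
) -> IcdCode:
    """Validate and normalize a raw code string.

    Input is case-insensitive; a single dot after the third character (the
    common EMR rendering, e.g. ``I50.20``) is stripped.  Validation is
    structural (length 3-7, alphabetic first character, alphanumeric rest)
    plus chapter-range membership of the 3-character category.  An optional
    ``dictionary`` of allowed code strings tightens validation further.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CodeValidationError("empty code string")
    code = raw.strip().upper()
    if len(code) >= 4 and code[3] == ".":
        code = code[:3] + code[4:]
    if "." in code:
        raise CodeValidationError(f"{raw!r}: dot only allowed after the 3rd character")
    if not 3 <= len(code) <= 7:
        raise CodeValidationError(
            f"{raw!r}: code must have 3-7 characters, got {len(code)}"
        )
    if not code[0].isalpha():
        raise CodeValidationError(f"{raw!r}: first character must be alphabetic")
    if not _CODE_RE.match(code):
        raise CodeValidationError(
            f"{raw!r}: characters after the first must be alphanumeric"
        )
    table = table or default_chapter_table()
    chapter = table.chapter_of_category(code[:3])
    if chapter is None:
        raise CodeValidationError(
            f"{raw!r}: category {code[:3]} outside all chapter block ranges"
        )
    if dictionary is not None and code not in dictionary:
        raise CodeValidationError(f"{raw!r}: not in the supplied code dictionary")
    return IcdCode(code=code, chapter=chapter)


def chapter_of(code: IcdCode, table: Optional[ChapterTable] = None) -> str:
    """Chapter (roman numeral) whose block range contains the code's category."""
    table = table or default_chapter_table()
    chapter = table.chapter_of_category(code.category)
    if chapter is None:
        raise CodeValidationError(f"category {code.category} unmapped in table")
    return chapter


def block_letter_of(code: IcdCode) -> str:
    """First character of the code; the letter-category used for breakdowns."""
    return code.block_letter


@dataclass(frozen=True)
class CodeSet:
    """One main (principal-diagnosis) code plus ordered unique other codes."""

    main_code: IcdCode
    other_codes: tuple[IcdCode, ...] = field(default_factory=tuple)

    def __post_init__(self):
        others = tuple(self.other_codes)
        object.__setattr__(self, "other_codes", others)
        seen = set()
        for c in others:
            if c.code in seen:
                raise ValueError(f"duplicate other code {c.code}")
            seen.add(c.code)
        if self.main_code.code in seen:
            raise ValueError(f"main code {self.main_code.code} repeated in other codes")

    @classmethod
    def from_strings(
        cls,
        main: str,
        others: Iterable[str] = (),
        table: Optional[ChapterTable] = None,
    ) -> "CodeSet":
        return cls(
            main_code=parse_code(main, table),
            other_codes=tuple(parse_code(o, table) for o in others),
        )

    def all_codes(self) -> frozenset[str]:
        """The full predicted/gold set {main} ∪ others as code strings."""
        return frozenset({self.main_code.code, *(c.code for c in self.other_codes)})
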