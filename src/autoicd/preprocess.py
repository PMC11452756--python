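"""Discharge-summary preprocessing.

Raw summaries carry export artifacts: full-line delimiters such as
``--underlying--`` and ``#`` prefixes marking diagnosis lines.  Cleaning
removes both; the remaining text is split into sentences at terminal
punctuation and line breaks and tokenized into lower-cased alphanumeric
runs plus single-character punctuation tokens.  One tokenizer serves both
coders so their inputs stay comparable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .icd import ChapterTable, CodeSet

__all__ = [
    "Document",
    "CorpusRecord",
    "clean_text",
    "split_sentences",
    "tokenize",
    "truncate_tokens",
    "make_document",
    "read_corpus",
    "write_corpus",
]

#: A full line consisting of dashes around an interior word, e.g. "--underlying--".
DEFAULT_DELIMITER_RE = r"^--\S*--\s*$"

_TOKEN_RE = re.compile(r"[a-z0-9]+|[^\sa-z0-9]")
_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+")


@dataclass(frozen=True)
class Document:
    """A cleaned, sentence/token-structured discharge summary."""

    doc_id: str
    raw_text: str
    cleaned_text: str
    sentences: tuple[tuple[str, ...], ...]

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.sentences)

    def tokens(self) -> list[str]:
        """All tokens in reading order."""
        return [t for sent in self.sentences for t in sent]


def clean_text(raw: str, delimiter_pattern: str = DEFAULT_DELIMITER_RE) -> str:
    """Drop delimiter lines and strip leading '#' prefixes; keep all else."""
    delim = re.compile(delimiter_pattern)
    out_lines = []
    for line in raw.split("\n"):
        # strip the prefix before the delimiter check so cleaning is idempotent
        while line.startswith("#"):
            line = line[1:]
            if line.startswith(" "):
                line = line[1:]
        if delim.match(line):
            continue
        out_lines.append(line)
    return "\n".join(out_lines)


def split_sentences(text: str) -> list[str]:
    """Rule-based splitting at sentence-final punctuation and line breaks."""
    sentences = []
    for line in text.split("\n"):
        for piece in _SENT_BOUNDARY_RE.split(line):
            piece = piece.strip()
            if piece:
                sentences.append(piece)
    return sentences


def tokenize(sentence: str) -> list[str]:
    """Lower-cased alphanumeric runs; punctuation as single-char tokens."""
    return _TOKEN_RE.findall(sentence.lower())


def truncate_tokens(tokens: list, max_len: int = 1024) -> list:
    """First ``max_len`` tokens (the causal LM's context-window cap)."""
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    return tokens[:max_len]


def make_document(
    doc_id: str, raw_text: str, delimiter_pattern: str = DEFAULT_DELIMITER_RE
) -> Document:
    """Run the full cleaning/splitting/tokenizing pipeline on one summary."""
    cleaned = clean_text(raw_text, delimiter_pattern)
    sentences = tuple(
        tuple(toks)
        for toks in (tokenize(s) for s in split_sentences(cleaned))
        if toks
    )
    return Document(
        doc_id=doc_id, raw_text=raw_text, cleaned_text=cleaned, sentences=sentences
    )


@dataclass(frozen=True)
class CorpusRecord:
    """One labeled summary: the document plus its gold code set."""

    document: Document
    gold: CodeSet


def read_corpus(
    path, table: Optional[ChapterTable] = None
) -> list[CorpusRecord]:
    """Read a JSON Lines corpus: {"id", "text", "main_code", "other_codes"}."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                doc = make_document(str(obj["id"]), obj["text"])
                gold = CodeSet.from_strings(
                    obj["main_code"], obj.get("other_codes", ()), table
                )
            except (KeyError, ValueError) as err:
                raise ValueError(f"{path}:{lineno}: bad corpus record: {err}") from err
            records.append(CorpusRecord(document=doc, gold=gold))
    return records


def write_corpus(path, records: Iterable[dict]) -> None:
    """Write raw corpus dicts ({"id","text","main_code","other_codes"}) as JSONL."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
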