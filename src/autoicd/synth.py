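"""Seeded synthetic discharge-summary corpora.

Real hospital coding data cannot be shipped, so this module generates
corpora with the structural and statistical properties the coders assume:

* sectioned English-like text (Chief complaint / Impression on Admission /
  Discharge Diagnosis with a ``--underlying--`` delimiter and ``#``-prefixed
  diagnosis lines / History on Admission);
* a long-tailed code inventory sampled with Zipf weights, averaging about
  4.4 codes per summary (truncated Poisson, at least one code);
* strong keyword-code correlations: each code owns unique trigger phrases
  that appear in the text with high probability, and the main code's phrase
  additionally appears in the leading sections, giving a position signal for
  principal-diagnosis selection.

Filler text is drawn from a fixed deterministic pool of pseudo-English
words, disjoint from all trigger phrases, so no download is needed and the
keyword-code association is exact by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .icd import CodeSet, default_chapter_table, parse_code
from .preprocess import write_corpus

__all__ = [
    "SynthConfig",
    "CodebookEntry",
    "Codebook",
    "make_codebook",
    "sample_document",
    "generate_records",
    "generate_corpus",
    "split_sizes",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults model the study conditions."""

    num_codes: int = 50
    vocab_noise: int = 500
    zipf_exponent: float = 1.2
    mean_codes_per_doc: float = 4.4
    keyword_emit_prob: float = 0.95
    n_docs: int = 1000
    split_fracs: tuple[float, float, float] = (0.9427, 0.05, 0.0073)
    seed: int = 0
    tail_leak: bool = False

    def __post_init__(self):
        if not math.isclose(sum(self.split_fracs), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"split_fracs must sum to 1, got {self.split_fracs}"
            )
        if any(not 0.0 < f < 1.0 for f in self.split_fracs):
            raise ValueError("each split fraction must lie in (0, 1)")
        if self.mean_codes_per_doc < 1:
            raise ValueError("mean_codes_per_doc must be >= 1")


@dataclass(frozen=True)
class CodebookEntry:
    code: str
    keywords: tuple[str, ...]
    weight: float


@dataclass(frozen=True)
class Codebook:
    """Synthetic code inventory with trigger phrases and Zipf weights."""

    entries: tuple[CodebookEntry, ...]
    filler_words: tuple[str, ...]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([e.weight for e in self.entries], dtype=float)
        return w / w.sum()

    def to_json(self) -> str:
        return json.dumps(
            {
                "codes": [
                    {"code": e.code, "keywords": list(e.keywords), "weight": e.weight}
                    for e in self.entries
                ]
            },
            indent=1,
        )


_ONSETS = (
    "b br c cl cr d dr f fl g gl gr h j k l m n p pl pr qu r s sc sk sl "
    "sn sp st str t th tr v w z"
).split()
_VOWELS = "a e i o u ai ea ou".split()
_CODAS = ["", "n", "r", "s", "t", "l", "m", "x", "sh", "ck", "rd", "st"]


def _word_pool(rng: np.random.Generator, n: int) -> list[str]:
    """n unique deterministic pseudo-English two-syllable words."""
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n:
        word = (
            _ONSETS[rng.integers(len(_ONSETS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            + _ONSETS[rng.integers(len(_ONSETS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            + _CODAS[rng.integers(len(_CODAS))]
        )
        if word not in seen:
            seen.add(word)
            pool.append(word)
    return pool


def make_codebook(config: SynthConfig) -> Codebook:
    """Draw a seeded inventory of structurally valid codes with keywords.

    Codes are category+suffix strings validated against the chapter table;
    keyword phrases (one to three per code, one or two words each) are
    unique across the codebook and disjoint from the filler vocabulary.
    Sampling weights follow rank^(-zipf_exponent).
    """
    if config.num_codes < 2:
        raise ValueError(f"num_codes must be >= 2, got {config.num_codes}")
    rng = np.random.default_rng(config.seed)
    table = default_chapter_table()
    letters = "ABCDEFGHIJKLMNOPQRSTVWXYZ"  # no U under the default table

    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < config.num_codes:
        cat = letters[rng.integers(len(letters))] + f"{rng.integers(100):02d}"
        if table.chapter_of_category(cat) is None:
            continue
        suffix = "".join(str(rng.integers(10)) for _ in range(1 + rng.integers(3)))
        code = cat + suffix
        if code in seen:
            continue
        try:
            parse_code(code, table)
        except ValueError:
            continue
        seen.add(code)
        codes.append(code)

    # one pool, then partition: filler first, keyword words after -> disjoint
    n_keyword_words = config.num_codes * 6
    pool = _word_pool(rng, config.vocab_noise + n_keyword_words)
    filler = tuple(pool[: config.vocab_noise])
    kw_words = pool[config.vocab_noise :]

    entries = []
    cursor = 0
    for rank, code in enumerate(codes, start=1):
        phrases = []
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(1, 3))
            phrases.append(" ".join(kw_words[cursor : cursor + length]))
            cursor += length
        entries.append(
            CodebookEntry(
                code=code,
                keywords=tuple(phrases),
                weight=rank ** (-config.zipf_exponent),
            )
        )
    return Codebook(entries=tuple(entries), filler_words=filler)


def _truncated_poisson_lambda(target_mean: float) -> float:
    """Rate lambda with E[X | X>=1] = target_mean for X ~ Poisson(lambda)."""
    lam = max(target_mean, 1e-6)
    for _ in range(100):
        lam = target_mean * (1.0 - math.exp(-lam))
    return lam


def _filler_sentence(rng: np.random.Generator, filler: Sequence[str], lo=4, hi=9) -> str:
    n = int(rng.integers(lo, hi))
    words = [filler[rng.integers(len(filler))] for _ in range(n)]
    return " ".join(words).capitalize() + "."


def _phrase(rng: np.random.Generator, entry: CodebookEntry) -> str:
    return entry.keywords[rng.integers(len(entry.keywords))]


def sample_document(
    codebook: Codebook,
    config: SynthConfig,
    rng: np.random.Generator,
    doc_id: str = "doc",
    force_codes: Sequence[str] = (),
) -> tuple[str, CodeSet]:
    """One raw summary (with delimiters and '#' prefixes) and its gold codes.

    The number of codes is truncated-Poisson distributed (>= 1); codes are
    drawn by Zipf weight without replacement, the first drawn acting as the
    main code.  Each code's trigger phrase is emitted into its diagnosis
    line with probability ``keyword_emit_prob`` (a filler line otherwise);
    the main code's phrase is additionally emitted into the chief-complaint
    and impression sections with the same probability.
    """
    lam = _truncated_poisson_lambda(config.mean_codes_per_doc)
    k = 0
    while k < 1:
        k = int(rng.poisson(lam))
    k = min(k, len(codebook.entries))
    idx = rng.choice(len(codebook.entries), size=k, replace=False, p=codebook.weights)
    by_code = {e.code: e for e in codebook.entries}
    drawn = [codebook.entries[i] for i in idx]
    for code in force_codes:
        if code not in {e.code for e in drawn}:
            drawn.append(by_code[code])
    main, others = drawn[0], drawn[1:]
    filler = codebook.filler_words

    def maybe_main_phrase() -> str:
        if rng.random() < config.keyword_emit_prob:
            return _phrase(rng, main)
        return " ".join(filler[rng.integers(len(filler))] for _ in range(2))

    lines = ["Chief complaint:"]
    lines.append(
        maybe_main_phrase().capitalize()
        + " with "
        + " ".join(filler[rng.integers(len(filler))] for _ in range(2))
    )
    lines.append("Impression on Admission:")
    lines.append(maybe_main_phrase().capitalize() + ".")
    lines.append("Discharge Diagnosis:")
    lines.append("--underlying--")
    for entry in drawn:
        if rng.random() < config.keyword_emit_prob:
            lines.append("#" + _phrase(rng, entry).capitalize() + ".")
        else:
            lines.append("#" + _filler_sentence(rng, filler, 2, 4))
    lines.append("History on Admission:")
    for _ in range(int(rng.integers(2, 5))):
        lines.append(_filler_sentence(rng, filler))

    gold = CodeSet.from_strings(main.code, [e.code for e in others])
    return "\n".join(lines), gold


def split_sizes(n: int, fracs: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to the given fractions."""
    raw = [n * f for f in fracs]
    sizes = [int(math.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = max(range(len(fracs)), key=lambda j: (remainders[j], -j))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def _record(doc_id: str, text: str, gold: CodeSet) -> dict:
    return {
        "id": doc_id,
        "text": text,
        "main_code": gold.main_code.code,
        "other_codes": [c.code for c in gold.other_codes],
    }


def generate_records(
    config: SynthConfig, codebook: Optional[Codebook] = None
) -> tuple[dict[str, list[dict]], Codebook]:
    """Generate train/val/test record lists (in memory), seeded.

    Unless ``tail_leak`` is set, every gold code in val/test is guaranteed
    to appear in at least one training summary (offending held-out docs are
    redrawn).  With ``tail_leak``, the rarest code is withheld from the
    train/val sampling pool and forced into the first test summary,
    emulating codes that only ever occur at evaluation time.
    """
    if config.n_docs < 10:
        raise ValueError(f"n_docs must be >= 10, got {config.n_docs}")
    codebook = codebook or make_codebook(config)
    rng = np.random.default_rng(config.seed + 1)
    n_train, n_val, n_test = split_sizes(config.n_docs, config.split_fracs)

    reserved: Optional[str] = None
    head_book = codebook
    if config.tail_leak:
        reserved = codebook.entries[-1].code
        head_book = Codebook(entries=codebook.entries[:-1], filler_words=codebook.filler_words)

    def draw(doc_id: str, book: Codebook, force=()) -> dict:
        text, gold = sample_document(book, config, rng, doc_id, force_codes=force)
        return _record(doc_id, text, gold)

    train = [draw(f"train-{i:05d}", head_book) for i in range(n_train)]
    train_codes = {c for r in train for c in [r["main_code"], *r["other_codes"]]}

    def held_out(prefix: str, n: int, book: Codebook, allow_unseen: bool) -> list[dict]:
        records = []
        for i in range(n):
            rec = draw(f"{prefix}-{i:05d}", book)
            if not allow_unseen:
                for _ in range(200):
                    if set([rec["main_code"], *rec["other_codes"]]) <= train_codes:
                        break
                    rec = draw(f"{prefix}-{i:05d}", book)
            records.append(rec)
        return records

    val = held_out("val", n_val, head_book, allow_unseen=False)
    test = held_out("test", n_test, codebook, allow_unseen=config.tail_leak)
    if config.tail_leak and n_test > 0:
        test[0] = draw("test-00000", codebook, force=(reserved,))
    return {"train": train, "val": val, "test": test}, codebook


def generate_corpus(config: SynthConfig, out_dir) -> dict[str, Path]:
    """Write train/val/test JSONL files plus the codebook JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    splits, codebook = generate_records(config)
    paths: dict[str, Path] = {}
    for name, records in splits.items():
        path = out_dir / f"{name}.jsonl"
        write_corpus(path, records)
        paths[name] = path
    cb_path = out_dir / "codebook.json"
    cb_path.write_text(codebook.to_json(), encoding="utf-8")
    paths["codebook"] = cb_path
    return paths
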