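"""Major-diagnostic-category (MDC) grouping and model-coder agreement.

For prospective DRG payment, the principal diagnosis is grouped into one of
26 MDCs (pre-MDC plus 1-25); cases with no groupable principal diagnosis
fall into NONE.  Agreement between a model's MDC assignments and the human
coder's is quantified per category with a one-vs-rest Cohen kappa, banded on
the Landis-Koch scale, and averaged arithmetically over the categories where
kappa is defined.

The packaged default code->MDC map is a chapter-range approximation of the
proprietary national grouper: ranges of 3-character categories map to the
nearest MDC, with a few specific sub-ranges (HIV, substance use,
hepatobiliary, burns, male/female genitourinary) listed first since the map
is first-match-wins.  Users can supply their own TSV for higher fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .icd import IcdCode

__all__ = [
    "MDC_IDS",
    "MdcMap",
    "KappaReport",
    "default_mdc_map",
    "mdc_of",
    "cohen_kappa",
    "kappa_band",
    "per_mdc_kappa",
    "average_kappa",
]

#: The 27 category labels: pre-MDC, MDC 1..25, and NONE (ungroupable).
MDC_IDS: tuple[str, ...] = ("PRE",) + tuple(str(i) for i in range(1, 26)) + ("NONE",)


@dataclass(frozen=True)
class MdcMap:
    """Ordered first-match-wins list of (category_start, category_end, mdc)."""

    entries: tuple[tuple[str, str, str], ...]
    source: str = "<memory>"

    def __post_init__(self):
        for start, end, mdc in self.entries:
            if len(start) != 3 or len(end) != 3 or start > end:
                raise ValueError(f"malformed MDC range {start}-{end}")
            if mdc not in MDC_IDS or mdc == "NONE":
                raise ValueError(f"unknown MDC id {mdc!r}")

    @classmethod
    def from_tsv(cls, path) -> "MdcMap":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["prefix_start", "prefix_end", "mdc"]:
                raise ValueError(f"unexpected MDC map header: {header}")
            for line in fh:
                line = line.strip()
                if line:
                    start, end, mdc = line.split("\t")
                    rows.append((start.upper(), end.upper(), mdc))
        return cls(tuple(rows), source=str(path))


_DEFAULT_MAP: Optional[MdcMap] = None


def default_mdc_map() -> MdcMap:
    """The packaged chapter-range approximation of the DRG grouper."""
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        path = resources.files("autoicd.data") / "mdc_default.tsv"
        _DEFAULT_MAP = MdcMap.from_tsv(path)
    return _DEFAULT_MAP


def mdc_of(code: Optional[IcdCode], mdc_map: Optional[MdcMap] = None) -> str:
    """MDC of a principal diagnosis; NONE for no match or no diagnosis."""
    if code is None:
        return "NONE"
    mdc_map = mdc_map or default_mdc_map()
    category = code.category
    for start, end, mdc in mdc_map.entries:
        if start <= category <= end:
            return mdc
    return "NONE"


def cohen_kappa(a: Sequence, b: Sequence) -> Optional[float]:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Returns None (undefined) when expected agreement p_e is 1, i.e. both
    raters use a single identical label.
    """
    if len(a) != len(b):
        raise ValueError(f"rater length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label lists")
    n = len(a)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    labels = set(a) | set(b)
    p_e = sum(
        (sum(1 for x in a if x == lab) / n) * (sum(1 for y in b if y == lab) / n)
        for lab in labels
    )
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


#: Landis-Koch interpretation bands, as (upper_bound, label) with bounds inclusive;
#: negative kappa is "poor".
_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def kappa_band(k: float) -> str:
    """Landis-Koch reliability band for a kappa value (k <= 1).

    The Landis-Koch table is stated at two decimals (0.61-0.80 substantial,
    0.81-1.00 almost perfect, ...), so banding is applied to the value
    rounded to two decimals; values in a gap such as 0.803 band downward,
    matching how agreement tables report them.
    """
    if k > 1.0:
        raise ValueError(f"kappa cannot exceed 1, got {k}")
    if k < 0.0:
        return "poor"
    k = round(k, 2)
    for upper, label in _BANDS:
        if k <= upper:
            return label
    return "almost perfect"


@dataclass(frozen=True)
class KappaReport:
    """Per-MDC one-vs-rest kappas, their bands, and the blank-excluding mean."""

    per_mdc: dict[str, Optional[float]]
    bands: dict[str, Optional[str]]
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    average: Optional[float]

    def defined(self) -> dict[str, float]:
        return {m: k for m, k in self.per_mdc.items() if k is not None}


def per_mdc_kappa(
    model_mdcs: Sequence[str], ccs_mdcs: Sequence[str]
) -> KappaReport:
    """Per-category agreement between model and coder MDC assignments.

    Each MDC is scored one-vs-rest: both label lists are reduced to binary
    indicators for that category and Cohen kappa is computed.  Categories
    used by neither rater (or with degenerate marginals) are left undefined
    and excluded from the arithmetic average.
    """
    if len(model_mdcs) != len(ccs_mdcs):
        raise ValueError(
            f"rater length mismatch: {len(model_mdcs)} vs {len(ccs_mdcs)}"
        )
    for lab in list(model_mdcs) + list(ccs_mdcs):
        if lab not in MDC_IDS:
            raise ValueError(f"unknown MDC id {lab!r}")
    per: dict[str, Optional[float]] = {}
    bands: dict[str, Optional[str]] = {}
    for mdc in MDC_IDS:
        if mdc not in set(model_mdcs) and mdc not in set(ccs_mdcs):
            per[mdc] = None
            bands[mdc] = None
            continue
        a = [int(x == mdc) for x in model_mdcs]
        b = [int(x == mdc) for x in ccs_mdcs]
        k = cohen_kappa(a, b)
        per[mdc] = k
        bands[mdc] = None if k is None else kappa_band(k)
    defined = [k for k in per.values() if k is not None]
    return KappaReport(
        per_mdc=per,
        bands=bands,
        counts_a={m: sum(1 for x in model_mdcs if x == m) for m in MDC_IDS},
        counts_b={m: sum(1 for x in ccs_mdcs if x == m) for m in MDC_IDS},
        average=sum(defined) / len(defined) if defined else None,
    )


def average_kappa(values: Sequence[Optional[float]]) -> float:
    """Arithmetic mean over defined (non-blank) kappa values."""
    defined = [v for v in values if v is not None]
    if not defined:
        raise ValueError("no defined kappa values")
    return sum(defined) / len(defined)
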