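"""Wicker-code bookkeeping, the >=80 bp / >=80% identity filter, and genome summaries.

Codes follow the hierarchical class/order/superfamily scheme used for
plant TEs: first letter R (class I retrotransposons) or D (class II DNA
transposons), H for Helitrons as conventionally printed; second letter
for the order (L=LTR, I=LINE, S=SINE, T=TIR); third letter for the
superfamily, X when unknown; a ``-comp``/``-incomp`` completeness suffix.
The non-autonomous LARD and TRIM derivatives are reported as
``RXX-LARD`` / ``RXX-TRIM`` without a suffix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import Interval, merge_intervals

__all__ = [
    "TEAnnotation",
    "FilterThresholds",
    "TESummary",
    "assign_wicker_code",
    "parse_wicker_code",
    "filter_80_80",
    "summarize_by_code",
]

_CLASS_LETTER = {"I": "R", "II": "D", "unknown": "X"}
_ORDER_LETTER = {"LTR": "L", "LINE": "I", "SINE": "S", "TIR": "T", "unknown": "X"}
_SUPERFAMILY_LETTER = {
    "Ty3/gypsy": "G",
    "Ty1/copia": "C",
    "hAT": "A",
    "Mutator": "M",
    "CACTA": "C",
    "Tc1/Mariner": "T",
    "unknown": "X",
}


@dataclass
class TEAnnotation:
    chrom: str
    span: Interval
    strand: str = "."
    te_class: str = "I"
    order: str = "unknown"
    superfamily: str = "unknown"
    completeness: str = "incomp"
    identity_to_consensus: float = 100.0
    te_id: str | None = None

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError(f"empty TE span {self.span}")
        if not 0.0 <= self.identity_to_consensus <= 100.0:
            raise ValueError("identity_to_consensus must lie in [0, 100]")

    @property
    def length_bp(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def wicker_code(self) -> str:
        return assign_wicker_code(self.te_class, self.order, self.superfamily, self.completeness)


@dataclass
class FilterThresholds:
    min_length_bp: int = 80
    min_identity_pct: float = 80.0

    def __post_init__(self) -> None:
        if self.min_length_bp < 0 or self.min_identity_pct < 0:
            raise ValueError("thresholds must be non-negative")


def assign_wicker_code(te_class: str, order: str, superfamily: str, completeness: str | None) -> str:
    """Three-letter Wicker code with completeness suffix.

    Examples: (I, LTR, Ty3/gypsy, comp) -> "RLG-comp";
    (II, TIR, unknown, incomp) -> "DTX-incomp";
    (I, LARD, unknown, None) -> "RXX-LARD".
    """
    if order in ("LARD", "TRIM"):
        return f"RXX-{order}"
    if order == "Helitron":
        if superfamily not in _SUPERFAMILY_LETTER:
            raise ValueError(f"unknown superfamily {superfamily!r}")
        base = "H" + _SUPERFAMILY_LETTER[superfamily]
    else:
        if te_class not in _CLASS_LETTER:
            raise ValueError(f"unknown TE class {te_class!r}")
        if order not in _ORDER_LETTER:
            raise ValueError(f"unknown order {order!r}")
        if superfamily not in _SUPERFAMILY_LETTER:
            raise ValueError(f"unknown superfamily {superfamily!r}")
        base = _CLASS_LETTER[te_class] + _ORDER_LETTER[order] + _SUPERFAMILY_LETTER[superfamily]
    if completeness not in ("comp", "incomp"):
        raise ValueError(f"unknown completeness {completeness!r}")
    return f"{base}-{completeness}"


def parse_wicker_code(code: str) -> tuple[str, str, str, str]:
    """Inverse of :func:`assign_wicker_code` (superfamily letters collapse to names)."""
    if code in ("RXX-LARD", "RXX-TRIM"):
        return ("I", code.split("-")[1], "unknown", "incomp")
    base, _, completeness = code.partition("-")
    completeness = completeness or "incomp"
    if base.startswith("H"):
        return ("II", "Helitron", "unknown", completeness)
    te_class = {v: k for k, v in _CLASS_LETTER.items()}.get(base[0], "unknown")
    order = {v: k for k, v in _ORDER_LETTER.items()}.get(base[1], "unknown")
    sf_letter = base[2] if len(base) > 2 else "X"
    if order == "LTR":
        superfamily = {"G": "Ty3/gypsy", "C": "Ty1/copia"}.get(sf_letter, "unknown")
    else:
        superfamily = "unknown"
    return (te_class, order, superfamily, completeness)


def filter_80_80(
    annotations: list[TEAnnotation],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[TEAnnotation], dict[str, int]]:
    """Keep TEs at least ``min_length_bp`` long with at least ``min_identity_pct``
    identity to their consensus; order-preserving.

    The drop summary partitions removals into ``short`` (length only),
    ``low_identity`` (identity only) and ``both``.
    """
    thresholds = thresholds or FilterThresholds()
    kept = []
    summary = {"short": 0, "low_identity": 0, "both": 0}
    for a in annotations:
        short = a.length_bp < thresholds.min_length_bp
        weak = a.identity_to_consensus < thresholds.min_identity_pct
        if not short and not weak:
            kept.append(a)
        elif short and weak:
            summary["both"] += 1
        elif short:
            summary["short"] += 1
        else:
            summary["low_identity"] += 1
    return kept, summary


@dataclass
class TESummary:
    table: pd.DataFrame  # one row per Wicker code: count, pct_of_te_count
    total_te_bp: int     # overlap-merged per chromosome
    genome_coverage_pct: float


def summarize_by_code(annotations: list[TEAnnotation], genome_length_bp: int) -> TESummary:
    """Per-code copy counts plus overlap-merged genome coverage.

    Coverage merges overlapping TE spans per chromosome before summing,
    so a base covered by several TEs counts once.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    counts: dict[str, int] = {}
    for a in annotations:
        code = a.wicker_code
        counts[code] = counts.get(code, 0) + 1
    n = len(annotations)
    table = pd.DataFrame(
        [
            {"wicker_code": code, "count": c, "pct_of_te_count": 100.0 * c / n if n else 0.0}
            for code, c in sorted(counts.items())
        ],
        columns=["wicker_code", "count", "pct_of_te_count"],
    )
    by_chrom: dict[str, list[Interval]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a.span)
    total = sum(
        sum(e - s for s, e in merge_intervals(spans)) for spans in by_chrom.values()
    )
    return TESummary(
        table=table,
        total_te_bp=total,
        genome_coverage_pct=100.0 * total / genome_length_bp,
    )
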