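"""Insertion dating of full-length LTR retroelements from LTR-pair divergence.

At insertion the two LTRs of an element are identical; they then diverge
neutrally, so an element's age is T = d / (2 r), where d is the
substitutions-per-site divergence between its 5' and 3' LTR and r the
per-site yearly substitution rate.  The rate is calibrated from a
cross-species synonymous divergence: r_coding = dKs / (2 T_spec), doubled
for non-coding sequence (LTRs), the doubling applied before any display
rounding.  The divergence d is either the raw p-distance or its
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); the JC correction
exactly inverts a JC mutation process in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .core import Interval

__all__ = [
    "RateCalibration",
    "LTRAlignmentStats",
    "InsertionDate",
    "SaturationError",
    "calibrate_rate",
    "calibrate_rate_from_species_ks",
    "format_rate",
    "align_ltr_pair",
    "divergence",
    "estimate_insertion_time",
    "date_elements",
    "bin_ages",
]

# fixed affine-gap scoring for LTR pair alignment (recorded in output metadata)
ALIGN_SCORING = {"match": 2, "mismatch": -2, "gap_open": -6, "gap_extend": -1}


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor saturation point (3/4)."""


def format_rate(rate: float) -> str:
    """Render a rate at 3 significant figures, e.g. 1.94e-9."""
    if rate == 0.0:
        return "0"
    mantissa_exp = f"{rate:.2e}"  # e.g. '1.94e-09'
    mantissa, exp = mantissa_exp.split("e")
    return f"{mantissa}e{int(exp)}"


@dataclass
class RateCalibration:
    delta_ks: float
    t_spec_my: float
    coding_rate: float
    noncoding_multiplier: float
    working_rate: float

    @property
    def datable(self) -> bool:
        return self.working_rate > 0.0

    def describe(self) -> dict[str, str]:
        d = {
            "delta_ks": f"{self.delta_ks:g}",
            "t_spec_my": f"{self.t_spec_my:g}",
            "coding_rate": format_rate(self.coding_rate),
            "working_rate": format_rate(self.working_rate),
        }
        if not self.datable:
            d["flag"] = "non-dating calibration"
        return d


def calibrate_rate(
    delta_ks: float, t_spec_my: float, noncoding_multiplier: float = 2.0
) -> RateCalibration:
    """Substitution-rate calibration from synonymous divergence and split time.

    ``coding_rate = delta_ks / (2 * t_spec_my * 1e6)`` and
    ``working_rate = coding_rate * noncoding_multiplier``, both at full
    precision (rounding is display-only, see :func:`format_rate`).
    """
    if delta_ks < 0:
        raise ValueError("delta_ks must be non-negative")
    if t_spec_my <= 0:
        raise ValueError("t_spec_my must be positive")
    if noncoding_multiplier <= 0:
        raise ValueError("noncoding_multiplier must be positive")
    coding = delta_ks / (2.0 * t_spec_my * 1e6)
    return RateCalibration(
        delta_ks=delta_ks,
        t_spec_my=t_spec_my,
        coding_rate=coding,
        noncoding_multiplier=noncoding_multiplier,
        working_rate=coding * noncoding_multiplier,
    )


def calibrate_rate_from_species_ks(
    ks_species_a: float,
    ks_species_b: float,
    t_spec_my: float,
    noncoding_multiplier: float = 2.0,
) -> RateCalibration:
    """Calibration front-end taking the two species' Ks values directly."""
    return calibrate_rate(abs(ks_species_a - ks_species_b), t_spec_my, noncoding_multiplier)


@dataclass
class LTRAlignmentStats:
    aligned_columns: int
    match_columns: int
    mismatch_columns: int
    gap_columns: int

    @property
    def p_distance(self) -> float:
        denom = self.match_columns + self.mismatch_columns
        return self.mismatch_columns / denom if denom else 0.0


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = ALIGN_SCORING["match"]
        a.mismatch_score = ALIGN_SCORING["mismatch"]
        a.open_gap_score = ALIGN_SCORING["gap_open"]
        a.extend_gap_score = ALIGN_SCORING["gap_extend"]
        _aligner = a
    return _aligner


def align_ltr_pair(ltr5: str, ltr3: str) -> LTRAlignmentStats:
    """Global affine-gap alignment of the two LTR copies.

    Gap columns are excluded from the p-distance denominator.
    """
    if not ltr5 or not ltr3:
        raise ValueError("LTR sequences must be non-empty")
    alignment = _get_aligner().align(ltr5, ltr3)[0]
    counts = alignment.counts()
    return LTRAlignmentStats(
        aligned_columns=counts.gaps + counts.identities + counts.mismatches,
        match_columns=counts.identities,
        mismatch_columns=counts.mismatches,
        gap_columns=counts.gaps,
    )


def divergence(stats: LTRAlignmentStats | float, model: str = "jc") -> float:
    """Substitutions-per-site divergence from alignment stats (or a raw p).

    ``raw`` returns the p-distance; ``jc`` applies the Jukes-Cantor
    multiple-hit correction and raises :class:`SaturationError` at
    p >= 0.75.
    """
    p = stats if isinstance(stats, float) else stats.p_distance
    if model == "raw":
        return p
    if model == "jc":
        if p >= 0.75:
            raise SaturationError(f"p-distance {p} is at/beyond JC saturation")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 avoids -0.0
    raise ValueError(f"unknown divergence model {model!r}")


def estimate_insertion_time(d: float, calibration: RateCalibration) -> tuple[float, float]:
    """Age from divergence: T = d / (2 r).  Returns (years, million years)."""
    if not calibration.datable:
        raise ValueError("non-dating calibration: working rate is zero")
    years = d / (2.0 * calibration.working_rate)
    return years, years / 1e6


@dataclass
class InsertionDate:
    element_id: str
    divergence_d: float
    model: str
    age_years: float
    age_my: float
    lineage: str = "RLX"
    superfamily: str = "unknown"


@dataclass
class TSDMismatchTally:
    n: int
    frac_intact: float
    frac_one: float
    frac_two: float


def date_elements(
    elements,
    genome: dict[str, str],
    calibration: RateCalibration,
    model: str = "jc",
) -> tuple[list[InsertionDate], TSDMismatchTally]:
    """Date every validated element and tally its TSD mismatch class.

    Elements with more than two TSD mismatches are expected to have been
    rejected upstream; the tally reports the fractions with 0/1/2
    mismatches among those dated.
    """
    dates = []
    mm_counts = [0, 0, 0]
    for i, el in enumerate(elements):
        seq = genome[el.chrom]
        stats = align_ltr_pair(seq[el.ltr5[0] : el.ltr5[1]], seq[el.ltr3[0] : el.ltr3[1]])
        d = divergence(stats, model)
        years, my = estimate_insertion_time(d, calibration)
        dates.append(
            InsertionDate(
                element_id=f"ltr_element{i:04d}",
                divergence_d=d,
                model=model,
                age_years=years,
                age_my=my,
                lineage=el.lineage,
                superfamily=el.superfamily,
            )
        )
        mm_counts[min(el.tsd_mismatches, 2)] += 1
    n = len(dates)
    if n:
        tally = TSDMismatchTally(n, mm_counts[0] / n, mm_counts[1] / n, mm_counts[2] / n)
    else:
        tally = TSDMismatchTally(0, 0.0, 0.0, 0.0)
    return dates, tally


def bin_ages(
    dates: list[InsertionDate],
    bin_width_my: float = 0.5,
    group_key: str = "superfamily",
) -> pd.DataFrame:
    """Histogram of ages in half-open bins [k*w, (k+1)*w), one row per (group, bin)."""
    if bin_width_my <= 0:
        raise ValueError("bin_width_my must be positive")
    if group_key not in ("superfamily", "lineage"):
        raise ValueError("group_key must be 'superfamily' or 'lineage'")
    rows: dict[tuple[str, int], int] = {}
    for date in dates:
        k = int(date.age_my // bin_width_my)
        key = (getattr(date, group_key), k)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [
            {
                "group": g,
                "bin_start_my": k * bin_width_my,
                "bin_end_my": (k + 1) * bin_width_my,
                "count": c,
            }
            for (g, k), c in sorted(rows.items())
        ],
        columns=["group", "bin_start_my", "bin_end_my", "count"],
    )
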