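"""Shared low-level primitives: intervals, DNA utilities, k-mer coding.

All genomic coordinates inside the package are 0-based half-open
``(start, end)`` tuples; conversion to 1-based inclusive happens only at
the GFF3 boundary (see :mod:`retroscape.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> set of bases (used by the motif scanner)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of an encoded sequence.

    Windows containing a non-ACGT character get code -1.  ``k`` must keep
    4**k within int64 (k <= 31).
    """
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    a64 = arr.astype(np.int64)
    for i in range(k):
        window = a64[i : i + n]
        codes = codes * 4 + np.where(window == 4, 0, window)
        bad |= window == 4
    codes[bad] = -1
    return codes


def interval_length(iv: Interval) -> int:
    return iv[1] - iv[0]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def interval_gap(a: Interval, b: Interval) -> int:
    """Gap in bp between two intervals on the same sequence; 0 if they touch."""
    return max(a[0] - b[1], b[0] - a[1], 0)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals; returns sorted disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random DNA with the given GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@dataclass
class GeneModel:
    """A gene locus as used by proximity, promoter and simulation stages.

    ``cds_start`` is the 0-based genomic coordinate of the first base of
    the start codon; for minus-strand genes the CDS runs leftward from it,
    so the promoter lies to its right.
    """

    gene_id: str
    chrom: str
    span: Interval
    strand: str
    cds_start: int

    def __post_init__(self) -> None:
        if not (self.span[0] <= self.cds_start < self.span[1]):
            raise ValueError(
                f"{self.gene_id}: cds_start {self.cds_start} outside span {self.span}"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
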