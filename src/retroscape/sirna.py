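"""TE-derived siRNA attribution: collapse, miRNA exclusion, best-hit mapping,
TE intersection, and size/superfamily quantification.

Mapping is exact-match on both strands (reads are 20-25 nt, so heuristic
alignment buys nothing); the BLAT-era ``minScore``/``tileSize`` vocabulary
is kept as configuration.  A read whose single best score is achieved at
exactly one locus is ``unique``; at several loci it is ``ambiguous`` and
recorded at the leftmost locus (chromosome lexicographic, then
coordinate); with no qualifying locus it is ``unmapped``.  Only unique
loci receive a TE assignment and enter quantification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import Interval, encode, kmer_codes, overlap_length, revcomp

__all__ = [
    "CollapsedRead",
    "SmallRNALocus",
    "MappingParams",
    "collapse_reads",
    "exclude_mirnas",
    "GenomeIndex",
    "map_best_hit",
    "intersect_te",
    "size_distribution",
    "production_by_superfamily",
]


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class SmallRNALocus:
    read: CollapsedRead
    chrom: str | None
    span: Interval | None
    strand: str | None
    score: int
    status: str  # unique | ambiguous | unmapped
    te_assignment: str | None = None


@dataclass
class MappingParams:
    min_score: int = 10   # minimum matched bases, mirroring minScore=10
    tile_size: int = 8    # kept as vocabulary; the exact matcher seeds on read prefixes
    max_mismatches: int = 0
    min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if min(self.min_score, self.tile_size, self.max_mismatches, self.min_overlap_bp) < 0:
            raise ValueError("mapping parameters must be non-negative")
        if self.max_mismatches != 0:
            raise NotImplementedError("only exact matching (max_mismatches=0) is implemented")


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty read sequence")
    if set(s) - set("ACGT"):
        raise ValueError(f"read contains non-ACGTU characters: {seq!r}")
    return s


def collapse_reads(raw: list[str]) -> list[CollapsedRead]:
    """One record per distinct sequence (U normalised to T), lexicographic order."""
    counts = Counter(_normalize(s) for s in raw)
    return [CollapsedRead(seq, counts[seq]) for seq in sorted(counts)]


def exclude_mirnas(
    collapsed: list[CollapsedRead], mirna_blacklist: list[str]
) -> tuple[list[CollapsedRead], int]:
    """Drop exact-sequence matches to the miRNA blacklist; (kept, dropped count)."""
    black = {_normalize(s) for s in mirna_blacklist}
    kept = [r for r in collapsed if r.sequence not in black]
    return kept, len(collapsed) - len(kept)


class GenomeIndex:
    """Sorted k-mer index over the forward strand of every sequence."""

    def __init__(self, genome: dict[str, str], k: int = 20):
        self.k = k
        self.genome = genome
        self.chroms = sorted(genome)
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for chrom in self.chroms:
            codes = kmer_codes(encode(genome[chrom]), k)
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes[order]
            self._order[chrom] = order

    def occurrences(self, seq: str) -> list[tuple[str, int]]:
        """All forward-strand exact occurrences of ``seq`` (len >= k)."""
        key = kmer_codes(encode(seq[: self.k]), self.k)
        if key.size == 0 or key[0] < 0:
            return []
        hits = []
        code = key[0]
        for chrom in self.chroms:
            sc = self._codes[chrom]
            lo = np.searchsorted(sc, code, side="left")
            hi = np.searchsorted(sc, code, side="right")
            target = self.genome[chrom]
            for pos in sorted(int(p) for p in self._order[chrom][lo:hi]):
                if target[pos : pos + len(seq)] == seq:
                    hits.append((chrom, pos))
        return hits


def map_best_hit(
    collapsed: list[CollapsedRead],
    genome: dict[str, str],
    params: MappingParams | None = None,
) -> list[SmallRNALocus]:
    """Exact best-hit placement of collapsed reads on both strands."""
    params = params or MappingParams()
    if not collapsed:
        return []
    k = min(min(r.length_nt for r in collapsed), 20)
    index = GenomeIndex(genome, k=max(k, 4))
    loci = []
    for read in collapsed:
        if read.length_nt < params.min_score:
            loci.append(SmallRNALocus(read, None, None, None, 0, "unmapped"))
            continue
        hits = [(c, p, "+") for c, p in index.occurrences(read.sequence)]
        rc = revcomp(read.sequence)
        hits += [(c, p, "-") for c, p in index.occurrences(rc)]
        if not hits:
            loci.append(SmallRNALocus(read, None, None, None, 0, "unmapped"))
            continue
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        chrom, pos, strand = hits[0]
        status = "unique" if len(hits) == 1 else "ambiguous"
        loci.append(
            SmallRNALocus(
                read,
                chrom,
                (pos, pos + read.length_nt),
                strand,
                read.length_nt,
                status,
            )
        )
    return loci


def intersect_te(
    loci: list[SmallRNALocus],
    te_annotations,
    params: MappingParams | None = None,
) -> list[SmallRNALocus]:
    """Assign uniquely mapped loci to the TE they overlap by >= min_overlap_bp.

    Assignment goes to the TE with the largest overlap, ties to the
    leftmost TE.  Ambiguous and unmapped loci stay unassigned (they are
    excluded from downstream quantification).
    """
    params = params or MappingParams()
    trees: dict[str, IntervalTree] = {}
    ids: dict[int, str] = {}
    for i, te in enumerate(te_annotations):
        te_id = te.te_id if getattr(te, "te_id", None) else f"te{i:05d}"
        ids[i] = te_id
        trees.setdefault(te.chrom, IntervalTree()).addi(te.span[0], te.span[1], i)
    out = []
    for locus in loci:
        assignment = None
        if locus.status == "unique" and locus.chrom in trees:
            best = None
            for hit in trees[locus.chrom].overlap(locus.span[0], locus.span[1]):
                ov = overlap_length(locus.span, (hit.begin, hit.end))
                if ov < params.min_overlap_bp:
                    continue
                key = (-ov, hit.begin, hit.data)
                if best is None or key < best[0]:
                    best = (key, hit.data)
            if best is not None:
                assignment = ids[best[1]]
        out.append(replace(locus, te_assignment=assignment))
    return out


def size_distribution(
    te_loci: list[SmallRNALocus], weighting: str = "by_read_count"
) -> pd.Series:
    """Length spectrum (20-25 nt) of TE-assigned loci, as fractions summing to 1.

    ``by_read_count`` weights each collapsed read by its multiplicity;
    ``by_unique_sequence`` counts each distinct sequence once.  The total
    weight is stored in ``.attrs['n']``.
    """
    if weighting not in ("by_read_count", "by_unique_sequence"):
        raise ValueError(f"unknown weighting {weighting!r}")
    weights = {length: 0.0 for length in range(20, 26)}
    total = 0.0
    for locus in te_loci:
        if locus.te_assignment is None:
            continue
        w = locus.read.count if weighting == "by_read_count" else 1
        length = locus.read.length_nt
        if length in weights:
            weights[length] += w
            total += w
    out = pd.Series(
        {length: (weights[length] / total if total else 0.0) for length in sorted(weights)},
        name=weighting,
    )
    out.attrs["n"] = total
    return out


def production_by_superfamily(
    te_loci: list[SmallRNALocus],
    te_annotations,
    length_nt: int = 24,
    weighting: str = "by_read_count",
) -> pd.Series:
    """Percent of size-selected siRNA production per Wicker superfamily code.

    Sums read counts of uniquely mapped, TE-assigned loci of the stated
    length per three-letter code of the assigned TE, as a percentage of
    the total across codes (sums to 100 within rounding).
    """
    code_of: dict[str, str] = {}
    for i, te in enumerate(te_annotations):
        te_id = te.te_id if getattr(te, "te_id", None) else f"te{i:05d}"
        code_of[te_id] = te.wicker_code.split("-")[0]
    totals: dict[str, float] = {}
    for locus in te_loci:
        if locus.te_assignment is None or locus.read.length_nt != length_nt:
            continue
        w = locus.read.count if weighting == "by_read_count" else 1
        code = code_of.get(locus.te_assignment, "RXX")
        totals[code] = totals.get(code, 0.0) + w
    grand = sum(totals.values())
    out = pd.Series(
        {code: 100.0 * v / grand for code, v in sorted(totals.items())} if grand else {},
        dtype=float,
        name=f"{length_nt}nt_pct",
    )
    out.attrs["n"] = grand
    return out
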