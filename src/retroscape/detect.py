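"""Structural detection of full-length LTR retrotransposons.

The detector is a transparent seed-and-extend search for long direct
repeats with the structural acceptance criteria a full-length LTR
retroelement must satisfy: two long terminal repeats of similar sequence
(pair identity above a threshold), canonical TG...CA termini, and an
almost intact target-site duplication (TSD, 4-6 bp) flanking the element,
with at most two mismatches tolerated between the two TSD copies.

Search outline per sequence (forward strand only; N runs longer than 11 nt
split sequences into independently searched chunks):

1. exact seed words (default 15-mers) shared between two positions at a
   separation compatible with the LTR/element length windows;
2. seeds grouped by diagonal and clustered, then extended ungapped with an
   X-drop rule;
3. boundaries snapped to the nearest TG/CA motif pair consistent with the
   best flanking TSD;
4. pair identity from a gapped edit-distance alignment (edlib);
5. overlapping candidates resolved by identity, then span, then position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .core import Interval, encode, kmer_codes, hamming, intervals_overlap

__all__ = [
    "DetectorParams",
    "FullLengthLTRElement",
    "StructureRejection",
    "find_ltr_candidates",
    "validate_structure",
    "classify_lineage",
    "detect_full_length_ltrs",
]

# internal search constants (not part of the structural acceptance criteria)
_MAX_SEED_OCCUPANCY = 64   # skip seed words more repetitive than this
_CLUSTER_GAP = 300         # max bp between seeds chained on one diagonal
_XDROP = 9                 # ungapped extension drop-off (match +1 / mismatch -3)
_SNAP_WINDOW = 8           # bp searched around raw boundaries for TG/CA
_MIN_CLUSTER_SPAN = 24     # seeds must cover at least this many bp


@dataclass
class DetectorParams:
    seed_word: int = 15
    ltr_length_range: tuple[int, int] = (100, 3000)
    element_span_range: tuple[int, int] = (1000, 15000)
    min_ltr_pair_identity: float = 0.80
    require_tg_ca: bool = True
    tsd_length_range: tuple[int, int] = (4, 6)
    max_tsd_mismatches: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.min_ltr_pair_identity <= 1.0:
            raise ValueError("min_ltr_pair_identity must lie in (0, 1]")
        if self.max_tsd_mismatches > 2:
            raise ValueError("max_tsd_mismatches is capped at 2")


@dataclass
class FullLengthLTRElement:
    chrom: str
    ltr5: Interval
    ltr3: Interval
    internal: Interval
    ltr_pair_identity: float
    tg_ca_ok: tuple[bool, bool]
    tsd_left: str
    tsd_right: str
    tsd_mismatches: int
    lineage: str = "RLX"
    superfamily: str = "unknown"

    @property
    def span(self) -> Interval:
        return (self.ltr5[0], self.ltr3[1])


@dataclass
class StructureRejection:
    reason: str
    candidate: tuple[Interval, Interval]


@dataclass
class _ScoredCandidate:
    left: Interval
    right: Interval
    identity: float

    @property
    def span(self) -> Interval:
        return (self.left[0], self.right[1])


def _pair_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _split_on_n_runs(seq: str, max_run: int = 11) -> list[tuple[int, str]]:
    """Split a sequence at N runs longer than ``max_run``; returns (offset, chunk)."""
    chunks = []
    last = 0
    for m in re.finditer(r"N{%d,}" % (max_run + 1), seq):
        if m.start() > last:
            chunks.append((last, seq[last : m.start()]))
        last = m.end()
    if last < len(seq):
        chunks.append((last, seq[last:]))
    return chunks


def _seed_pairs(seq: str, params: DetectorParams) -> list[tuple[int, int]]:
    """(diagonal, left_position) seed pairs at LTR-compatible separations."""
    k = params.seed_word
    codes = kmer_codes(encode(seq), k)
    if codes.size == 0:
        return []
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    d_min = params.ltr_length_range[0]
    d_max = params.element_span_range[1] - params.ltr_length_range[0]
    pairs: list[tuple[int, int]] = []
    n = sorted_codes.size
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and sorted_codes[stop] == sorted_codes[start]:
            stop += 1
        g = stop - start
        if 2 <= g <= _MAX_SEED_OCCUPANCY and sorted_codes[start] >= 0:
            pos = np.sort(order[start:stop])
            for ii in range(g):
                for jj in range(ii + 1, g):
                    d = int(pos[jj] - pos[ii])
                    if d < d_min:
                        continue
                    if d > d_max:
                        break
                    pairs.append((d, int(pos[ii])))
        start = stop
    return pairs


def _cluster(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Chain seeds sharing a diagonal into (d, start, end) rough repeats."""
    clusters = []
    pairs.sort()
    i = 0
    n = len(pairs)
    while i < n:
        d = pairs[i][0]
        s0 = s1 = pairs[i][1]
        j = i + 1
        while j < n and pairs[j][0] == d and pairs[j][1] - s1 <= _CLUSTER_GAP:
            s1 = pairs[j][1]
            j += 1
        if s1 + k - s0 >= _MIN_CLUSTER_SPAN:
            clusters.append((d, s0, s1 + k))
        i = j
    return clusters


def _extend(arr: np.ndarray, d: int, s: int, e: int) -> tuple[int, int]:
    """X-drop ungapped extension of the repeat [s, e) vs [s+d, e+d)."""
    n = arr.shape[0]
    # leftwards
    best, cur, best_i = 0, 0, s
    i = s - 1
    while i >= 0 and i + d < n:
        cur += 1 if arr[i] == arr[i + d] and arr[i] != 4 else -3
        if cur > best:
            best, best_i = cur, i
        if best - cur > _XDROP:
            break
        i -= 1
    s = best_i
    # rightwards
    best, cur, best_j = 0, 0, e
    j = e
    while j + d < n:
        cur += 1 if arr[j] == arr[j + d] and arr[j] != 4 else -3
        if cur > best:
            best, best_j = cur, j + 1
        if best - cur > _XDROP:
            break
        j += 1
    return s, best_j


def _best_tsd(seq: str, left_start: int, right_end: int, params: DetectorParams):
    """Best-matching TSD pair in the flanking windows; (left, right, mismatches)."""
    lo, hi = params.tsd_length_range
    best = None
    for length in range(hi, lo - 1, -1):
        if left_start - length < 0 or right_end + length > len(seq):
            continue
        left = seq[left_start - length : left_start]
        right = seq[right_end : right_end + length]
        mm = hamming(left, right)
        if best is None or mm < best[2]:
            best = (left, right, mm)
    return best


def _snap_boundaries(seq: str, d: int, s: int, e: int, params: DetectorParams):
    """Snap raw boundaries to TG/CA motif pairs, preferring TSD-consistent combos.

    Both LTR copies must carry the motif at the snapped position.  Among
    combinations within the snap window the one whose flanking TSD has the
    fewest mismatches wins; ties go to the smallest shift from the raw
    boundaries.  Returns (s, e) or None when no motif pair exists.
    """
    n = len(seq)
    starts = []
    for cand in range(max(0, s - _SNAP_WINDOW), min(n - 1, s + _SNAP_WINDOW) + 1):
        if cand + d + 2 <= n and seq[cand : cand + 2] == "TG" and seq[cand + d : cand + d + 2] == "TG":
            starts.append(cand)
    ends = []
    for cand in range(max(2, e - _SNAP_WINDOW), min(n, e + _SNAP_WINDOW) + 1):
        if cand + d <= n and seq[cand - 2 : cand] == "CA" and seq[cand + d - 2 : cand + d] == "CA":
            ends.append(cand)
    best = None
    for cs in starts:
        for ce in ends:
            if ce - cs < params.ltr_length_range[0]:
                continue
            tsd = _best_tsd(seq, cs, ce + d, params)
            mm = tsd[2] if tsd is not None else params.max_tsd_mismatches + 1
            shift = abs(cs - s) + abs(ce - e)
            key = (mm, shift)
            if best is None or key < best[0]:
                best = (key, cs, ce)
    if best is None:
        return None
    return best[1], best[2]


def _scored_candidates(sequence: str, params: DetectorParams) -> list[_ScoredCandidate]:
    """All structural repeat-pair candidates, unresolved, sorted by left start."""
    out: list[_ScoredCandidate] = []
    for offset, chunk in _split_on_n_runs(sequence):
        if len(chunk) < 2 * params.ltr_length_range[0]:
            continue
        arr = encode(chunk)
        clusters = _cluster(_seed_pairs(chunk, params), params.seed_word)
        seen: set[tuple[int, int, int]] = set()
        for d, s, e in clusters:
            s, e = _extend(arr, d, s, e)
            if params.require_tg_ca:
                snapped = _snap_boundaries(chunk, d, s, e, params)
                if snapped is None:
                    continue
                s, e = snapped
            if (d, s, e) in seen:
                continue
            seen.add((d, s, e))
            length = e - s
            span = d + length
            if not params.ltr_length_range[0] <= length <= params.ltr_length_range[1]:
                continue
            if not params.element_span_range[0] <= span <= params.element_span_range[1]:
                continue
            if s + d <= e:  # LTR copies must not touch (internal region non-empty)
                continue
            identity = _pair_identity(chunk[s:e], chunk[s + d : e + d])
            if identity < params.min_ltr_pair_identity:
                continue
            out.append(
                _ScoredCandidate(
                    left=(offset + s, offset + e),
                    right=(offset + s + d, offset + e + d),
                    identity=identity,
                )
            )
    out.sort(key=lambda c: c.left)
    return out


def _resolve_overlaps(cands: list[_ScoredCandidate]) -> list[_ScoredCandidate]:
    ranked = sorted(cands, key=lambda c: (-c.identity, -(c.span[1] - c.span[0]), c.span[0]))
    kept: list[_ScoredCandidate] = []
    for c in ranked:
        if all(not intervals_overlap(c.span, k.span) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.left)
    return kept


def find_ltr_candidates(sequence: str, params: DetectorParams | None = None) -> list[tuple[Interval, Interval]]:
    """Direct-repeat LTR-pair candidates on one sequence (forward strand).

    Overlapping candidates are resolved by highest pair identity, then
    longest span, then leftmost position; the result is sorted by the left
    LTR's start.
    """
    params = params or DetectorParams()
    resolved = _resolve_overlaps(_scored_candidates(sequence, params))
    return [(c.left, c.right) for c in resolved]


def validate_structure(
    candidate: tuple[Interval, Interval],
    sequence: str,
    params: DetectorParams | None = None,
    chrom: str = "seq",
) -> FullLengthLTRElement | StructureRejection:
    """Check termini and TSD of a candidate repeat pair.

    Returns a populated :class:`FullLengthLTRElement`, or a
    :class:`StructureRejection` carrying the failure reason
    (``"termini"``, ``"tsd_mismatches>N"``, ``"identity"`` or ``"flank"``).
    Out-of-bounds candidates raise ``ValueError``.
    """
    params = params or DetectorParams()
    (ls, le), (rs, re_) = candidate
    n = len(sequence)
    if not (0 <= ls < le <= rs < re_ <= n):
        raise ValueError(f"candidate {candidate} out of bounds for sequence of length {n}")

    five_ok = sequence[ls : ls + 2] == "TG" and sequence[le - 2 : le] == "CA"
    three_ok = sequence[rs : rs + 2] == "TG" and sequence[re_ - 2 : re_] == "CA"
    if params.require_tg_ca and not (five_ok and three_ok):
        return StructureRejection("termini", candidate)

    tsd = _best_tsd(sequence, ls, re_, params)
    if tsd is None:
        return StructureRejection("flank", candidate)
    tsd_left, tsd_right, mm = tsd
    if mm > params.max_tsd_mismatches:
        return StructureRejection(f"tsd_mismatches>{params.max_tsd_mismatches}", candidate)

    identity = _pair_identity(sequence[ls:le], sequence[rs:re_])
    if identity < params.min_ltr_pair_identity:
        return StructureRejection("identity", candidate)

    return FullLengthLTRElement(
        chrom=chrom,
        ltr5=(ls, le),
        ltr3=(rs, re_),
        internal=(le, rs),
        ltr_pair_identity=identity,
        tg_ca_ok=(five_ok, three_ok),
        tsd_left=tsd_left,
        tsd_right=tsd_right,
        tsd_mismatches=mm,
    )


def classify_lineage(
    element: FullLengthLTRElement,
    sequence: str,
    lineage_table: list[tuple[str, str, str]],
) -> tuple[str, str]:
    """Label an element by the best local signature match in its internal region.

    A lineage qualifies when its signature (or either half of it, i.e. at
    least 50% of its length) matches somewhere inside the internal region
    at >= 0.7 identity; the highest identity wins, ties broken by table
    order.  With no qualifying lineage the element stays ("RLX", "unknown").
    """
    internal = sequence[element.internal[0] : element.internal[1]]
    if not internal or not lineage_table:
        return ("RLX", "unknown")
    best: tuple[float, int] | None = None  # (identity, table index)
    for idx, (name, superfamily, signature) in enumerate(lineage_table):
        fragments = [signature]
        half = len(signature) // 2
        if half >= 20:
            fragments += [signature[:half], signature[half:]]
        score = 0.0
        for frag in fragments:
            if len(frag) > len(internal):
                continue
            res = edlib.align(frag, internal, mode="HW", task="distance")
            ident = 1.0 - res["editDistance"] / len(frag)
            if ident >= 0.7:
                score = max(score, ident)
        if score > 0.0 and (best is None or score > best[0]):
            best = (score, idx)
    if best is None:
        return ("RLX", "unknown")
    name, superfamily, _ = lineage_table[best[1]]
    return (name, superfamily)


def detect_full_length_ltrs(
    genome: dict[str, str],
    params: DetectorParams | None = None,
    lineage_table: list[tuple[str, str, str]] | None = None,
) -> list[FullLengthLTRElement]:
    """Full structural detection over a genome: find, validate, classify.

    Candidates are validated before overlap resolution so that a spurious
    high-identity repeat (which validation would reject) can never
    suppress a genuine element; resolution then ranks the surviving
    elements by pair identity, span and position.  Deterministic.
    """
    params = params or DetectorParams()
    elements: list[FullLengthLTRElement] = []
    for chrom in sorted(genome):
        sequence = genome[chrom]
        validated: list[tuple[_ScoredCandidate, FullLengthLTRElement]] = []
        for cand in _scored_candidates(sequence, params):
            result = validate_structure((cand.left, cand.right), sequence, params, chrom=chrom)
            if isinstance(result, FullLengthLTRElement):
                validated.append((cand, result))
        kept = _resolve_overlaps([c for c, _ in validated])
        kept_keys = {(c.left, c.right) for c in kept}
        for cand, el in validated:
            if (cand.left, cand.right) in kept_keys:
                if lineage_table:
                    el.lineage, el.superfamily = classify_lineage(el, sequence, lineage_table)
                elements.append(el)
    elements.sort(key=lambda e: (e.chrom, e.ltr5[0]))
    return elements
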