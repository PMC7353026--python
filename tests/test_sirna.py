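"""Read collapsing, miRNA exclusion, best-hit mapping, TE intersection, tables."""

import numpy as np
import pytest

from retroscape.annotate import TEAnnotation
from retroscape.core import overlap_length, random_dna, revcomp
from retroscape.sirna import (
    CollapsedRead,
    MappingParams,
    SmallRNALocus,
    collapse_reads,
    exclude_mirnas,
    intersect_te,
    map_best_hit,
    production_by_superfamily,
    size_distribution,
)


def test_collapse_counts_and_order():
    collapsed = collapse_reads(["A" * 21, "A" * 21, "C" * 24])
    assert collapsed == [CollapsedRead("A" * 21, 2), CollapsedRead("C" * 24, 1)]
    assert collapsed[0].length_nt == 21
    assert collapse_reads([]) == []


def test_collapse_normalizes_u_to_t():
    collapsed = collapse_reads(["ACGU" * 5, "ACGT" * 5])
    assert collapsed == [CollapsedRead("ACGT" * 5, 2)]


def test_collapse_rejects_empty_sequence():
    with pytest.raises(ValueError):
        collapse_reads(["ACGT", ""])


def test_exclude_mirnas():
    collapsed = collapse_reads(["AAAA" * 5, "CCCC" * 5, "GGGG" * 5])
    kept, dropped = exclude_mirnas(collapsed, ["CCCC" * 5])
    assert dropped == 1
    assert [r.sequence for r in kept] == ["AAAA" * 5, "GGGG" * 5]
    # empty blacklist is the identity
    assert exclude_mirnas(collapsed, []) == (collapsed, 0)
    kept, dropped = exclude_mirnas(collapsed, [r.sequence for r in collapsed])
    assert kept == [] and dropped == 3


def _genome_with(read, copies=1, seed=0):
    rng = np.random.default_rng(seed)
    parts = [random_dna(rng, 500)]
    positions = []
    for _ in range(copies):
        positions.append(sum(len(p) for p in parts))
        parts.append(read)
        parts.append(random_dna(rng, 500))
    return {"chr1": "".join(parts)}, positions


def test_unique_ambiguous_and_unmapped_reads():
    rng = np.random.default_rng(1)
    read = random_dna(rng, 21)
    genome, (pos,) = _genome_with(read, copies=1, seed=2)
    (locus,) = map_best_hit(collapse_reads([read]), genome)
    assert locus.status == "unique"
    assert locus.span == (pos, pos + 21)
    assert locus.strand == "+"
    assert locus.score == 21

    genome2, positions = _genome_with(read, copies=2, seed=3)
    (locus2,) = map_best_hit(collapse_reads([read]), genome2)
    assert locus2.status == "ambiguous"
    assert locus2.span[0] == min(positions)  # leftmost locus recorded

    absent = "ACGT" * 5 + "A"
    genome3, _ = _genome_with(random_dna(rng, 21), seed=4)
    if absent not in genome3["chr1"]:
        (locus3,) = map_best_hit(collapse_reads([absent]), genome3)
        assert locus3.status == "unmapped"
        assert locus3.span is None


def test_reverse_strand_hit_found():
    rng = np.random.default_rng(5)
    read = random_dna(rng, 22)
    genome, (pos,) = _genome_with(revcomp(read), copies=1, seed=6)
    (locus,) = map_best_hit(collapse_reads([read]), genome)
    assert locus.status == "unique"
    assert locus.strand == "-"
    assert locus.span == (pos, pos + 22)


def test_read_below_min_score_unmapped():
    genome = {"c": "ACGTACGTACGT"}
    (locus,) = map_best_hit([CollapsedRead("ACGTA", 1)], genome, MappingParams())
    assert locus.status == "unmapped"


def _te(chrom, start, end, te_id, order="LTR", superfamily="unknown", te_class="I"):
    return TEAnnotation(chrom=chrom, span=(start, end), te_class=te_class, order=order,
                        superfamily=superfamily, completeness="comp", te_id=te_id)


def _locus(chrom, start, length, count=1, status="unique"):
    return SmallRNALocus(CollapsedRead("A" * length, count), chrom, (start, start + length),
                         "+", length, status)


def test_intersection_rules():
    tes = [_te("c", 100, 400, "teA"), _te("c", 395, 600, "teB")]
    inside = _locus("c", 200, 24)
    boundary = _locus("c", 100 - 23, 24)     # span (77, 101): overlaps teA by exactly 1 bp
    outside = _locus("c", 700, 24)
    ambiguous = _locus("c", 200, 24, status="ambiguous")
    out = intersect_te([inside, boundary, outside, ambiguous], tes)
    assert out[0].te_assignment == "teA"
    assert out[1].te_assignment == "teA"
    assert out[2].te_assignment is None
    assert out[3].te_assignment is None  # ambiguous loci are never assigned
    # largest overlap wins, tie -> leftmost TE
    straddle = _locus("c", 390, 24)  # 10 bp in teA, 19 bp in teB
    assert intersect_te([straddle], tes)[0].te_assignment == "teB"


def test_intersection_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    tes = []
    for i in range(300):
        s = int(rng.integers(0, 50_000))
        tes.append(_te("c", s, s + int(rng.integers(30, 400)), f"te{i:03d}"))
    loci = [_locus("c", int(rng.integers(0, 50_000)), 24) for _ in range(300)]
    result = intersect_te(loci, tes)
    for locus, got in zip(loci, result):
        best = None
        for i, te in enumerate(tes):  # O(n*m) all-pairs scan
            ov = overlap_length(locus.span, te.span)
            if ov >= 1:
                key = (-ov, te.span[0], i)
                if best is None or key < best[0]:
                    best = (key, te.te_id)
        assert got.te_assignment == (best[1] if best else None)


def test_size_distribution_fractions():
    loci = [_locus("c", i * 100, 24) for i in range(10)] + [
        _locus("c", 5000 + i * 100, 21) for i in range(10)
    ]
    for l in loci:
        l.te_assignment = "teA"
    dist = size_distribution(loci, "by_read_count")
    assert dist[21] == pytest.approx(0.5)
    assert dist[24] == pytest.approx(0.5)
    assert dist.sum() == pytest.approx(1.0)
    assert dist.attrs["n"] == 20

    empty = size_distribution([])
    assert empty.sum() == 0.0
    assert empty.attrs["n"] == 0


def test_size_distribution_weighting_modes():
    a = _locus("c", 0, 24, count=9)
    b = _locus("c", 100, 21, count=1)
    a.te_assignment = b.te_assignment = "teA"
    by_reads = size_distribution([a, b], "by_read_count")
    by_seq = size_distribution([a, b], "by_unique_sequence")
    assert by_reads[24] == pytest.approx(0.9)
    assert by_seq[24] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        size_distribution([a], "by_magic")


def test_production_by_superfamily_percentages():
    tes = [
        _te("c", 0, 1000, "rlg", superfamily="Ty3/gypsy"),
        _te("c", 2000, 3000, "rix", order="LINE"),
        _te("c", 4000, 5000, "rlc", superfamily="Ty1/copia"),
        _te("c", 6000, 7000, "dtx", order="TIR", te_class="II"),
    ]
    counts = {"rlg": 33, "rix": 18, "rlc": 16, "dtx": 33}
    loci = []
    for te_id, n in counts.items():
        locus = _locus("c", 10, 24, count=n)
        locus.te_assignment = te_id
        loci.append(locus)
    pct = production_by_superfamily(loci, tes, length_nt=24)
    assert pct["RLG"] == pytest.approx(33.0)
    assert pct["RIX"] == pytest.approx(18.0)
    assert pct["RLC"] == pytest.approx(16.0)
    assert pct["DTX"] == pytest.approx(33.0)
    assert pct.sum() == pytest.approx(100.0)

    # length filter: nothing at 22 nt
    assert production_by_superfamily(loci, tes, length_nt=22).empty


def test_pipeline_conservation():
    raw = ["ACGTACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGTA", "TTTTGGGGCCCCAAAATTTTG"]
    collapsed = collapse_reads(raw)
    kept, dropped = exclude_mirnas(collapsed, ["TTTTGGGGCCCCAAAATTTTG"])
    assert len(kept) + dropped == len(collapsed)
    genome = {"c": "ACGTACGTACGTACGTACGTA" + "G" * 100}
    loci = map_best_hit(kept, genome)
    assert all(l.status in ("unique", "ambiguous", "unmapped") for l in loci)
    assert len(loci) == len(kept)
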