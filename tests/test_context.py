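"""Interval distances, gene-TE proximity, promoters, motif scanning, dot plots."""

import numpy as np
import pytest

from retroscape.annotate import TEAnnotation
from retroscape.context import (
    MotifCatalog,
    default_motif_catalog,
    dotplot_matrix,
    extract_promoters,
    gene_te_proximity,
    interval_distance,
    scan_motifs,
)
from retroscape.core import GeneModel, random_dna, revcomp


def test_interval_distance_cases():
    assert interval_distance((100, 200), (150, 250)) == 0   # overlap
    assert interval_distance((100, 200), (200, 300)) == 0   # adjacency, zero gap
    assert interval_distance((100, 200), (260, 300)) == 60
    with pytest.raises(ValueError):
        interval_distance((0, 10), (20, 30), chrom_a="c1", chrom_b="c2")


def _gene(gid, start, end, chrom="c", strand="+", cds=None):
    return GeneModel(gid, chrom, (start, end), strand, cds if cds is not None else start)


def _te(start, end, chrom="c"):
    return TEAnnotation(chrom=chrom, span=(start, end), te_class="I", order="LTR",
                        superfamily="unknown", completeness="comp")


def test_proximity_fractions_for_known_distances():
    # nearest-TE distances 0 (overlap), 600, 2000
    genes = [_gene("g0", 1000, 2000), _gene("g1", 5000, 6000), _gene("g2", 20_000, 21_000)]
    tes = [_te(1500, 1600), _te(6600, 6700), _te(23_000, 23_100)]
    res = {r.threshold_bp: r for r in gene_te_proximity(genes, tes, [500, 1000])}
    assert res[500].fraction == pytest.approx(1 / 3)
    assert res[1000].fraction == pytest.approx(2 / 3)
    assert res[1000].n_genes == 3


def test_proximity_with_no_tes_is_zero():
    genes = [_gene("g", 0, 100)]
    for r in gene_te_proximity(genes, [], [500, 1000]):
        assert r.fraction == 0.0


def test_te_inside_gene_counts_at_every_threshold():
    genes = [_gene("g", 0, 10_000)]
    tes = [_te(4000, 4200)]  # e.g. intronic TE
    for r in gene_te_proximity(genes, tes, [1, 500, 1000]):
        assert r.n_genes_with_te == 1


def test_proximity_is_monotone_in_threshold():
    rng = np.random.default_rng(11)
    genes = [_gene(f"g{i}", s := int(rng.integers(0, 90_000)), s + 500) for i in range(50)]
    tes = [_te(s := int(rng.integers(0, 90_000)), s + 300) for _ in range(30)]
    fractions = [r.fraction for r in gene_te_proximity(genes, tes, [100, 500, 1000, 5000])]
    assert fractions == sorted(fractions)


def test_proximity_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    genes = [_gene(f"g{i}", s := int(rng.integers(0, 50_000)), s + int(rng.integers(100, 2000)))
             for i in range(200)]
    tes = [_te(s := int(rng.integers(0, 50_000)), s + int(rng.integers(50, 1000)))
           for _ in range(200)]
    for res in gene_te_proximity(genes, tes, [500, 1000]):
        brute = 0
        for g in genes:
            d = min(
                (max(t.span[0] - g.span[1], g.span[0] - t.span[1], 0) for t in tes),
                default=None,
            )
            if d is not None and d <= res.threshold_bp:
                brute += 1
        assert res.n_genes_with_te == brute


def test_promoter_extraction_plus_strand():
    rng = np.random.default_rng(13)
    seq = random_dna(rng, 8000)
    genome = {"c": seq}
    gene = _gene("g", 4500, 7000, cds=5000)
    promoters = extract_promoters([gene], genome, 2000)
    assert promoters["g"] == seq[3000:5000]


def test_promoter_truncated_at_contig_edge():
    rng = np.random.default_rng(14)
    seq = random_dna(rng, 3000)
    genome = {"c": seq}
    gene = _gene("g", 500, 1500, cds=700)
    promoters = extract_promoters([gene], genome, 2000)
    assert promoters["g"] == seq[0:700]
    assert len(promoters["g"]) == 700


def test_promoter_minus_strand_is_reverse_complement():
    rng = np.random.default_rng(15)
    seq = random_dna(rng, 9000)
    genome = {"c": seq}
    gene = _gene("g", 1000, 4000, strand="-", cds=3999)
    promoters = extract_promoters([gene], genome, 2000)
    assert revcomp(promoters["g"]) == seq[4000:6000]


def test_promoter_missing_chromosome_raises():
    with pytest.raises(KeyError):
        extract_promoters([_gene("g", 0, 100, chrom="nope")], {"c": "ACGT" * 100})


def test_motif_scan_counts_overlapping_hits():
    catalog = MotifCatalog(entries=[("CAAT-box", "Enhancer", "CAAT")])
    counts, _ = scan_motifs({"p": "TTCAATggCAATtt"}, catalog)
    assert counts.loc["p", "CAAT-box"] == 2
    assert counts.loc["p", "Total"] == 2


def test_motif_scan_reverse_strand_and_palindromes():
    # non-palindromic pattern present only as its reverse complement
    catalog = MotifCatalog(entries=[("m", "Other", "AACC")])
    counts, _ = scan_motifs({"p": "GGTT"}, catalog)
    assert counts.loc["p", "m"] == 1
    # palindromic pattern: counted once per strand by default, switchable
    pal = MotifCatalog(entries=[("pal", "Other", "ACGT")])
    both, _ = scan_motifs({"p": "ACGT"}, pal)
    once, _ = scan_motifs({"p": "ACGT"}, pal, count_palindromes_twice=False)
    assert both.loc["p", "pal"] == 2
    assert once.loc["p", "pal"] == 1


def test_motif_scan_category_totals_and_empty_catalog():
    catalog = MotifCatalog(entries=[("a", "Light", "GGG"), ("b", "Light", "CCC")])
    counts, cats = scan_motifs({"p": "GGGCCC"}, catalog)
    # GGG: fwd 1 + rc(GGG)=CCC 1; CCC likewise
    assert cats.set_index("category").loc["Light", "total"] == counts.loc["p", "Total"]
    counts, cats = scan_motifs({"p": "ACGT"}, MotifCatalog(entries=[]))
    assert counts.loc["p", "Total"] == 0


def test_invalid_iupac_code_names_the_entry():
    with pytest.raises(ValueError, match="bad-motif"):
        MotifCatalog(entries=[("bad-motif", "Other", "ACQT")])


def test_default_catalog_loads_and_scans():
    catalog = default_motif_catalog()
    assert len(catalog.entries) >= 15
    counts, _ = scan_motifs({"p": "CCAATTTCACGTGTT"}, catalog)
    assert counts.loc["p", "CAAT-box"] >= 1
    assert counts.loc["p", "G-Box"] >= 1


def test_dotplot_self_comparison_gives_main_diagonal():
    rng = np.random.default_rng(16)
    seq = random_dna(rng, 120)
    matches = set(dotplot_matrix(seq, seq, word_size=10))
    assert {(i, i, "+") for i in range(len(seq) - 9)} <= matches


def test_dotplot_reverse_complement_gives_antidiagonal():
    rng = np.random.default_rng(17)
    seq = random_dna(rng, 100)
    w = 10
    matches = dotplot_matrix(seq, revcomp(seq), word_size=w)
    minus = {(i, j) for i, j, s in matches if s == "-"}
    for i in range(len(seq) - w + 1):
        assert (i, len(seq) - w - i) in minus


def test_dotplot_matches_brute_force_oracle_on_random_pair():
    rng = np.random.default_rng(18)
    a, b = random_dna(rng, 400), random_dna(rng, 400)
    w = 12
    got = set(dotplot_matrix(a, b, word_size=w))
    brute = set()
    for i in range(len(a) - w + 1):
        wa = a[i : i + w]
        for j in range(len(b) - w + 1):
            wb = b[j : j + w]
            if wa == wb:
                brute.add((i, j, "+"))
            if wa == revcomp(wb):
                brute.add((i, j, "-"))
    assert got == brute
    assert got == set()  # two random 400-mers share no exact 12-mer, as expected


def test_dotplot_short_sequence_and_word_floor():
    assert dotplot_matrix("ACG", "ACGTACGT", word_size=10) == []
    with pytest.raises(ValueError):
        dotplot_matrix("ACGTACGT", "ACGTACGT", word_size=3)
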