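"""Structural detector: candidates, TSD/termini validation, lineage labels."""

import numpy as np
import pytest

from retroscape.core import random_dna
from retroscape.detect import (
    DetectorParams,
    FullLengthLTRElement,
    StructureRejection,
    classify_lineage,
    detect_full_length_ltrs,
    find_ltr_candidates,
    validate_structure,
)
from retroscape.simulate import DEFAULT_LINEAGES, SimulationConfig, simulate_genome


def _planted(seed=1, n=1, **kw):
    base = dict(
        seed=seed, genome_length=40_000 * max(1, n), n_elements=n,
        n_fragments=0, n_genes=0, ltr_length_range=(800, 1200),
        internal_length_range=(2000, 3000), age_range_my=(0.0, 0.0),
    )
    base.update(kw)
    cfg = SimulationConfig(**base)
    genome, te, _ = simulate_genome(cfg)
    return cfg, genome, [r for r in te if r.is_full_length]


def _synthetic_element(rng, ltr_identity_mm=0, tsd_mm=0, break_tg=False, tsd="GATCC"):
    """Hand-built element; returns (sequence, candidate interval pair)."""
    bg1 = random_dna(rng, 300)
    bg2 = random_dna(rng, 300)
    ltr = "TG" + random_dna(rng, 196) + "CA"
    ltr3 = list(ltr)
    pos = rng.choice(np.arange(2, 196), size=ltr_identity_mm, replace=False)
    for p in pos:
        ltr3[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ltr3[p]]
    ltr3 = "".join(ltr3)
    if break_tg:
        ltr = "AG" + ltr[2:]
    internal = random_dna(rng, 1500)
    tsd_r = list(tsd)
    for p in range(tsd_mm):
        tsd_r[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tsd_r[p]]
    tsd_r = "".join(tsd_r)
    seq = bg1 + tsd + ltr + internal + ltr3 + tsd_r + bg2
    s = len(bg1) + len(tsd)
    left = (s, s + len(ltr))
    right = (left[1] + len(internal), left[1] + len(internal) + len(ltr3))
    return seq, (left, right)


def test_pure_background_has_no_candidates():
    for seed in (1, 2):
        cfg = SimulationConfig(seed=seed, genome_length=100_000, n_elements=0, n_fragments=0, n_genes=0)
        genome, _, _ = simulate_genome(cfg)
        assert find_ltr_candidates(genome[cfg.chrom_name]) == []


def test_no_false_positives_on_megabase_background_across_seeds():
    for seed in range(5):
        cfg = SimulationConfig(seed=100 + seed, genome_length=1_000_000, n_elements=0, n_fragments=0, n_genes=0)
        genome, _, _ = simulate_genome(cfg)
        assert detect_full_length_ltrs(genome, DetectorParams(), DEFAULT_LINEAGES) == []


def test_age_zero_element_recovered_at_exact_planted_spans():
    cfg, genome, truth = _planted(seed=3)
    (rec,) = truth
    cands = find_ltr_candidates(genome[cfg.chrom_name])
    assert len(cands) == 1
    left, right = cands[0]
    assert left == rec.ltr5_span
    assert right == rec.ltr3_span


def test_low_identity_repeat_pair_not_reported():
    rng = np.random.default_rng(0)
    # ~50% of informative sites mutated -> pair identity far below 0.80
    seq, _ = _synthetic_element(rng, ltr_identity_mm=98)
    assert find_ltr_candidates(seq) == []


def test_validate_accepts_intact_tsd():
    rng = np.random.default_rng(1)
    seq, cand = _synthetic_element(rng, tsd_mm=0)
    el = validate_structure(cand, seq)
    assert isinstance(el, FullLengthLTRElement)
    assert el.tsd_mismatches == 0
    assert el.tsd_left == el.tsd_right
    assert el.tg_ca_ok == (True, True)


def test_validate_rejects_three_tsd_mismatches():
    rng = np.random.default_rng(2)
    seq, cand = _synthetic_element(rng, tsd_mm=3)
    rej = validate_structure(cand, seq)
    assert isinstance(rej, StructureRejection)
    assert rej.reason == "tsd_mismatches>2"


def test_validate_rejects_non_canonical_terminus():
    rng = np.random.default_rng(3)
    seq, cand = _synthetic_element(rng, break_tg=True)
    rej = validate_structure(cand, seq)
    assert isinstance(rej, StructureRejection)
    assert rej.reason == "termini"


def test_validate_out_of_bounds_raises():
    with pytest.raises(ValueError):
        validate_structure(((0, 50), (100, 5000)), "ACGT" * 100)


def test_classify_exact_signature_and_background_and_ties():
    rng = np.random.default_rng(4)
    name, superfamily, signature = DEFAULT_LINEAGES[0]
    internal = random_dna(rng, 400) + signature + random_dna(rng, 400)
    seq = "TGAA" + internal + "TTCA"
    el = FullLengthLTRElement(
        chrom="c", ltr5=(0, 4), ltr3=(len(seq) - 4, len(seq)), internal=(4, len(seq) - 4),
        ltr_pair_identity=1.0, tg_ca_ok=(True, True), tsd_left="", tsd_right="", tsd_mismatches=0,
    )
    assert classify_lineage(el, seq, DEFAULT_LINEAGES) == (name, superfamily)
    # pure background -> unknown
    bg = "TGAA" + random_dna(rng, 800) + "TTCA"
    assert classify_lineage(el, bg, DEFAULT_LINEAGES) == ("RLX", "unknown")
    assert classify_lineage(el, seq, []) == ("RLX", "unknown")
    # identical signatures under two names: first table entry wins
    table = [("first", "Ty1/copia", signature), ("second", "Ty3/gypsy", signature)]
    assert classify_lineage(el, seq, table) == ("first", "Ty1/copia")


def test_fragments_without_ltr_pair_are_not_reported():
    cfg = SimulationConfig(
        seed=9, genome_length=300_000, n_elements=5, n_fragments=5, n_genes=0,
        age_range_my=(0.0, 2.0),
    )
    genome, te, _ = simulate_genome(cfg)
    elements = detect_full_length_ltrs(genome, DetectorParams(), cfg.lineage_table)
    full = [r for r in te if r.is_full_length]
    assert len(elements) == len(full)
    frag_spans = [r.span for r in te if not r.is_full_length]
    for el in elements:
        for fs in frag_spans:
            assert not (el.span[0] < fs[1] and fs[0] < el.span[1])


def test_empty_genome_gives_empty_result():
    assert detect_full_length_ltrs({}) == []


def test_detected_elements_revalidate_and_do_not_overlap():
    cfg = SimulationConfig(
        seed=10, genome_length=500_000, n_elements=10, n_fragments=3, n_genes=5,
        age_range_my=(0.0, 5.0),
    )
    genome, te, _ = simulate_genome(cfg)
    elements = detect_full_length_ltrs(genome, DetectorParams(), cfg.lineage_table)
    full = [r for r in te if r.is_full_length]
    assert len(elements) >= 0.95 * len(full)
    params = DetectorParams()
    spans = []
    for el in elements:
        again = validate_structure((el.ltr5, el.ltr3), genome[el.chrom], params, chrom=el.chrom)
        assert isinstance(again, FullLengthLTRElement)
        spans.append(el.span)
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


def test_lineage_labels_match_planted_truth():
    cfg, genome, truth = _planted(seed=12, n=6, genome_length=300_000, age_range_my=(0.0, 3.0))
    elements = detect_full_length_ltrs(genome, DetectorParams(), cfg.lineage_table)
    by_start = {r.ltr5_span[0]: r for r in truth}
    hits = 0
    for el in elements:
        rec = by_start.get(el.ltr5[0])
        if rec is not None and el.lineage == rec.lineage:
            hits += 1
    assert hits >= 0.9 * len(elements)


def test_sequences_split_at_long_n_runs():
    rng = np.random.default_rng(13)
    seq, cand = _synthetic_element(rng)
    gap = "N" * 50
    genome = {"c1": random_dna(rng, 500) + gap + seq + gap + random_dna(rng, 500)}
    elements = detect_full_length_ltrs(genome)
    assert len(elements) == 1
    offset = 500 + 50
    assert elements[0].ltr5 == (cand[0][0] + offset, cand[0][1] + offset)
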