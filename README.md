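# retroscape

Transposable-element (TE) landscapes at desk scale: structural detection of
full-length LTR retrotransposons, calibrated insertion-time dating from LTR
divergence, Wicker-code filtering and genome summaries, TE-derived siRNA
attribution, and gene–TE / promoter context analysis — all exercisable on
seeded synthetic genomes with complete ground truth.

The package is aimed at people building or sanity-checking TE annotation
pipelines for large repeat-rich plant genomes (the motivating system is the
rubber tree, *Hevea brasiliensis*, whose genome is ~75% TE and dominated by
*Ty3/gypsy* and *Ty1/copia* LTR retrotransposons). Every stage is an
importable, tested function; the numbered scripts under `analysis/` are thin
drivers that run the stages in order on a synthetic fixture and write their
tables under `results/`.

## The models at the core

**Insertion dating.** A full-length LTR retrotransposon inserts with two
identical long terminal repeats. They then diverge neutrally, so an element's
age is

    T = d / (2 r)

where `d` is the substitutions/site divergence between its 5′ and 3′ LTR
(raw p-distance or Jukes–Cantor corrected, `d = −(3/4) ln(1 − 4p/3)`), and
`r` is the per-site yearly substitution rate. The rate is calibrated from a
cross-species synonymous divergence: with ΔKs = 0.37 − 0.23 = 0.14 between
cassava and *Hevea* and a fossil-dated split of 36 My,
`r_coding = ΔKs/(2·T_spec) = 1.94e-9`, doubled to `3.89e-9` for non-coding
LTR sequence (the doubling happens before rounding: 2 × 1.9444e-9 → 3.89e-9).

**Structural detection.** A transparent seed-and-extend search for long
direct repeats (default 100–3000 bp, element span 1–15 kb, pair identity
≥ 0.80) with the classical structural checks: TG…CA termini and an almost
intact 4–6 bp target-site duplication (TSD), at most two mismatches between
the TSD copies. Lineages are labelled by signature matching inside the
internal region (nine default lineages across *Ty1/copia* and *Ty3/gypsy*).

**Wicker bookkeeping.** Three-letter class/order/superfamily codes
(RLG = retrotransposon/LTR/Gypsy, DTX = DNA/TIR/unknown, …) with
comp/incomp suffixes and RXX-LARD / RXX-TRIM for the non-autonomous
derivatives; the standard "at least 80 bp and at least 80% identity" filter;
per-code summaries with overlap-merged genome coverage.

**siRNA attribution.** Collapse reads, drop blacklisted miRNAs, exact
best-hit mapping on both strands (unique / ambiguous / unmapped), intersect
unique loci with the TE annotation, then quantify length classes (20–25 nt)
and per-superfamily 24-nt production.

**Genomic context.** Symmetric gene–TE proximity fractions (±500 bp, ±1 kb),
2-kb promoter extraction from the start codon (truncated at contig edges),
IUPAC cis-element scanning on both strands, and a word-match dot-plot.

The synthetic-data generator plants all of this with known truth: elements
are TSD–5′LTR–internal–3′LTR–TSD with each LTR copy mutated independently
under Jukes–Cantor so the pair's expected corrected divergence is exactly
`2 r T` for a planted age `T`, making the dating model invertible.

## Worked example

```python
from retroscape import (SimulationConfig, simulate_genome, detect_full_length_ltrs,
                        calibrate_rate_from_species_ks, date_elements)
from retroscape.simulate import DEFAULT_LINEAGES

cfg = SimulationConfig(seed=7, genome_length=800_000, n_elements=20,
                       n_fragments=5, n_genes=10, age_range_my=(0.0, 5.0),
                       ltr_length_range=(800, 1500))
genome, te_truth, genes = simulate_genome(cfg)
elements = detect_full_length_ltrs(genome, lineage_table=cfg.lineage_table)
cal = calibrate_rate_from_species_ks(0.37, 0.23, 36, 2.0)
print(cal.describe())
dates, tally = date_elements(elements, genome, cal, model="jc")
print(len(elements), "elements;", f"{tally.frac_intact:.0%} intact TSDs")
for d in dates[:3]:
    print(d.element_id, round(d.age_my, 2), "My", d.lineage)
```

prints

```
{'delta_ks': '0.14', 't_spec_my': '36', 'coding_rate': '1.94e-9', 'working_rate': '3.89e-9'}
20 elements; 100% intact TSDs
ltr_element0000 3.35 My CRM
ltr_element0001 4.08 My Galadriel
ltr_element0002 0.0 My Tork/TAR
```

i.e. all 20 planted elements are recovered with intact TSDs, the calibration
reproduces the published Euphorbiaceae rates, and each element gets a
JC-corrected age (noisy around its planted value — an 800–1500 bp LTR pair
carries limited site information) and a lineage label.

The full narrative pipeline:

```
python analysis/01_simulate_fixture.py    # genome + truth + reads -> results/fixture/
python analysis/02_detect_ltr.py          # structural detection vs truth
python analysis/03_date_insertions.py     # calibration, dating, 0.5-My histograms
python analysis/04_te_summary.py          # 80/80 filter + Wicker summary
python analysis/05_sirna_attribution.py   # read mapping, TE intersection, tables
python analysis/06_genomic_context.py     # proximity, promoters, motifs, dot-plot
```

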