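# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate about real genomes.

## Coordinates and formats

All internal coordinates are 0-based half-open `(start, end)` tuples;
conversion to 1-based inclusive happens only when writing or reading GFF3.
FASTA I/O goes through Bio.SeqIO, GFF3 parsing through gffutils; GFF3
writing is plain formatting. Truth tables round-trip exactly through TSV.

## Synthetic genomes (`retroscape.simulate`)

The generator emulates the statistical structure the downstream stages
assume, not the full complexity of a plant genome.

* **Background**: i.i.d. nucleotides at a configurable GC fraction
  (default 0.34, typical for plant genomes). No isochores, no tandem
  repeats, no heterozygosity.
* **Full-length elements**: TSD–5′LTR–internal–3′LTR–TSD. The ancestral LTR
  starts `TG` and ends `CA`; a lineage signature (60 bp) is embedded at a
  random offset in the internal region. Each LTR copy is mutated
  independently under Jukes–Cantor with per-site substitution probability
  `p1 = (3/4)(1 − exp(−(4/3) r T))` for planted age `T` (years) and rate
  `r`, so the pair's expected corrected divergence is `2 r T` and the
  dating model is exactly invertible in expectation. No indels by default,
  which keeps LTR pairs equal-length and divergence estimation clean.
* **Terminal dinucleotides are held invariant during mutation**
  (`preserve_termini=True`). The TG/CA integration motif is what a
  structural detector keys on; letting it drift would make detector recall
  an artifact of sequence age rather than of the search. The cost is a
  divergence bias of 4 protected sites per ~1.5 kb LTR (< 0.3%), far below
  the binomial noise of a single pair. Set `preserve_termini=False` to
  study motif decay instead.
* **TSDs**: planted identical on both flanks, then 0–2 mismatches
  optionally injected on one side (`tsd_mismatch_probs`) to exercise the
  0/1/2-mismatch acceptance classes. TSDs do not accumulate age-dependent
  mutations, so planted mismatch counts are exact truth. TSD length 4–6 bp
  is the field convention for LTR retroelements.
* **Fragments**: truncated copies of independent pseudo-elements built as
  a single LTR plus internal sequence, sliced so they never contain a
  repeat pair — degenerate copies that a structural detector must ignore.
* **Genes**: plain background-composition loci with a strand and a start
  codon position; they exist to give the proximity, promoter and
  read-attribution stages non-TE targets. No exons/introns or codon bias.
* **Lineage signatures** are fixed synthetic 60-mers, deliberately shorter
  than the minimum LTR length (100 bp): two same-lineage elements share
  their signature, and keeping it below the LTR length window guarantees
  that signature sharing alone can never form a candidate LTR pair.
* **Placement**: features are shuffled and placed left to right with a
  minimum inter-feature gap (default 200 bp); the remaining slack is split
  by a flat Dirichlet draw, which reproduces the exponential-like spacing
  of uniform random placement. Features never overlap and never nest —
  nested insertions, solo-LTR recombination and methylation are out of
  scope.
* **Reads**: lengths drawn from `sirna_profile` (default dominated by
  23–24 nt with secondary 21/22 nt classes); a fraction `frac_te_reads`
  (default 0.7) originates uniformly inside planted TE spans, the rest
  splits evenly between gene bodies and background; strands uniform. Reads
  are error-free — sequencing error and adapter contamination are not
  simulated (adapter handling is explicitly upstream of this package).
* **Determinism**: one master seed; each stage draws from a deterministic
  sub-stream (`default_rng([seed, stage])`), so identical configurations
  give byte-identical outputs regardless of which stages run.

Consequently, passing the recovery tests shows the pipeline's logic and
statistics are sound under the stated model; it does not certify
performance on real assemblies with nested, truncated and diverged repeat
families.

## Structural detection (`retroscape.detect`)

The published tool historically used for this task has no public
algorithm, so the detector here is its own transparent search with the
same acceptance criteria (long direct repeat, TG…CA, near-intact TSD):

1. N runs longer than 11 nt split sequences into independent chunks.
2. Exact seed words (default 15-mers) shared by two positions at a
   separation compatible with the LTR/span windows are grouped by diagonal
   and chained (gap ≤ 300 bp; seed words occurring > 64 times are skipped
   as repetitive).
3. Chains are extended ungapped with an X-drop rule (+1 match, −3
   mismatch, drop 9).
4. When TG…CA is required, boundaries snap to the nearest motif pair
   (window ± 8 bp) present on **both** copies; among motif combinations
   the one whose flanking TSD has the fewest mismatches wins, ties to the
   smallest shift. This makes boundary calls TSD-driven, which is what
   yields exact planted-boundary recovery on young elements.
5. Pair identity is `1 − edit_distance / max(len)` from a gapped edlib
   alignment; candidates outside the length/span/identity windows are
   dropped.
6. Overlap resolution ranks by identity, then span, then position.
   `detect_full_length_ltrs` validates candidates **before** resolving
   overlaps: a spurious high-identity repeat (e.g. the shared signature of
   two neighbouring same-lineage elements) would otherwise outrank two
   genuine elements and then be rejected anyway, costing recall for no
   benefit. `find_ltr_candidates` called standalone still resolves first,
   as its contract states.
7. Validation checks TG…CA on each copy (reason `termini`), finds the
   best TSD pair over lengths 6→4 (fewest mismatches, ties to longest;
   reason `tsd_mismatches>2` past the cap) and re-checks identity.
8. Lineage labels come from the best local (infix) match of each
   signature — or either half of it, keeping coverage ≥ 50% — inside the
   internal region at ≥ 0.7 identity; ties break by table order.

The detector scans the forward strand only; the simulator plants
forward-strand elements, and reverse-strand search is a documented
extension point. Minimum LTR length, span windows and the seed/extend
constants are stand-in defaults surfaced in `DetectorParams` — no
published values exist for them.

## Wicker bookkeeping (`retroscape.annotate`)

Threshold semantics of the 80/80 filter are "at least": length ≥ 80 bp
**and** identity ≥ 80.0% (the two conventional phrasings "at least 80" and
"> 79" coincide for integer lengths; for identity we adopt ≥ 80.0).
Identity-to-consensus is an input attribute carried in GFF3 (`identity=`),
not recomputed — consensus building is out of scope. Genome coverage
merges overlapping TE spans per chromosome before summing, since per-base
occupancy is the only self-consistent "% of genome"; the per-code table
reports copy counts and percent of TE count. Helitron codes print as `HX`
with a completeness suffix, matching common practice in published
summaries; LARD/TRIM print as `RXX-LARD` / `RXX-TRIM` without one.

## Insertion dating (`retroscape.dating`)

* Calibration: `coding_rate = ΔKs / (2 T_spec)` with ΔKs = |Ks_a − Ks_b|,
  then `working_rate = coding_rate × multiplier` (default 2.0 for
  non-coding sequence). Both are kept at full precision; display rounds to
  3 significant figures. The doubling-before-rounding order matters:
  2 × 1.9444e-9 displays as 3.89e-9, whereas doubling the displayed
  1.94e-9 would print 3.88e-9.
* LTR pair alignment: global affine-gap (match +2, mismatch −2, gap open
  −6, gap extend −1; fixed and recorded in `ALIGN_SCORING`) via
  Bio.Align.PairwiseAligner. Gap columns are excluded from the p-distance
  denominator.
* Divergence models: `raw` (p-distance) and `jc`
  (−(3/4) ln(1 − 4p/3); saturation error at p ≥ 0.75). The source method
  does not name a correction; `jc` is the default because it inverts the
  simulator's mutation process, and every output row is labelled with the
  model used. `raw` underestimates `jc` for all p > 0.
* Ages: `T = d / (2 × working_rate)`; a zero-rate calibration is flagged
  and refused. Histograms use half-open 0.5-My bins by default, grouped by
  superfamily or lineage, and only TSD-validated elements are dated (the
  validation cap of ≤ 2 TSD mismatches is enforced upstream).

## siRNA attribution (`retroscape.sirna`)

Exact matching replaces heuristic read alignment: at 20–25 nt an exact
best-hit search is deterministic and strictly testable, and the historical
`minScore`/`tileSize` parameters remain as configuration vocabulary
(`min_score` keeps its role: reads shorter than it are unmapped).
U normalises to T at collapse; collapse order is lexicographic. miRNA
exclusion is exact-sequence matching against the blacklist. Multi-mapped
(ambiguous) reads are recorded at their leftmost locus but never assigned
to a TE and never counted in quantification — this is stated in the output
rather than silently applied. TE assignment requires ≥ 1 bp overlap and
goes to the TE with the largest overlap, ties to the leftmost. Both
read-count and unique-sequence weightings are implemented for the size
distribution and superfamily tables because published figures are
ambiguous about which they use; read-count weighting is the default.

## Genomic context (`retroscape.context`)

Proximity is measured from the annotated gene span, not the TSS, and ±t is
symmetric; an overlapping TE counts at every threshold. Promoters are the
2 kb upstream of the start codon ("when possible": truncated at contig
edges, so shorter returns are expected and lengths are reported); for
minus-strand genes the downstream genomic bases are reverse-complemented.
Motif scanning counts overlapping occurrences on both strands; palindromic
patterns count once per strand by default (switchable), which is
documented because it doubles palindrome totals. The shipped catalog uses
the familiar PlantCARE-style names and categories with field-convention
IUPAC consensi that are explicitly **not** authoritative — supply a real
catalog for biological conclusions. The dot-plot is an exact word-match
matrix (default word 10) on both strands.

## Problem sizes and study conditions

The canonical studies (`retroscape.studies`) run at desk scale: the age
recovery study plants 200 elements with 1.5 kb LTRs (ages uniform on
0.5–10 My, rate 3.89e-9) on a ~4.4 Mb genome (~1/3 TE density) and
regresses estimated on true age; the siRNA study samples 10,000 TE-origin
reads with profile {24: 0.7, 21: 0.3} over 20 elements on 0.6 Mb; the
Jukes–Cantor check uses a single 1e5-site LTR pair at 5 My, where the
closed-form expected difference is 0.0379. TSD mismatch classes are
planted at the observed 0/1/2 fractions (79.4/19/1.5, normalised) so the
downstream tally is a genuine pipeline readout. These sizes keep each
study within seconds to tens of seconds on one CPU while leaving the
statistical checks (3-SE binomial bounds, slope within [0.9, 1.1], bias
below 5%) well-powered.

## Known limitations

* No reverse-strand or nested-element detection; no solo LTRs.
* The mutation model is substitution-only by default; real LTR pairs
  accumulate indels, which the affine aligner handles but the simulator
  does not generate unless extended.
* The boundary snap assumes intact TG/CA on both copies; heavily decayed
  termini reduce recall by design when `require_tg_ca` is set.
* Exact read mapping cannot place reads across sequencing errors or
  polymorphisms; `max_mismatches > 0` is reserved but unimplemented.
* The TSD mismatch tally reflects detector boundary calls, so a small
  fraction of planted-intact TSDs can be counted in the 1–2 mismatch
  classes when a boundary is off by a few bases — visible in the studies
  as a few percent of mass shifting out of the intact class.
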