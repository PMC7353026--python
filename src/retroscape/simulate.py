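"""Seeded synthetic genomes with planted LTR retrotransposons and small RNAs.

The generator emulates the statistical structure the downstream stages
assume: a background chromosome carrying full-length LTR retrotransposons
(TSD - 5'LTR - internal - 3'LTR - TSD, with TG...CA termini and a lineage
signature embedded in the internal region), degenerate/truncated TE
fragments, plain genes, and 20-25 nt small-RNA reads sampled from those
features with per-read truth.

The two LTR copies of each element are mutated independently under a
Jukes-Cantor process so that the pair's expected corrected divergence is
2*r*T for a planted age T and substitution rate r; this makes insertion
dating exactly invertible in expectation.  The terminal TG/CA
dinucleotides are held invariant (see ``preserve_termini``): they are the
integration motif a structural detector keys on, and letting them drift
would conflate detector recall with sequence age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GeneModel, Interval, random_dna, revcomp

__all__ = [
    "DEFAULT_LINEAGES",
    "SimulationConfig",
    "TruthRecord",
    "ReadTruth",
    "simulate_genome",
    "simulate_small_rna_reads",
    "write_fixture",
    "read_fixture",
    "jc_transition_probability",
]

#: (lineage, superfamily, signature) triples; nine lineages, four Ty1/copia
#: and five Ty3/gypsy, mirroring the major plant LTR-retrotransposon
#: lineages.  Signatures are fixed synthetic 60-mers: long enough to
#: classify on, shorter than any plausible LTR so that signature sharing
#: between elements cannot masquerade as an LTR pair.
DEFAULT_LINEAGES: list[tuple[str, str, str]] = [
    ("Del/Tekay", "Ty3/gypsy", "CCTACCGAAGAGAAATTAATGCTTAGACCGTGGATCGATACAGAAACTGCCGCCTAAATG"),
    ("Athila/Tat", "Ty3/gypsy", "ACTAACCGTGAACGGTAATGGGCTAAAGCGCTTACTCTTAGAGCTAGGCCTAGTCAGTTC"),
    ("Reina", "Ty3/gypsy", "TCTACGCTAACCACTTGGGGCGCACGGCATCCGGACACTTGAGTCGAACTGACACGGCCT"),
    ("CRM", "Ty3/gypsy", "TCCAAAGGCAGGTATCCGAAGTAAGCAAAGATCCGTTGAGAGTACATGGATTGAGTATCT"),
    ("Galadriel", "Ty3/gypsy", "CTGAAAACACGTAGTTGGCCGGGGAGGCAGCTGGACTCTACAGATAGTGAAGTACGGGGT"),
    ("Retrofit/Ale", "Ty1/copia", "TAAAGTGACAGGGCACGCGTAGCATCCGGCGTCAGTGTGAACGCTAGCAGCGCAAGGGAG"),
    ("Tork/TAR", "Ty1/copia", "CGGCCACCGCACCGAGAAGGCGCTCTTGAATGTCAATGTAGTCTTCTACTGCTCGCTCCC"),
    ("Oryco/Ivana", "Ty1/copia", "CATTAGGAGCTTAGAGGGTCTCTAGATTGGGTTGCCACTGCGGAACATATAAATTAACCG"),
    ("SIRE/Maximus", "Ty1/copia", "CCCAGAGGATCGAATGTTGATAAGGCCTGCCCCGGCGATAAATGAAGGCTTGGATAGAGC"),
]


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


class CapacityError(ValueError):
    """Requested features cannot be placed without overlap."""


def _default_profile() -> dict[int, float]:
    # Small-RNA length spectrum dominated by the 23-24 nt heterochromatic
    # classes, with secondary 21/22 nt classes.
    return {20: 0.05, 21: 0.10, 22: 0.15, 23: 0.18, 24: 0.37, 25: 0.15}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 1_000_000
    n_elements: int = 20
    ltr_length_range: tuple[int, int] = (500, 1500)
    internal_length_range: tuple[int, int] = (2000, 5000)
    tsd_length_range: tuple[int, int] = (4, 6)
    age_range_my: tuple[float, float] = (0.0, 10.0)
    substitution_rate: float = 3.89e-9
    lineage_table: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_LINEAGES)
    )
    n_fragments: int = 10
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (1000, 4000)
    sirna_profile: dict[int, float] = field(default_factory=_default_profile)
    n_reads: int = 10_000
    frac_te_reads: float = 0.7
    background_gc: float = 0.34
    tsd_mismatch_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    min_feature_gap: int = 200
    chrom_name: str = "chr1"
    preserve_termini: bool = True

    def validate(self) -> None:
        pairs = {
            "ltr_length_range": self.ltr_length_range,
            "internal_length_range": self.internal_length_range,
            "tsd_length_range": self.tsd_length_range,
            "age_range_my": self.age_range_my,
            "gene_length_range": self.gene_length_range,
        }
        for name, (lo, hi) in pairs.items():
            if lo > hi:
                raise SimulationConfigError(f"{name}: lo {lo} > hi {hi}")
        if self.genome_length <= 0:
            raise SimulationConfigError("genome_length must be positive")
        if min(self.n_elements, self.n_fragments, self.n_genes, self.n_reads) < 0:
            raise SimulationConfigError("feature counts must be non-negative")
        if not (self.tsd_length_range[0] >= 4 and self.tsd_length_range[1] <= 6):
            raise SimulationConfigError("tsd_length_range must lie within [4, 6]")
        if self.age_range_my[0] < 0:
            raise SimulationConfigError("ages must be non-negative")
        if self.substitution_rate <= 0:
            raise SimulationConfigError("substitution_rate must be positive")
        if not 0.0 <= self.frac_te_reads <= 1.0:
            raise SimulationConfigError("frac_te_reads must lie in [0, 1]")
        if not 0.0 <= self.background_gc <= 1.0:
            raise SimulationConfigError("background_gc must lie in [0, 1]")
        for length in self.sirna_profile:
            if not 20 <= length <= 25:
                raise SimulationConfigError(
                    f"sirna_profile length {length} outside [20, 25]"
                )
        total = sum(self.sirna_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(f"sirna_profile sums to {total}, not 1")
        if abs(sum(self.tsd_mismatch_probs) - 1.0) > 1e-9:
            raise SimulationConfigError("tsd_mismatch_probs must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth for one planted TE copy (full-length or fragment)."""

    element_id: str
    chrom: str
    span: Interval  # element without flanking TSDs
    true_age_my: float
    lineage: str
    superfamily: str
    tsd_seq: str
    tsd_mismatches_planted: int
    is_full_length: bool
    ltr5_span: Interval | None = None
    ltr3_span: Interval | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.tsd_mismatches_planted <= 2:
            raise ValueError("tsd_mismatches_planted must lie in [0, 2]")


@dataclass
class ReadTruth:
    read_id: str
    origin_feature: str  # element_id | gene_id | "background"
    chrom: str
    origin_locus: Interval
    length_nt: int
    strand: str


def jc_transition_probability(rate: float, t_years: float) -> float:
    """Per-site substitution probability after t years under Jukes-Cantor."""
    return 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * rate * t_years))


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one master seed, deterministic sub-stream per pipeline stage
    return np.random.default_rng([config.seed, stage])


def _mutate_jc(seq: str, p: float, rng: np.random.Generator, protect: tuple[int, ...]) -> str:
    if p <= 0.0:
        return seq
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < p
    for pos in protect:
        hit[pos % len(seq)] = False
    idx = np.nonzero(hit)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in idx:
        alternatives = bases[bases != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return chars.tobytes().decode("ascii")


def _inject_mismatches(seq: str, n: int, rng: np.random.Generator) -> str:
    if n == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n, replace=False):
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[rng.integers(0, 3)]
    return "".join(chars)


def _build_element(
    config: SimulationConfig, rng: np.random.Generator, idx: int
) -> dict:
    """Assemble one full-length element's sequence and layout metadata."""
    ltr_len = int(rng.integers(config.ltr_length_range[0], config.ltr_length_range[1] + 1))
    int_len = int(rng.integers(config.internal_length_range[0], config.internal_length_range[1] + 1))
    tsd_len = int(rng.integers(config.tsd_length_range[0], config.tsd_length_range[1] + 1))
    age_my = float(rng.uniform(config.age_range_my[0], config.age_range_my[1]))
    li = int(rng.integers(0, len(config.lineage_table)))
    lineage, superfamily, signature = config.lineage_table[li]

    ancestral = list(random_dna(rng, ltr_len, config.background_gc))
    ancestral[0:2] = "TG"
    ancestral[-2:] = "CA"
    ancestral = "".join(ancestral)

    internal = random_dna(rng, int_len, config.background_gc)
    if len(signature) <= int_len:
        off = int(rng.integers(0, int_len - len(signature) + 1))
        internal = internal[:off] + signature + internal[off + len(signature):]

    p1 = jc_transition_probability(config.substitution_rate, age_my * 1e6)
    protect = (0, 1, ltr_len - 2, ltr_len - 1) if config.preserve_termini else ()
    ltr5 = _mutate_jc(ancestral, p1, rng, protect)
    ltr3 = _mutate_jc(ancestral, p1, rng, protect)

    tsd = random_dna(rng, tsd_len, config.background_gc)
    n_mm = int(rng.choice(3, p=config.tsd_mismatch_probs))
    tsd_right = _inject_mismatches(tsd, n_mm, rng)

    seq = tsd + ltr5 + internal + ltr3 + tsd_right
    return {
        "kind": "element",
        "id": f"te{idx:04d}",
        "seq": seq,
        "tsd_len": tsd_len,
        "ltr_len": ltr_len,
        "int_len": int_len,
        "age_my": age_my,
        "lineage": lineage,
        "superfamily": superfamily,
        "tsd_seq": tsd,
        "tsd_mm": n_mm,
    }


def _build_fragment(config: SimulationConfig, rng: np.random.Generator, idx: int) -> dict:
    """A truncated, degenerate TE copy lacking an LTR pair by construction."""
    li = int(rng.integers(0, len(config.lineage_table)))
    lineage, superfamily, signature = config.lineage_table[li]
    ltr_len = int(rng.integers(config.ltr_length_range[0], config.ltr_length_range[1] + 1))
    int_len = int(rng.integers(config.internal_length_range[0], config.internal_length_range[1] + 1))
    ltr = list(random_dna(rng, ltr_len, config.background_gc))
    ltr[0:2] = "TG"
    ltr[-2:] = "CA"
    internal = random_dna(rng, int_len, config.background_gc)
    if len(signature) <= int_len:
        off = int(rng.integers(0, int_len - len(signature) + 1))
        internal = internal[:off] + signature + internal[off + len(signature):]
    whole = "".join(ltr) + internal  # single LTR + internal: never a repeat pair
    lo = max(200, len(whole) // 4)
    take = int(rng.integers(lo, len(whole) + 1))
    start = int(rng.integers(0, len(whole) - take + 1))
    return {
        "kind": "fragment",
        "id": f"frag{idx:04d}",
        "seq": whole[start : start + take],
        "lineage": lineage,
        "superfamily": superfamily,
    }


def _build_gene(config: SimulationConfig, rng: np.random.Generator, idx: int) -> dict:
    length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    offset = int(rng.integers(0, max(1, length // 4)))
    return {
        "kind": "gene",
        "id": f"gene{idx:04d}",
        "seq": random_dna(rng, length, config.background_gc),
        "strand": strand,
        "cds_offset": offset,  # from span start (+) / span end (-)
    }


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TruthRecord], list[GeneModel]]:
    """Generate a genome with planted elements, fragments and genes.

    Returns the genome as ``{chrom: sequence}``, the TE truth records
    (full-length elements and fragments) and the gene models.  Identical
    configuration gives byte-identical output.
    """
    config.validate()

    features: list[dict] = []
    el_rng = _rng(config, 2)
    for i in range(config.n_elements):
        features.append(_build_element(config, el_rng, i))
    fr_rng = _rng(config, 4)
    for i in range(config.n_fragments):
        features.append(_build_fragment(config, fr_rng, i))
    ge_rng = _rng(config, 3)
    for i in range(config.n_genes):
        features.append(_build_gene(config, ge_rng, i))

    place_rng = _rng(config, 1)
    order = place_rng.permutation(len(features))
    features = [features[i] for i in order]

    total = sum(len(f["seq"]) for f in features)
    gap = config.min_feature_gap
    slack = config.genome_length - total - gap * (len(features) + 1)
    if slack < 0:
        raise CapacityError(
            f"genome_length {config.genome_length} cannot host {len(features)} "
            f"features totalling {total} bp with {gap} bp gaps"
        )
    if features:
        # uniform random placement: spacings follow Dirichlet(1,..,1) order
        # statistics, i.e. exponential-like gaps rather than equal ones
        props = place_rng.dirichlet(np.ones(len(features) + 1))
        extra = np.floor(props * slack).astype(int)
        extra[-1] += slack - int(extra.sum())
    else:
        extra = np.array([slack])

    background = random_dna(_rng(config, 0), config.genome_length, config.background_gc)
    parts: list[str] = []
    cursor = 0
    te_truth: list[TruthRecord] = []
    gene_truth: list[GeneModel] = []
    chrom = config.chrom_name
    for i, feat in enumerate(features):
        pad = gap + int(extra[i])
        parts.append(background[cursor : cursor + pad])
        cursor += pad
        start = cursor
        seq = feat["seq"]
        parts.append(seq)
        cursor += len(seq)
        end = cursor
        if feat["kind"] == "element":
            t = feat["tsd_len"]
            ltr = feat["ltr_len"]
            inner_start = start + t
            inner_end = end - t
            te_truth.append(
                TruthRecord(
                    element_id=feat["id"],
                    chrom=chrom,
                    span=(inner_start, inner_end),
                    true_age_my=feat["age_my"],
                    lineage=feat["lineage"],
                    superfamily=feat["superfamily"],
                    tsd_seq=feat["tsd_seq"],
                    tsd_mismatches_planted=feat["tsd_mm"],
                    is_full_length=True,
                    ltr5_span=(inner_start, inner_start + ltr),
                    ltr3_span=(inner_end - ltr, inner_end),
                )
            )
        elif feat["kind"] == "fragment":
            te_truth.append(
                TruthRecord(
                    element_id=feat["id"],
                    chrom=chrom,
                    span=(start, end),
                    true_age_my=0.0,
                    lineage=feat["lineage"],
                    superfamily=feat["superfamily"],
                    tsd_seq="",
                    tsd_mismatches_planted=0,
                    is_full_length=False,
                )
            )
        else:
            if feat["strand"] == "+":
                cds = start + feat["cds_offset"]
            else:
                cds = end - 1 - feat["cds_offset"]
            gene_truth.append(
                GeneModel(
                    gene_id=feat["id"],
                    chrom=chrom,
                    span=(start, end),
                    strand=feat["strand"],
                    cds_start=cds,
                )
            )
    parts.append(background[cursor:config.genome_length])
    genome = {chrom: "".join(parts)[: config.genome_length]}

    te_truth.sort(key=lambda r: r.span)
    gene_truth.sort(key=lambda g: g.span)
    return genome, te_truth, gene_truth


def simulate_small_rna_reads(
    genome: dict[str, str],
    te_truth: list[TruthRecord],
    gene_truth: list[GeneModel],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Sample small-RNA reads from TE spans, genes and background.

    A fraction ``frac_te_reads`` originates uniformly from within planted
    TE spans; the remainder splits evenly between gene bodies and
    background (all background when no genes exist).  Strands are chosen
    uniformly and every read's true origin is recorded.
    """
    config.validate()
    if not genome:
        raise ValueError("genome is empty")
    if config.n_reads == 0:
        return [], []

    rng = _rng(config, 5)
    lengths = sorted(config.sirna_profile)
    probs = [config.sirna_profile[k] for k in lengths]
    max_len = max(lengths)

    te_spans = [(r.chrom, r.span, r.element_id) for r in te_truth]
    gene_spans = [(g.chrom, g.span, g.gene_id) for g in gene_truth]
    for name, spans in (("TE", te_spans), ("gene", gene_spans)):
        for _, (s, e), fid in spans:
            if e - s < max_len:
                raise ValueError(
                    f"requested read length {max_len} exceeds {name} feature {fid}"
                )
    chroms = sorted(genome)
    for c in chroms:
        if len(genome[c]) < max_len:
            raise ValueError(f"requested read length {max_len} exceeds sequence {c}")

    reads: list[tuple[str, str]] = []
    truth: list[ReadTruth] = []
    for i in range(config.n_reads):
        length = int(rng.choice(lengths, p=probs))
        from_te = te_spans and rng.random() < config.frac_te_reads
        if from_te:
            chrom, (s, e), fid = te_spans[int(rng.integers(0, len(te_spans)))]
        elif gene_spans and rng.random() < 0.5:
            chrom, (s, e), fid = gene_spans[int(rng.integers(0, len(gene_spans)))]
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s, e = 0, len(genome[chrom])
            fid = "background"
        start = int(rng.integers(s, e - length + 1))
        seq = genome[chrom][start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        truth.append(ReadTruth(rid, fid, chrom, (start, start + length), length, strand))
    return reads, truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    genome: dict[str, str],
    te_truth: list[TruthRecord],
    gene_truth: list[GeneModel],
    reads: list[tuple[str, str]],
    out_dir,
    read_truth: list[ReadTruth] | None = None,
) -> dict[str, str]:
    """Write a complete fixture (FASTA, GFF3, TSV truth) and return a manifest."""
    from . import io as rio  # local import to avoid a cycle at module load

    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    manifest["genome"] = str(rio.write_fasta(genome, out / "genome.fa"))
    manifest["features"] = str(rio.write_truth_gff3(te_truth, gene_truth, out / "features.gff3"))
    manifest["reads"] = str(rio.write_fasta(dict(reads), out / "reads.fa", order=[r for r, _ in reads]))
    manifest["te_truth"] = str(rio.write_te_truth_tsv(te_truth, out / "te_truth.tsv"))
    manifest["gene_truth"] = str(rio.write_gene_truth_tsv(gene_truth, out / "gene_truth.tsv"))
    if read_truth is not None:
        manifest["read_truth"] = str(rio.write_read_truth_tsv(read_truth, out / "read_truth.tsv"))
    return manifest


def read_fixture(out_dir):
    """Re-read a fixture written by :func:`write_fixture` (exact round-trip)."""
    from . import io as rio

    import pathlib

    out = pathlib.Path(out_dir)
    genome = rio.read_fasta(out / "genome.fa")
    reads_map = rio.read_fasta(out / "reads.fa", keep_order=True)
    reads = list(reads_map.items())
    te_truth = rio.read_te_truth_tsv(out / "te_truth.tsv")
    gene_truth = rio.read_gene_truth_tsv(out / "gene_truth.tsv")
    read_truth = None
    if (out / "read_truth.tsv").exists():
        read_truth = rio.read_read_truth_tsv(out / "read_truth.tsv")
    return genome, te_truth, gene_truth, reads, read_truth
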