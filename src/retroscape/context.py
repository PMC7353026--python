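"""Gene-TE proximity, promoter extraction, cis-element scanning, dot plots.

Proximity is measured symmetrically from the annotated gene span to the
nearest TE span (overlap counts as distance zero).  Promoters are the
``length_bp`` bases upstream of the start codon, truncated at contig
edges; for minus-strand genes the downstream genomic bases are taken and
reverse-complemented.  Motif scanning counts overlapping occurrences of
IUPAC patterns on both strands (palindromes count once per strand by
default; switchable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import IUPAC, GeneModel, Interval, interval_gap, iupac_revcomp, revcomp

__all__ = [
    "ProximityResult",
    "MotifCatalog",
    "interval_distance",
    "gene_te_proximity",
    "extract_promoters",
    "scan_motifs",
    "dotplot_matrix",
    "default_motif_catalog",
]


def interval_distance(a: Interval, b: Interval, chrom_a: str | None = None, chrom_b: str | None = None) -> int:
    """Gap in bp between two intervals; 0 when they overlap or touch.

    When chromosome labels are supplied they must agree.
    """
    if chrom_a is not None and chrom_b is not None and chrom_a != chrom_b:
        raise ValueError(f"intervals on different chromosomes: {chrom_a} vs {chrom_b}")
    return interval_gap(a, b)


@dataclass
class ProximityResult:
    threshold_bp: int
    n_genes: int
    n_genes_with_te: int

    @property
    def fraction(self) -> float:
        return self.n_genes_with_te / self.n_genes if self.n_genes else 0.0


def gene_te_proximity(
    genes: list[GeneModel],
    tes,
    thresholds: list[int] = (500, 1000),
) -> list[ProximityResult]:
    """Fraction of genes with a TE within +/- t bp of their span, per threshold.

    A gene counts for threshold t when the minimum distance from its span
    to any TE span on the same chromosome is <= t; a TE overlapping the
    gene (e.g. in an intron) gives distance 0 and counts at every
    threshold.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    te_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in tes}:
        spans = [t.span for t in tes if t.chrom == chrom]
        te_by_chrom[chrom] = (
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )
    min_dist = []
    for g in genes:
        if g.chrom not in te_by_chrom:
            min_dist.append(np.inf)
            continue
        starts, ends = te_by_chrom[g.chrom]
        gaps = np.maximum.reduce(
            [starts - g.span[1], g.span[0] - ends, np.zeros_like(starts)]
        )
        min_dist.append(int(gaps.min()))
    results = []
    for t in thresholds:
        hit = sum(1 for d in min_dist if d <= t)
        results.append(ProximityResult(threshold_bp=t, n_genes=len(genes), n_genes_with_te=hit))
    return results


def extract_promoters(
    genes: list[GeneModel],
    genome: dict[str, str],
    length_bp: int = 2000,
) -> dict[str, str]:
    """Promoter sequence (up to ``length_bp``) upstream of each start codon.

    Plus strand: ``genome[cds_start - L : cds_start]``.  Minus strand: the
    reverse complement of the L bases to the right of the start codon.
    Truncated at contig edges, so the returned string may be shorter than
    requested.
    """
    promoters = {}
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"gene {g.gene_id}: chromosome {g.chrom} absent from genome")
        seq = genome[g.chrom]
        if g.strand == "+":
            start = max(0, g.cds_start - length_bp)
            promoters[g.gene_id] = seq[start : g.cds_start]
        else:
            end = min(len(seq), g.cds_start + 1 + length_bp)
            promoters[g.gene_id] = revcomp(seq[g.cds_start + 1 : end])
    return promoters


@dataclass
class MotifCatalog:
    """Named IUPAC patterns grouped by response category."""

    entries: list[tuple[str, str, str]]  # (name, category, iupac pattern)

    def __post_init__(self) -> None:
        for name, _, pattern in self.entries:
            if not pattern:
                raise ValueError(f"motif {name!r}: empty pattern")
            bad = set(pattern.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"motif {name!r}: invalid IUPAC code(s) {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path) -> "MotifCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(entries=[(r["name"], r["category"], r["iupac"]) for _, r in df.iterrows()])


def default_motif_catalog() -> MotifCatalog:
    """The packaged cis-element catalog (PlantCARE-style names, placeholder consensi)."""
    with resources.as_file(resources.files("retroscape.data") / "cis_motifs.tsv") as p:
        return MotifCatalog.from_tsv(p)


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for code in pattern.upper():
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?={''.join(parts)})")  # lookahead => overlapping hits


def _count(pattern: re.Pattern, seq: str) -> int:
    return sum(1 for _ in pattern.finditer(seq))


def scan_motifs(
    promoters: dict[str, str],
    catalog: MotifCatalog,
    count_palindromes_twice: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrences of each catalog motif per promoter, both strands, overlapping.

    Returns ``(counts, category_totals)``: counts has one row per
    promoter, one column per motif plus a ``Total`` column; palindromic
    patterns count once per strand unless ``count_palindromes_twice`` is
    off.
    """
    compiled = []
    for name, category, pattern in catalog.entries:
        fwd = _iupac_regex(pattern)
        rc = iupac_revcomp(pattern.upper())
        palindromic = rc == pattern.upper()
        compiled.append((name, category, fwd, _iupac_regex(rc), palindromic))
    rows = {}
    for pid in sorted(promoters):
        seq = promoters[pid].upper()
        row = {}
        for name, _, fwd, rev, palindromic in compiled:
            n = _count(fwd, seq)
            if not palindromic or count_palindromes_twice:
                n += _count(rev, seq)
            row[name] = row.get(name, 0) + n
        rows[pid] = row
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if counts.empty:
        counts = pd.DataFrame(index=sorted(promoters))
    counts["Total"] = counts.sum(axis=1) if len(counts.columns) else 0
    cat_of = {name: category for name, category, _ in catalog.entries}
    cat_totals = {}
    for name in counts.columns:
        if name == "Total":
            continue
        cat = cat_of.get(name, "Other")
        cat_totals[cat] = cat_totals.get(cat, 0) + counts[name].sum()
    category_totals = pd.DataFrame(
        sorted(cat_totals.items()), columns=["category", "total"]
    )
    return counts, category_totals


def dotplot_matrix(
    seq_a: str, seq_b: str, word_size: int = 10
) -> list[tuple[int, int, str]]:
    """Exact word matches between two sequences, as (i, j, strand) triples.

    ``(i, j, '+')`` when ``seq_a[i:i+w] == seq_b[j:j+w]``; ``(i, j, '-')``
    when the a-word equals the reverse complement of the b-word.
    Sequences shorter than the word size give an empty list.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    a, b = seq_a.upper(), seq_b.upper()
    w = word_size
    if len(a) < w or len(b) < w:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - w + 1):
        index.setdefault(b[j : j + w], []).append(j)
    matches = []
    for i in range(len(a) - w + 1):
        word = a[i : i + w]
        for j in index.get(word, ()):
            matches.append((i, j, "+"))
        for j in index.get(revcomp(word), ()):
            matches.append((i, j, "-"))
    matches.sort()
    return matches
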