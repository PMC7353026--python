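"""Reading and writing the standard formats (FASTA, GFF3, TSV).

Internal coordinates are 0-based half-open; GFF3 is written and read as
1-based inclusive.  FASTA goes through Bio.SeqIO; GFF3 parsing goes
through gffutils (in-memory database); writing GFF3 is plain formatting.
"""

from __future__ import annotations

import pathlib

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel
from .simulate import ReadTruth, TruthRecord

GFF_SOURCE = "retroscape"


def write_fasta(seqs: dict[str, str], path, order=None) -> pathlib.Path:
    path = pathlib.Path(path)
    ids = order if order is not None else sorted(seqs)
    records = [SeqRecord(Seq(seqs[i]), id=i, description="") for i in ids]
    try:
        SeqIO.write(records, path, "fasta")
    except OSError as exc:
        raise OSError(f"cannot write FASTA {path}: {exc}") from exc
    return path


def read_fasta(path, keep_order: bool = False) -> dict[str, str]:
    path = pathlib.Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise OSError(f"cannot read FASTA {path}: {exc}") from exc
    return {r.id: str(r.seq).upper() for r in records}


def _attrs(**kwargs) -> str:
    return ";".join(f"{k}={v}" for k, v in kwargs.items() if v is not None and v != "")


def _gff_line(chrom, ftype, span, strand=".", attrs="", score=".") -> str:
    # 0-based half-open -> 1-based inclusive
    return f"{chrom}\t{GFF_SOURCE}\t{ftype}\t{span[0] + 1}\t{span[1]}\t{score}\t{strand}\t.\t{attrs}"


def write_truth_gff3(te_truth: list[TruthRecord], gene_truth: list[GeneModel], path) -> pathlib.Path:
    """Simulator truth as GFF3 (SO types LTR_retrotransposon / gene)."""
    path = pathlib.Path(path)
    lines = ["##gff-version 3"]
    for r in te_truth:
        ftype = "LTR_retrotransposon" if r.is_full_length else "transposable_element_fragment"
        attrs = _attrs(
            ID=r.element_id,
            lineage=r.lineage.replace("/", "-"),
            superfamily=r.superfamily.replace("/", "-"),
            age_my=f"{r.true_age_my:.6f}",
            tsd_seq=r.tsd_seq,
            tsd_mismatches=r.tsd_mismatches_planted,
            full_length=str(r.is_full_length).lower(),
        )
        lines.append(_gff_line(r.chrom, ftype, r.span, "+", attrs))
        if r.is_full_length and r.ltr5_span is not None:
            for name, span in (("ltr5", r.ltr5_span), ("ltr3", r.ltr3_span)):
                lines.append(
                    _gff_line(
                        r.chrom,
                        "long_terminal_repeat",
                        span,
                        "+",
                        _attrs(ID=f"{r.element_id}_{name}", Parent=r.element_id),
                    )
                )
    for g in gene_truth:
        attrs = _attrs(ID=g.gene_id, cds_start=g.cds_start + 1)
        lines.append(_gff_line(g.chrom, "gene", g.span, g.strand, attrs))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gene_gff3(path) -> list[GeneModel]:
    """Parse gene features (with a ``cds_start`` attribute) from GFF3."""
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique")
    genes = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = int(f.attributes["cds_start"][0]) - 1 if "cds_start" in f.attributes else f.start - 1
        genes.append(
            GeneModel(
                gene_id=f.id,
                chrom=f.seqid,
                span=(f.start - 1, f.end),
                strand=f.strand if f.strand in "+-" else "+",
                cds_start=cds,
            )
        )
    return genes


def write_ltr_gff3(elements, path) -> pathlib.Path:
    """Detector output: LTR_retrotransposon parents with long_terminal_repeat children."""
    path = pathlib.Path(path)
    lines = ["##gff-version 3"]
    for i, el in enumerate(elements):
        eid = f"ltr_element{i:04d}"
        span = (el.ltr5[0], el.ltr3[1])
        attrs = _attrs(
            ID=eid,
            lineage=el.lineage.replace("/", "-"),
            superfamily=el.superfamily.replace("/", "-"),
            ltr_identity=f"{el.ltr_pair_identity:.4f}",
            tsd_left=el.tsd_left,
            tsd_right=el.tsd_right,
            tsd_mismatches=el.tsd_mismatches,
        )
        lines.append(_gff_line(el.chrom, "LTR_retrotransposon", span, "+", attrs))
        for name, ltr in (("ltr5", el.ltr5), ("ltr3", el.ltr3)):
            lines.append(
                _gff_line(
                    el.chrom,
                    "long_terminal_repeat",
                    ltr,
                    "+",
                    _attrs(ID=f"{eid}_{name}", Parent=eid),
                )
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_elements_tsv(elements, path) -> pathlib.Path:
    rows = []
    for i, el in enumerate(elements):
        rows.append(
            {
                "element_id": f"ltr_element{i:04d}",
                "chrom": el.chrom,
                "ltr5_start": el.ltr5[0],
                "ltr5_end": el.ltr5[1],
                "ltr3_start": el.ltr3[0],
                "ltr3_end": el.ltr3[1],
                "ltr_pair_identity": el.ltr_pair_identity,
                "tg_ca_ok_5": el.tg_ca_ok[0],
                "tg_ca_ok_3": el.tg_ca_ok[1],
                "tsd_left": el.tsd_left,
                "tsd_right": el.tsd_right,
                "tsd_mismatches": el.tsd_mismatches,
                "lineage": el.lineage,
                "superfamily": el.superfamily,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return pathlib.Path(path)


def write_te_gff3(annotations, path) -> pathlib.Path:
    """TE annotations with ``wicker_code`` and ``identity`` attributes."""
    from .annotate import assign_wicker_code

    path = pathlib.Path(path)
    lines = ["##gff-version 3"]
    for i, a in enumerate(annotations):
        code = assign_wicker_code(a.te_class, a.order, a.superfamily, a.completeness)
        attrs = _attrs(
            ID=a.te_id or f"te{i:05d}",
            wicker_code=code,
            identity=f"{a.identity_to_consensus:.2f}",
        )
        lines.append(_gff_line(a.chrom, "transposable_element", a.span, a.strand, attrs))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_te_gff3(path):
    """Read TE annotations written by :func:`write_te_gff3`."""
    from .annotate import TEAnnotation, parse_wicker_code

    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique")
    annotations = []
    for f in db.features_of_type("transposable_element", order_by=("seqid", "start")):
        code = f.attributes.get("wicker_code", ["RXX-incomp"])[0]
        te_class, order, superfamily, completeness = parse_wicker_code(code)
        annotations.append(
            TEAnnotation(
                chrom=f.seqid,
                span=(f.start - 1, f.end),
                strand=f.strand if f.strand in "+-." else ".",
                te_class=te_class,
                order=order,
                superfamily=superfamily,
                completeness=completeness,
                identity_to_consensus=float(f.attributes.get("identity", ["100"])[0]),
                te_id=f.id,
            )
        )
    return annotations


def write_sirna_gff3(loci, path) -> pathlib.Path:
    """TE-derived siRNA loci (only assigned, uniquely mapped loci are written)."""
    path = pathlib.Path(path)
    lines = ["##gff-version 3"]
    n = 0
    for locus in loci:
        if locus.te_assignment is None:
            continue
        attrs = _attrs(
            ID=f"sirna{n:06d}",
            te_id=locus.te_assignment,
            count=locus.read.count,
            length_nt=locus.read.length_nt,
        )
        lines.append(_gff_line(locus.chrom, "siRNA", locus.span, locus.strand, attrs))
        n += 1
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# truth TSVs (exact round-trip)


def write_te_truth_tsv(te_truth: list[TruthRecord], path) -> pathlib.Path:
    rows = []
    for r in te_truth:
        rows.append(
            {
                "element_id": r.element_id,
                "chrom": r.chrom,
                "start": r.span[0],
                "end": r.span[1],
                "true_age_my": repr(r.true_age_my),
                "lineage": r.lineage,
                "superfamily": r.superfamily,
                "tsd_seq": r.tsd_seq,
                "tsd_mismatches_planted": r.tsd_mismatches_planted,
                "is_full_length": int(r.is_full_length),
                "ltr5_start": "" if r.ltr5_span is None else r.ltr5_span[0],
                "ltr5_end": "" if r.ltr5_span is None else r.ltr5_span[1],
                "ltr3_start": "" if r.ltr3_span is None else r.ltr3_span[0],
                "ltr3_end": "" if r.ltr3_span is None else r.ltr3_span[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return pathlib.Path(path)


def read_te_truth_tsv(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        full = bool(int(row["is_full_length"]))
        out.append(
            TruthRecord(
                element_id=row["element_id"],
                chrom=row["chrom"],
                span=(int(row["start"]), int(row["end"])),
                true_age_my=float(row["true_age_my"]),
                lineage=row["lineage"],
                superfamily=row["superfamily"],
                tsd_seq=row["tsd_seq"],
                tsd_mismatches_planted=int(row["tsd_mismatches_planted"]),
                is_full_length=full,
                ltr5_span=(int(row["ltr5_start"]), int(row["ltr5_end"])) if full else None,
                ltr3_span=(int(row["ltr3_start"]), int(row["ltr3_end"])) if full else None,
            )
        )
    return out


def write_gene_truth_tsv(gene_truth: list[GeneModel], path) -> pathlib.Path:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.span[0],
            "end": g.span[1],
            "strand": g.strand,
            "cds_start": g.cds_start,
        }
        for g in gene_truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return pathlib.Path(path)


def read_gene_truth_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        GeneModel(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            span=(int(row["start"]), int(row["end"])),
            strand=row["strand"],
            cds_start=int(row["cds_start"]),
        )
        for _, row in df.iterrows()
    ]


def write_read_truth_tsv(read_truth: list[ReadTruth], path) -> pathlib.Path:
    rows = [
        {
            "read_id": t.read_id,
            "origin_feature": t.origin_feature,
            "chrom": t.chrom,
            "start": t.origin_locus[0],
            "end": t.origin_locus[1],
            "length_nt": t.length_nt,
            "strand": t.strand,
        }
        for t in read_truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return pathlib.Path(path)


def read_read_truth_tsv(path) -> list[ReadTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ReadTruth(
            read_id=row["read_id"],
            origin_feature=row["origin_feature"],
            chrom=row["chrom"],
            origin_locus=(int(row["start"]), int(row["end"])),
            length_nt=int(row["length_nt"]),
            strand=row["strand"],
        )
        for _, row in df.iterrows()
    ]
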