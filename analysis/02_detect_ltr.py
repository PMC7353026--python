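#!/usr/bin/env python
"""Structurally detect full-length LTR retrotransposons in the fixture genome
and score the detections against the planted truth.

Reads results/fixture/, writes detector GFF3 + evidence TSV under results/,
and prints recall and boundary accuracy.
"""

import argparse
import pathlib

from retroscape.detect import DetectorParams, detect_full_length_ltrs
from retroscape.io import write_elements_tsv, write_ltr_gff3
from retroscape.simulate import DEFAULT_LINEAGES, read_fixture
from retroscape.studies import match_elements_to_truth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=pathlib.Path, default=pathlib.Path("results/fixture"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()

    genome, te_truth, _, _, _ = read_fixture(args.fixture)
    elements = detect_full_length_ltrs(genome, DetectorParams(), DEFAULT_LINEAGES)
    args.out.mkdir(parents=True, exist_ok=True)
    write_ltr_gff3(elements, args.out / "detected_ltr.gff3")
    write_elements_tsv(elements, args.out / "detected_ltr.tsv")

    pairs, recall = match_elements_to_truth(elements, te_truth)
    exact = sum(1 for r, el in pairs if el.ltr5 == r.ltr5_span and el.ltr3 == r.ltr3_span)
    lineage_ok = sum(1 for r, el in pairs if el.lineage == r.lineage)
    n_full = sum(r.is_full_length for r in te_truth)
    print(f"detected {len(elements)} elements; recall {recall:.3f} ({len(pairs)}/{n_full})")
    print(f"exact LTR boundaries: {exact}/{len(pairs)}; lineage labels correct: {lineage_ok}/{len(pairs)}")


if __name__ == "__main__":
    main()
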