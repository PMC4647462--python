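#!/usr/bin/env python
"""Classify the detected circRNAs against the gene models.

Produces the genomic-origin category table (CDS-CDS, UTR combinations,
intron, intergenic, ...), known-splice-site scores, antisense overlaps,
alternative-backsplicing isoform families and the exon-span / length
summaries, written under results/.
"""

from __future__ import annotations

import json
from pathlib import Path

from ricircle.annotation import ModelIndex, alternative_backsplicing, classify, \
    summarize
from ricircle.circ_calling import read_calls
from ricircle.io_core import read_gff3

DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    calls = read_calls(RESULTS / "calls.tsv")
    models = read_gff3(DATA / "models.gff3")
    mindex = ModelIndex(models)
    annotated = [classify(c, mindex) for c in calls]

    with open(RESULTS / "annotated_calls.tsv", "w") as fh:
        fh.write("id\tcategory\texonic\tknown_sites\tparental\tantisense\t"
                 "exon_span\texonic_length\n")
        for a in annotated:
            fh.write(f"{a.call.id}\t{a.category}\t{int(a.exonic)}\t"
                     f"{a.known_sites}\t{','.join(a.parental_genes)}\t"
                     f"{','.join(a.antisense_genes)}\t{a.exon_span}\t"
                     f"{a.exonic_length}\n")

    report = {
        "summary": summarize(annotated, models),
        "alternative_backsplicing": alternative_backsplicing(annotated),
    }
    (RESULTS / "annotation_report.json").write_text(
        json.dumps(report, indent=2, default=str))

    s = report["summary"]
    print(f"{s['n_calls']} calls annotated; {s['n_exonic']} exonic")
    print("categories:", dict(sorted(s["categories"].items())))
    print(f"fraction spanning 1-4 exons: {s['frac_span_1_4']:.3f}")
    print(f"mean trimmed exonic length: {s['mean_exonic_length']:.1f} bp")
    ab = report["alternative_backsplicing"]
    print(f"alternative backsplicing: {ab['n_genes_multi']} parental genes "
          f"with >=2 isoforms {ab['histogram']}")
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
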