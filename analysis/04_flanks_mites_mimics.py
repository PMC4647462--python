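#!/usr/bin/env python
"""Mechanism/function screens on the detected circRNAs.

Three screens over the calls from 02_detect_circrnas.py:

1. flanking inverted repeats (>= 18-bp reverse-complement matches between
   the 500-bp backsplice flanks), after planting such a repeat pair around
   one call to demonstrate a positive;
2. MITE overlap, against a synthetic MITE annotation (BED) constructed so
   that a subset of calls carries elements in both flanks — the planted
   intervals are labelled synthetic, there is no real P-MITE data here;
3. miRNA target-mimic prediction, against a synthetic miRNA set containing
   designed mimics of two call sequences (seed-perfect, central 3-nt
   bulge) plus random decoys.

Writes per-screen tables under results/.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ricircle.circ_calling import read_calls
from ricircle.downstream_analysis import (
    FlankConfig,
    MimicConfig,
    find_flanking_complements,
    mite_overlap,
    predict_mimics,
)
from ricircle.io_core import Genome, read_fasta, revcomp, write_bed

DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parents[1] / "results"

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def plant_inverted_repeat(genome: Genome, call, rng) -> Genome:
    """Copy a 24-bp word into one flank and its rc into the other."""
    seq = bytearray(genome[call.chrom], "ascii")
    word = "".join("ACGT"[i] for i in rng.integers(0, 4, 24))
    up_pos = call.start - 350
    down_pos = call.end + 1 + 180
    seq[up_pos:up_pos + 24] = word.encode()
    seq[down_pos:down_pos + 24] = revcomp(word).encode()
    chroms = dict(genome.chroms)
    chroms[call.chrom] = seq.decode()
    return Genome(chroms)


def synthetic_mites(calls, rng) -> list[tuple[str, int, int, str]]:
    """MITE-like intervals: both flanks for the first three calls, one
    flank only for the next three, plus random background."""
    mites = []
    for i, c in enumerate(calls[:6]):
        mites.append((c.chrom, c.start - 400, c.start - 250, f"synMITE{2 * i}"))
        if i < 3:
            mites.append((c.chrom, c.end + 100, c.end + 260,
                          f"synMITE{2 * i + 1}"))
    for i in range(20):
        s = int(rng.integers(0, 480_000))
        mites.append(("chr1" if i % 2 else "chr2", s, s + 200, f"synBG{i}"))
    return mites


def designed_mimic_mirnas(genome, calls, rng) -> list[tuple[str, str]]:
    """21-nt miRNAs reverse-complementary to a call sequence except for a
    3-nt bulge on the circRNA side opposite positions 10/11."""
    mirnas = []
    for i, c in enumerate(calls[:2]):
        span = genome.fetch(c.chrom, c.start, c.end + 1)
        site = span[40:40 + 24]  # 21 paired bases + 3-nt bulge
        target_paired = site[:11] + site[14:]  # drop the bulge bases
        mirna = "".join(COMP[b] for b in target_paired)[::-1]
        mirnas.append((f"syn-miR{i + 1}", mirna))
    for i in range(8):
        mirnas.append((f"decoy-miR{i + 1}",
                       "".join("ACGT"[j] for j in rng.integers(0, 4, 21))))
    return mirnas


def main() -> None:
    rng = np.random.default_rng(404)
    genome = read_fasta(DATA / "genome.fa")
    calls = read_calls(RESULTS / "calls.tsv")
    if not calls:
        raise SystemExit("no calls found; run 02_detect_circrnas.py first")
    cfg = FlankConfig()

    genome = plant_inverted_repeat(genome, calls[0], rng)
    rows = []
    for c in calls:
        for p in find_flanking_complements(c, genome, cfg):
            rows.append((c.id, p.up_start + 1, p.down_start + 1, p.length, p.seq))
    with open(RESULTS / "flanking_complements.tsv", "w") as fh:
        fh.write("id\tup_start\tdown_start\tlength\tseq\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")

    mites = synthetic_mites(calls, rng)
    write_bed([(c, s, e, n, 0, "+") for c, s, e, n in mites],
              DATA / "synthetic_mites.bed")
    flagged = mite_overlap(calls, mites, cfg)

    mirnas = designed_mimic_mirnas(genome, calls, rng)
    mimic_rows = []
    for c in calls:
        span = genome.fetch(c.chrom, c.start, c.end + 1)
        for s in predict_mimics(c.id, span, mirnas, MimicConfig()):
            mimic_rows.append((s.circ_id, s.mirna_id, s.position,
                               s.bulge_after, s.weighted_mismatches))
    with open(RESULTS / "mimic_sites.tsv", "w") as fh:
        fh.write("circ_id\tmirna_id\tposition\tbulge_after\tweighted_mismatches\n")
        for r in mimic_rows:
            fh.write("\t".join(map(str, r)) + "\n")

    report = {
        "n_calls": len(calls),
        "calls_with_flanking_complements": len({r[0] for r in rows}),
        "complement_pairs": len(rows),
        "mite_flagged_calls": flagged,
        "mimic_sites": len(mimic_rows),
        "mimic_bearing_calls": len({r[0] for r in mimic_rows}),
    }
    (RESULTS / "downstream_report.json").write_text(json.dumps(report, indent=2))
    print(f"{report['calls_with_flanking_complements']} of {len(calls)} calls "
          f"carry >=18-bp flanking inverted repeats ({len(rows)} pairs)")
    print(f"{len(flagged)} calls with MITEs in both flanks: {flagged}")
    print(f"{report['mimic_bearing_calls']} calls carry "
          f"{len(mimic_rows)} predicted target-mimic sites")
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
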