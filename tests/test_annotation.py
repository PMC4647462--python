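"""Classification vs a per-base feature-map oracle, and summaries."""

from __future__ import annotations

import numpy as np
import pytest

from ricircle.annotation import (
    AnnotatedCirc,
    ModelIndex,
    alternative_backsplicing,
    classify,
    containment_in_transcripts,
    endpoint_label,
    known_site_score,
    summarize,
)
from ricircle.circ_calling import CircRNACall
from ricircle.io_core import GeneModel, partition_transcript


def call_at(chrom, strand, start, end, cid="c1"):
    return CircRNACall(id=cid, chrom=chrom, strand=strand, start=start, end=end,
                       support=2, gtag_ok=True)


@pytest.fixture(scope="module")
def toy_models():
    """Hand-built annotation on a 50-kb toy chromosome (both strands)."""
    m1 = GeneModel("GA", "GA.1", "chr1", "+",
                   exons=[(1_000, 1_200), (1_500, 1_700), (2_000, 2_300),
                          (2_600, 2_800)])
    partition_transcript(m1, 150, 250)  # 5'UTR into exon 1, 3'UTR into exon 4
    m2 = GeneModel("GB", "GB.1", "chr1", "-",
                   exons=[(5_000, 5_300), (5_600, 5_900), (6_200, 6_500)])
    partition_transcript(m2, 100, 100)
    m3 = GeneModel("GC", "GC.1", "chr1", "+",
                   exons=[(8_000, 8_400), (8_700, 9_000)], biotype="ncRNA")
    m4 = GeneModel("GD", "GD.1", "chr1", "+",
                   exons=[(12_000, 12_300), (12_600, 12_900)])
    partition_transcript(m4, 50, 50)
    # antisense gene fully covering GA's neighbourhood
    m5 = GeneModel("GE", "GE.1", "chr1", "-", exons=[(900, 3_000)],
                   biotype="ncRNA")
    return [m1, m2, m3, m4, m5]


@pytest.fixture(scope="module")
def mindex(toy_models):
    return ModelIndex(toy_models)


# ---------------------------------------------------------------------------
# Per-base oracle
# ---------------------------------------------------------------------------

def oracle_label(models, chrom, strand, pos):
    """Independent per-base labeling: scan every feature interval."""
    best = "intergenic"
    rank = {"intergenic": 0, "intron": 1, "ncRNA": 2, "3UTR": 2, "5UTR": 2,
            "CDS": 2}
    for m in models:
        if m.chrom != chrom or m.strand != strand:
            continue
        if not (m.start <= pos < m.end):
            continue
        label = "intron"
        for a, b in m.exons:
            if a <= pos < b:
                label = "ncRNA" if m.biotype == "ncRNA" else "CDS"
                if m.biotype != "ncRNA":
                    for name, ivs in (("CDS", m.cds), ("5UTR", m.utr5),
                                      ("3UTR", m.utr3)):
                        if any(s <= pos < e for s, e in ivs):
                            label = name
                break
        if rank[label] >= rank[best]:
            best = label if best == "intergenic" or rank[label] > rank[best] \
                else best
    return best


def test_endpoint_labels_match_per_base_oracle(toy_models, rng):
    """classify's endpoint labels agree with an exhaustive per-base map for
    endpoints swept across the toy annotation."""
    mindex = ModelIndex(toy_models)
    positions = list(rng.integers(500, 13_500, size=300))
    positions += [1_000, 1_199, 1_350, 1_500, 2_799, 5_000, 6_499, 8_000,
                  11_000, 12_000]
    for pos in map(int, positions):
        for strand in "+-":
            call = call_at("chr1", strand, pos, pos + 10_000)
            ann = classify(call, mindex)
            if ann.best_transcript is None:
                continue
            model = mindex.by_id[ann.best_transcript]
            got = ann.endpoint_labels[0]
            assert got == endpoint_label(model, pos)
            # the oracle agrees whenever the endpoint's own label is decided
            # by the best transcript (single-gene loci here)
            oracle = oracle_label(toy_models, "chr1", strand, pos)
            if got != "intergenic" and oracle != "intergenic":
                assert got == oracle


@pytest.mark.parametrize("start,end,strand,category,exonic", [
    (1_160, 2_100, "+", "CDS-CDS", True),          # both in CDS exons of GA
    (1_000, 2_799, "+", "5UTR-3UTR", True),        # UTR ends of GA
    (1_050, 2_200, "+", "5UTR-CDS", True),
    (30_000, 31_000, "+", "intergenic", False),    # no gene at all
    (1_300, 2_100, "+", "exon-intron", False),     # intron..CDS
    (1_250, 1_450, "+", "intron", False),          # fully intronic
    (8_100, 8_900, "+", "ncRNA", True),            # ncRNA host
    (2_100, 3_500, "+", "CDS-intergenic", False),
    (5_700, 6_399, "-", "CDS-CDS", True),          # minus-strand gene
    (1_100, 12_700, "+", "cross-genic", False),    # GA .. GD
])
def test_categories(mindex, start, end, strand, category, exonic):
    ann = classify(call_at("chr1", strand, start, end), mindex)
    assert ann.category == category
    assert ann.exonic is exonic


def test_minus_strand_sense_ordering(mindex):
    """On '-', the sense-5' endpoint is the genomic right one: a circle from
    GB's 3'UTR (genomic left) to CDS reads CDS-3UTR, not 3UTR-CDS."""
    ann = classify(call_at("chr1", "-", 5_050, 6_300), mindex)
    assert ann.endpoint_labels == ("3UTR", "CDS")
    assert ann.category == "CDS-3UTR"


def test_antisense_overlap_reported(mindex):
    ann = classify(call_at("chr1", "+", 1_000, 2_799), mindex)
    assert ann.antisense_genes == ["GE"]
    ann2 = classify(call_at("chr1", "+", 12_000, 12_899), mindex)
    assert ann2.antisense_genes == []


def test_category_is_a_partition(mindex, rng):
    for _ in range(200):
        s = int(rng.integers(0, 14_000))
        e = s + int(rng.integers(50, 8_000))
        ann = classify(call_at("chr1", "+", s, e), mindex)
        assert isinstance(ann.category, str) and ann.category


class TestKnownSites:
    def test_whole_exon_circle_scores_two(self, mindex, toy_models):
        m1 = toy_models[0]
        call = call_at("chr1", "+", m1.exons[1][0], m1.exons[2][1] - 1)
        assert classify(call, mindex).known_sites == 2

    def test_shifted_acceptor_scores_one(self, mindex, toy_models):
        m1 = toy_models[0]
        call = call_at("chr1", "+", m1.exons[1][0] + 3, m1.exons[2][1] - 1)
        assert classify(call, mindex).known_sites == 1

    def test_random_interior_scores_zero(self, toy_models):
        m1 = toy_models[0]
        assert known_site_score(call_at("chr1", "+", 1_550, 2_100), m1) == 0

    def test_terminal_boundaries_not_splice_sites(self, toy_models):
        """Transcript-terminal exon edges have no flanking intron and do
        not count as known splice sites."""
        m1 = toy_models[0]
        call = call_at("chr1", "+", m1.exons[0][0], m1.exons[-1][1] - 1)
        assert known_site_score(call, m1) == 0


def test_alternative_backsplicing_histogram():
    def ann(gene, key_i):
        call = call_at("chr1", "+", key_i * 10, key_i * 10 + 5, cid=f"{gene}.{key_i}")
        return AnnotatedCirc(call, "CDS-CDS", True, parental_genes=[gene])

    annotated = []
    counts = {"g2": 2, "g3": 3, "g4": 4, "g5": 6, "g1": 1}
    i = 0
    for gene, n in counts.items():
        for _ in range(n):
            i += 1
            annotated.append(ann(gene, i))
    out = alternative_backsplicing(annotated)
    assert out["n_genes_multi"] == 4
    assert out["histogram"] == {"2": 1, "3": 1, "4": 1, "5+": 1}
    assert out["n_events_isoforms"] == 15
    assert out["n_events_extra"] == 11
    assert "g1" not in out["groups"]


def test_summarize_hand_computed(toy_models):
    """A circle over GA exons 2-4 spans 3 exons; its trimmed length is the
    sum of overlapped exon pieces."""
    mindex = ModelIndex(toy_models)
    m1 = toy_models[0]
    start = m1.exons[1][0] + 20          # trimmed into exon 2
    end = m1.exons[3][1] - 1 - 30        # trimmed into exon 4
    ann = classify(call_at("chr1", "+", start, end), mindex)
    assert ann.exon_span == 3
    expected_len = (m1.exons[1][1] - start) + (m1.exons[2][1] - m1.exons[2][0]) \
        + (end + 1 - m1.exons[3][0])
    assert ann.exonic_length == expected_len

    single = classify(call_at("chr1", "+", 2_050, 2_250), mindex)
    assert single.exon_span == 1
    assert single.exonic_length == 2_250 - 2_050 + 1

    report = summarize([ann, single], toy_models)
    assert report["n_exonic"] == 2
    assert report["exon_span_hist"] == {3: 1, 1: 1}
    assert report["mean_exonic_length"] == (ann.exonic_length + 201) / 2
    assert sum(report["categories"].values()) == report["n_calls"] == 2


def test_containment_in_transcripts_brute_force(rng):
    transcripts = []
    for i in range(30):
        s = int(rng.integers(0, 40_000))
        transcripts.append((f"t{i}", "chr1", s, s + int(rng.integers(200, 5_000)),
                            "+" if rng.random() < 0.5 else "-"))
    calls = []
    for i in range(40):
        s = int(rng.integers(0, 42_000))
        calls.append(call_at("chr1", "+" if rng.random() < 0.5 else "-",
                             s, s + int(rng.integers(50, 3_000)), cid=f"c{i}"))
    got = sorted(containment_in_transcripts(calls, transcripts))
    expected = sorted(
        (c.id, tid)
        for c in calls
        for tid, chrom, s, e, strand in transcripts
        if chrom == c.chrom and strand == c.strand and s <= c.start and c.end < e)
    assert got == expected
    assert expected  # the construction produced at least one contained pair
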