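"""Annotation of circRNA calls against gene models.

Each call's two backsplice endpoints are labeled by the sense-strand
feature containing them (CDS, 5'UTR, 3'UTR, ncRNA exon, intron or
intergenic) in the best matching transcript, giving a genomic-origin
category; calls are scored for known (annotated) splice sites, flagged for
antisense gene overlap, grouped into alternative-backsplicing isoform
families per parental gene, and summarized (exon spans, trimmed exonic
lengths, category counts).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .circ_calling import CircRNACall
from .io_core import GeneModel

log = logging.getLogger("ricircle")

EXONIC_LABELS = {"CDS", "5UTR", "3UTR", "ncRNA"}


@dataclass
class AnnotatedCirc:
    """A call with its genomic-origin classification."""

    call: CircRNACall
    category: str
    exonic: bool
    known_sites: int = 0
    parental_genes: list[str] = field(default_factory=list)
    antisense_genes: list[str] = field(default_factory=list)
    best_transcript: str | None = None
    endpoint_labels: tuple[str, str] = ("intergenic", "intergenic")
    exon_span: int = 0
    exonic_length: int = 0


# ---------------------------------------------------------------------------
# Indexing and per-endpoint labels
# ---------------------------------------------------------------------------

class ModelIndex:
    """Interval lookups over transcripts, split by chromosome and strand."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self.by_id = {m.transcript_id: m for m in models}
        self._span_trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            tree = self._span_trees.setdefault((m.chrom, m.strand), IntervalTree())
            tree.addi(m.start, m.end, m)

    def overlapping(self, chrom: str, strand: str, start: int, end: int
                    ) -> list[GeneModel]:
        tree = self._span_trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda m: m.transcript_id)

    def containing(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        return self.overlapping(chrom, strand, pos, pos + 1)


def endpoint_label(model: GeneModel, pos: int) -> str:
    """Feature label of a position within one transcript (sense strand)."""
    if not (model.start <= pos < model.end):
        return "intergenic"
    in_exon = any(a <= pos < b for a, b in model.exons)
    if not in_exon:
        return "intron"
    if model.biotype == "ncRNA":
        return "ncRNA"
    if any(a <= pos < b for a, b in model.cds):
        return "CDS"
    if any(a <= pos < b for a, b in model.utr5):
        return "5UTR"
    if any(a <= pos < b for a, b in model.utr3):
        return "3UTR"
    return "CDS"  # exon base not partitioned (degenerate model): treat as coding


def _overlap_len(model: GeneModel, start: int, end: int) -> int:
    return max(0, min(model.end, end) - max(model.start, start))


# ---------------------------------------------------------------------------
# classify
# ---------------------------------------------------------------------------

def classify(call: CircRNACall, mindex: ModelIndex) -> AnnotatedCirc:
    """Assign the genomic-origin category of one call.

    The best matching transcript maximizes (number of endpoints it
    explains, span overlap length); endpoints in two different genes with
    no shared transcript give ``cross-genic``.  Category names join the
    two endpoint labels in transcript-sense order (the sense-5' endpoint
    first), e.g. ``CDS-CDS``, ``5UTR-CDS``, ``CDS-intergenic``; fully
    intronic calls are ``intron``, ncRNA-hosted exonic calls ``ncRNA``.
    ``exonic`` requires both endpoints in exon features of one transcript.
    """
    left, right = call.start, call.end
    span = (left, right + 1)
    candidates = mindex.overlapping(call.chrom, call.strand, *span)

    antisense = sorted({m.gene_id for m in mindex.overlapping(
        call.chrom, "-" if call.strand == "+" else "+", *span)
        if m.start <= left and right < m.end})

    if not candidates:
        return AnnotatedCirc(call, "intergenic", False,
                             antisense_genes=antisense)

    def explained(m: GeneModel) -> int:
        return sum(endpoint_label(m, p) != "intergenic" for p in (left, right))

    best = max(candidates,
               key=lambda m: (explained(m), _overlap_len(m, *span), m.transcript_id))
    l_left = endpoint_label(best, left)
    l_right = endpoint_label(best, right)

    genes_left = {m.gene_id for m in mindex.containing(call.chrom, call.strand, left)}
    genes_right = {m.gene_id for m in mindex.containing(call.chrom, call.strand, right)}
    if genes_left and genes_right and not (genes_left & genes_right):
        return AnnotatedCirc(call, "cross-genic", False,
                             parental_genes=sorted(genes_left | genes_right),
                             antisense_genes=antisense,
                             best_transcript=best.transcript_id,
                             endpoint_labels=(l_left, l_right))

    # sense order: the acceptor-side (5' in the circle's sense) endpoint first
    if call.strand == "+":
        l1, l2 = l_left, l_right
    else:
        l1, l2 = l_right, l_left

    exonic = l_left in EXONIC_LABELS and l_right in EXONIC_LABELS
    if l1 == "intergenic" and l2 == "intergenic":
        category = "intergenic"
    elif l1 == "intergenic" or l2 == "intergenic":
        other = l2 if l1 == "intergenic" else l1
        category = f"{other}-intergenic"
    elif l1 == "ncRNA" or l2 == "ncRNA":
        category = "ncRNA" if exonic else "exon-intron"
    elif l1 == "intron" and l2 == "intron":
        category = "intron"
    elif "intron" in (l1, l2):
        category = "exon-intron"
    else:
        category = f"{l1}-{l2}"

    ann = AnnotatedCirc(call, category, exonic,
                        parental_genes=sorted(genes_left | genes_right) or
                        [best.gene_id],
                        antisense_genes=antisense,
                        best_transcript=best.transcript_id,
                        endpoint_labels=(l_left, l_right))
    if exonic:
        overlaps = [(max(a, left), min(b, right + 1)) for a, b in best.exons
                    if a < right + 1 and b > left]
        ann.exon_span = len(overlaps)
        ann.exonic_length = sum(b - a for a, b in overlaps if b > a)
    ann.known_sites = known_site_score(call, best)
    return ann


def known_site_score(call: CircRNACall, model: GeneModel) -> int:
    """How many call endpoints coincide with genuine annotated splice sites.

    The left endpoint must equal an exon start that has an intron on its
    genomic left; the right endpoint an exon end (inclusive) with an
    intron on its genomic right — i.e. boundaries a spliceosome actually
    uses, in circle orientation, in the best matching transcript.
    """
    score = 0
    ex = model.exons
    for idx, (a, b) in enumerate(ex):
        if call.start == a and idx > 0:
            score += 1
            break
    for idx, (a, b) in enumerate(ex):
        if call.end == b - 1 and idx < len(ex) - 1:
            score += 1
            break
    return score


# ---------------------------------------------------------------------------
# Alternative backsplicing
# ---------------------------------------------------------------------------

def alternative_backsplicing(annotated: Sequence[AnnotatedCirc]) -> dict[str, object]:
    """Group exonic calls by parental gene and count isoform families.

    Reports genes producing 2, 3, 4 and >=5 distinct junctions, plus two
    event counters (the literature does not pin down the definition):
    ``n_events_isoforms`` counts every isoform of a multi-isoform gene,
    ``n_events_extra`` counts isoforms beyond the first per gene.
    """
    per_gene: dict[str, set] = {}
    for ann in annotated:
        if not ann.exonic or not ann.parental_genes:
            continue
        gene = ann.parental_genes[0]
        per_gene.setdefault(gene, set()).add(ann.call.key)
    multi = {g: len(ks) for g, ks in per_gene.items() if len(ks) >= 2}
    hist = {"2": 0, "3": 0, "4": 0, "5+": 0}
    for k in multi.values():
        hist[str(k) if k <= 4 else "5+"] += 1
    return {
        "n_genes_multi": len(multi),
        "histogram": hist,
        "n_events_isoforms": sum(multi.values()),
        "n_events_extra": sum(k - 1 for k in multi.values()),
        "groups": multi,
    }


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(annotated: Sequence[AnnotatedCirc],
              models: Sequence[GeneModel]) -> dict[str, object]:
    """Category counts, exon-span histogram and trimmed exonic lengths."""
    by_id = {m.transcript_id: m for m in models}
    categories = Counter(a.category for a in annotated)
    exonic = [a for a in annotated if a.exonic]
    span_hist = Counter(a.exon_span for a in exonic)
    n_span = sum(span_hist.values())
    frac_1_4 = (sum(v for k, v in span_hist.items() if 1 <= k <= 4) / n_span
                if n_span else 0.0)
    lengths = [a.exonic_length for a in exonic]
    parent_exons = Counter(
        by_id[a.best_transcript].n_exons for a in exonic
        if a.best_transcript in by_id)
    return {
        "n_calls": len(annotated),
        "categories": dict(categories),
        "n_exonic": len(exonic),
        "exon_span_hist": dict(span_hist),
        "frac_span_1_4": frac_1_4,
        "mean_exonic_length": (sum(lengths) / len(lengths)) if lengths else 0.0,
        "parental_exon_hist": dict(parent_exons),
        "known_sites_hist": dict(Counter(a.known_sites for a in annotated)),
    }


def containment_in_transcripts(
    calls: Sequence[CircRNACall],
    transcripts: Sequence[tuple[str, str, int, int, str]],
) -> list[tuple[str, str]]:
    """Pairs (call id, transcript id) where the call lies fully inside a
    same-strand transcript span.

    ``transcripts`` rows are (id, chrom, start, end, strand), half-open.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for tid, chrom, start, end, strand in transcripts:
        trees.setdefault((chrom, strand), IntervalTree()).addi(start, end, tid)
    out: list[tuple[str, str]] = []
    for c in calls:
        tree = trees.get((c.chrom, c.strand))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(c.start, c.end + 1)):
            if iv.begin <= c.start and c.end < iv.end:
                out.append((c.id, iv.data))
    return out
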