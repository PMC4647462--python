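"""End-to-end detection driver: read pairs -> circRNA calls.

Mirrors the published funnel, with per-stage counters so a run can be
audited: reads screened -> partially mapped -> chiastic candidates ->
resolved junction reads -> mate-consistent junction reads -> supported,
GT..AG-flanked calls.  Both mates of every pair are examined as potential
junction-spanning reads; the pair's other read serves as the mate filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .candidate_detection import (
    CandidateRead,
    GenomeIndex,
    PipelineConfig,
    Rejection,
    colinear_prefilter,
    select_chiastic,
)
from .circ_calling import CircRNACall, mate_filter, merge_and_call
from .io_core import Genome, ReadPair
from .junction_resolution import (
    AlignmentRejection,
    BackspliceJunction,
    build_pseudo_genome,
    spliced_align,
)

log = logging.getLogger("ricircle")


@dataclass
class DetectionResult:
    calls: list[CircRNACall]
    junction_reads: list[BackspliceJunction]
    rejections: list[Rejection | AlignmentRejection]
    funnel: Counter = field(default_factory=Counter)


def detect_junction_reads(
    genome: Genome,
    index: GenomeIndex,
    pairs: Sequence[ReadPair],
    cfg: PipelineConfig,
    use_prefilter: bool = True,
    collect_rejections: bool = False,
) -> tuple[list[BackspliceJunction], list[Rejection | AlignmentRejection], Counter]:
    """Run candidate selection, junction resolution and the mate filter."""
    junctions: list[BackspliceJunction] = []
    rejections: list[Rejection | AlignmentRejection] = []
    funnel: Counter = Counter()

    def note(rej):
        funnel[f"reject:{rej.reason}"] += 1
        if collect_rejections:
            rejections.append(rej)

    for frag_id, s1, s2 in pairs:
        for suffix, read, mate in (("/1", s1, s2), ("/2", s2, s1)):
            read_id = frag_id + suffix
            funnel["reads"] += 1
            if len(read) < 2 * cfg.anchor_len:
                note(Rejection(read_id, "too-short"))
                continue
            head = read[:cfg.anchor_len]
            tail = read[-cfg.anchor_len:]
            head_hits = index.lookup(head, limit=cfg.max_anchor_hits)
            tail_hits = index.lookup(tail, limit=cfg.max_anchor_hits)
            if use_prefilter:
                verdict = colinear_prefilter(read, index, cfg,
                                             head_hits=head_hits, tail_hits=tail_hits)
                if verdict == "fully_mapped":
                    funnel["fully_mapped"] += 1
                    continue
                funnel["partially_mapped"] += 1
            cand = select_chiastic(read_id, read, index, cfg, mate=mate,
                                   head_hits=head_hits, tail_hits=tail_hits)
            if isinstance(cand, Rejection):
                note(cand)
                continue
            funnel["candidates"] += 1
            pseudo = build_pseudo_genome(cand, genome, cfg)
            res = spliced_align(cand, pseudo, genome, cfg)
            if isinstance(res, AlignmentRejection):
                note(res)
                continue
            funnel["junction_reads"] += 1
            if not mate_filter(res, mate, index, cfg):
                note(Rejection(read_id, "mate-outside"))
                continue
            funnel["mate_ok"] += 1
            junctions.append(res)
    return junctions, rejections, funnel


def detect(
    genome: Genome,
    index: GenomeIndex,
    pairs: Sequence[ReadPair],
    cfg: PipelineConfig,
    sample: str = "sample1",
    use_prefilter: bool = True,
    collect_rejections: bool = False,
) -> DetectionResult:
    """Full detection: junction reads plus merge/support/signal calling."""
    junctions, rejections, funnel = detect_junction_reads(
        genome, index, pairs, cfg, use_prefilter=use_prefilter,
        collect_rejections=collect_rejections)
    calls = merge_and_call(junctions, genome, cfg, sample=sample)
    funnel["calls"] = len(calls)
    log.info("detection funnel: %s",
             ", ".join(f"{k}={v}" for k, v in sorted(funnel.items())))
    return DetectionResult(calls=calls, junction_reads=junctions,
                           rejections=rejections, funnel=funnel)
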