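"""Chiastic candidate-read selection: stage 1 of backsplice detection.

A read spanning a backsplice junction cannot be explained by a colinear
alignment: its 5' end maps *downstream* of its 3' end on the same strand
("permuted, chiastic order").  This module screens reads with a colinear
prefilter, extracts fixed-length terminal anchors (20 bp by default), maps
them exactly against both genome strands, and accepts reads whose two
anchors hit uniquely, perfectly and chiastically on one chromosome within
a bounded genomic window (15 kb by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import Genome, revcomp

log = logging.getLogger("ricircle")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Detection-pipeline parameters.

    ``pseudo_len`` is fixed at ``2 * flank_len``: the per-read pseudo-genome
    concatenates one downstream and one upstream flank.  The defaults
    (20-bp anchors, 15-kb window, 5.1-kb flanks, >=2 supporting reads,
    GT..AG required) reproduce the published pipeline settings; the flank
    size is justified by intron/gene size distributions (effectively all
    introns < 5 kb).
    """

    anchor_len: int = 20
    max_span: int = 15_000
    flank_len: int = 5_100
    min_support: int = 2
    min_identity: float = 0.95
    require_gtag: bool = True
    junction_slack: int = 0
    max_anchor_hits: int = 50  # cap on enumerated placements per anchor
    id_prefix: str = "Os"

    def __post_init__(self) -> None:
        if self.anchor_len < 15:
            raise ValueError("anchor_len must be >= 15")
        if self.max_span <= 2 * self.anchor_len:
            raise ValueError("max_span must exceed twice the anchor length")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.junction_slack < 0:
            raise ValueError("junction_slack must be >= 0")

    @property
    def pseudo_len(self) -> int:
        return 2 * self.flank_len


# ---------------------------------------------------------------------------
# Anchor index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorHit:
    """Exact match of an anchor word: forward-strand window [pos, pos+k)."""

    chrom: str
    pos: int
    strand: str


_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


class GenomeIndex:
    """Exact-match index of all anchor-length words of a genome.

    Words are 2-bit encoded into sorted integer codes; lookups run on both
    strands and report forward-window coordinates.  Windows containing
    non-ACGT bases are excluded (and never match).  The ``verdict`` of a
    word is 'unique', 'multi' or 'absent', counting hits over both strands.
    """

    def __init__(self, genome: Genome, anchor_len: int = 20):
        if anchor_len < 15 or anchor_len > 31:
            raise ValueError("anchor_len must be in [15, 31] (2-bit packing)")
        self.genome = genome
        self.k = anchor_len
        codes_all, chrom_all, pos_all = [], [], []
        for ci, (name, seq) in enumerate(genome.items()):
            if len(seq) < anchor_len:
                continue
            vals = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
            n_win = len(seq) - anchor_len + 1
            codes = np.zeros(n_win, dtype=np.int64)
            for j in range(anchor_len):
                codes = (codes << 2) | vals[j:j + n_win]
            # invalidate windows containing non-ACGT bases
            bad = np.flatnonzero(vals < 0)
            valid = np.ones(n_win, dtype=bool)
            for b in bad:
                valid[max(0, b - anchor_len + 1):b + 1] = False
            codes_all.append(codes[valid])
            pos_all.append(np.flatnonzero(valid).astype(np.int64))
            chrom_all.append(np.full(int(valid.sum()), ci, dtype=np.int64))
        if not codes_all:
            raise ValueError("no chromosome is long enough for the anchor length")
        codes = np.concatenate(codes_all)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._chrom = np.concatenate(chrom_all)[order]
        self._pos = np.concatenate(pos_all)[order]
        self._names = genome.names

    def _encode(self, word: str) -> int | None:
        if len(word) != self.k:
            raise ValueError(f"word length {len(word)} != anchor length {self.k}")
        code = 0
        for ch in word.encode():
            v = _ENC[ch]
            if v < 0:
                return None
            code = (code << 2) | int(v)
        return code

    def _query(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._chrom[lo:hi], self._pos[lo:hi]

    def lookup(self, word: str, limit: int | None = None) -> list[AnchorHit]:
        """All exact hits of ``word`` on both strands (forward coordinates)."""
        hits: list[AnchorHit] = []
        fwd = self._encode(word)
        if fwd is not None:
            for c, p in zip(*self._query(fwd)):
                hits.append(AnchorHit(self._names[c], int(p), "+"))
        rc = self._encode(revcomp(word))
        if rc is not None and rc != fwd:
            for c, p in zip(*self._query(rc)):
                hits.append(AnchorHit(self._names[c], int(p), "-"))
        elif rc is not None and rc == fwd:
            # palindromic word: the same windows match both strands
            for c, p in zip(*self._query(rc)):
                hits.append(AnchorHit(self._names[c], int(p), "-"))
        if limit is not None and len(hits) > limit:
            return hits[:limit]
        return hits

    def hit_count(self, word: str) -> int:
        n = 0
        fwd = self._encode(word)
        if fwd is not None:
            n += len(self._query(fwd)[0])
        rc = self._encode(revcomp(word))
        if rc is not None:
            n += len(self._query(rc)[0])
        return n

    def verdict(self, word: str) -> str:
        n = self.hit_count(word)
        return "absent" if n == 0 else ("unique" if n == 1 else "multi")


# ---------------------------------------------------------------------------
# Candidate records
# ---------------------------------------------------------------------------

@dataclass
class CandidateRead:
    """A read accepted by chiastic selection.

    ``span`` is the genomic footprint of both anchors (leftmost window
    start to rightmost window end).
    """

    read_id: str
    sequence: str
    head_hit: AnchorHit
    tail_hit: AnchorHit
    span: int
    mate: str | None = None


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_anchors(read: str, cfg: PipelineConfig) -> tuple[str, str]:
    """First and last ``anchor_len`` bases; read must fit both without overlap."""
    k = cfg.anchor_len
    if len(read) < 2 * k:
        raise ValueError(f"read length {len(read)} < 2 x anchor length {k}")
    return read[:k], read[-k:]


def _placements_from_hits(read_len: int, k: int, head_hits: Sequence[AnchorHit],
                          tail_hits: Sequence[AnchorHit]) -> set[tuple[str, str, int]]:
    """Full-length colinear placements implied by anchor hits.

    A placement is (chrom, strand, start-of-read window on forward strand).
    """
    placements: set[tuple[str, str, int]] = set()
    for h in head_hits:
        start = h.pos if h.strand == "+" else h.pos + k - read_len
        placements.add((h.chrom, h.strand, start))
    for t in tail_hits:
        start = t.pos - (read_len - k) if t.strand == "+" else t.pos
        placements.add((t.chrom, t.strand, start))
    return placements


def _score_placement(read: str, genome: Genome, chrom: str, strand: str,
                     start: int) -> tuple[int, int, int]:
    """(matches, aligned_len, off_chrom) for an ungapped full-length placement."""
    n = len(read)
    L = genome.length(chrom)
    lo, hi = max(0, start), min(L, start + n)
    if hi <= lo:
        return 0, 0, n
    ref = genome.fetch(chrom, lo, hi)
    if strand == "-":
        # read index i maps to forward position start + n - 1 - i
        ref = revcomp(ref)
        seg = read[(start + n - hi):(start + n - lo)]
    else:
        seg = read[lo - start:hi - start]
    matches = sum(a == b for a, b in zip(seg, ref))
    return matches, hi - lo, n - (hi - lo)


def colinear_prefilter(
    read: str,
    index: GenomeIndex,
    cfg: PipelineConfig,
    head_hits: Sequence[AnchorHit] | None = None,
    tail_hits: Sequence[AnchorHit] | None = None,
) -> str:
    """Classify a read as ``fully_mapped`` or ``partially_mapped``.

    A read is fully mapped when some single ungapped colinear placement
    (seeded by either terminal anchor) covers it at >= ``min_identity``
    leaving fewer than ``anchor_len`` unaligned bases at each end; such
    reads cannot harbour a detectable backsplice and are discarded from
    the circRNA search.
    """
    k = cfg.anchor_len
    if len(read) < 2 * k:
        return "fully_mapped"  # too short for the chiastic test; caller logs
    head, tail = extract_anchors(read, cfg)
    if head_hits is None:
        head_hits = index.lookup(head, limit=cfg.max_anchor_hits)
    if tail_hits is None:
        tail_hits = index.lookup(tail, limit=cfg.max_anchor_hits)
    for chrom, strand, start in _placements_from_hits(len(read), k, head_hits, tail_hits):
        matches, aligned, off = _score_placement(read, index.genome, chrom, strand, start)
        left_off = max(0, -start)
        right_off = max(0, start + len(read) - index.genome.length(chrom))
        if (left_off < k and right_off < k and aligned > 0
                and matches / len(read) >= cfg.min_identity):
            return "fully_mapped"
    return "partially_mapped"


def select_chiastic(
    read_id: str,
    read: str,
    index: GenomeIndex,
    cfg: PipelineConfig,
    mate: str | None = None,
    head_hits: Sequence[AnchorHit] | None = None,
    tail_hits: Sequence[AnchorHit] | None = None,
) -> CandidateRead | Rejection:
    """Accept a read whose anchors map uniquely, perfectly and chiastically.

    Acceptance requires: both anchors unique over both strands; same
    chromosome and strand; permuted order (on '+', the head anchor starts
    downstream of the tail anchor; mirrored on '-'); anchor footprint
    within ``max_span``.  Rejections carry a machine-readable reason.
    """
    k = cfg.anchor_len
    if len(read) < 2 * k:
        return Rejection(read_id, "too-short")
    head, tail = extract_anchors(read, cfg)
    if head_hits is None:
        head_hits = index.lookup(head, limit=cfg.max_anchor_hits)
    if tail_hits is None:
        tail_hits = index.lookup(tail, limit=cfg.max_anchor_hits)
    if len(head_hits) == 0 or len(tail_hits) == 0:
        return Rejection(read_id, "no-hit")
    if len(head_hits) > 1 or len(tail_hits) > 1:
        return Rejection(read_id, "multi-hit")
    h, t = head_hits[0], tail_hits[0]
    if h.chrom != t.chrom:
        return Rejection(read_id, "cross-chrom")
    if h.strand != t.strand:
        return Rejection(read_id, "strand-mismatch")
    if h.strand == "+":
        chiastic = h.pos > t.pos
    else:
        chiastic = h.pos < t.pos
    if not chiastic:
        return Rejection(read_id, "colinear-order")
    span = max(h.pos, t.pos) + k - min(h.pos, t.pos)
    if span > cfg.max_span:
        return Rejection(read_id, "span-exceeded")
    return CandidateRead(read_id=read_id, sequence=read, head_hit=h,
                         tail_hit=t, span=span, mate=mate)
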