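"""Pseudo-genome spliced alignment: stage 2 of backsplice detection.

For each chiastic candidate, the genomic flank *downstream* of the head
anchor and the flank *upstream* of the tail anchor are reverse-assembled
(downstream block first) into a per-read pseudo-genome, so that the
backsplice becomes an ordinary forward splice and the read can be aligned
as cDNA-to-genome.  The aligner splits the read into a 5' segment anchored
at the start of block D and a 3' segment anchored at the end of block U,
scans every split point, and prefers splits whose back-transformed genomic
junction is flanked by the canonical GT..AG signal (leftmost split on
remaining ties).  Junction coordinates are then mapped back to the genome
through the invertible block descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .candidate_detection import CandidateRead, PipelineConfig
from .io_core import Genome, backsplice_signal_ok, revcomp

log = logging.getLogger("ricircle")


# ---------------------------------------------------------------------------
# Pseudo-genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One pseudo-genome block: an oriented genomic window.

    ``fstart``/``fend`` delimit the forward-strand window; for '-' blocks
    the block content is the reverse complement of that window, so pseudo
    offset ``o`` maps to forward position ``fend - 1 - o``.
    """

    chrom: str
    fstart: int
    fend: int
    strand: str

    @property
    def length(self) -> int:
        return self.fend - self.fstart

    def to_genome(self, offset: int) -> int:
        if not (0 <= offset < self.length):
            raise IndexError(f"offset {offset} outside block of length {self.length}")
        if self.strand == "+":
            return self.fstart + offset
        return self.fend - 1 - offset

    def from_genome(self, fpos: int) -> int:
        if not (self.fstart <= fpos < self.fend):
            raise IndexError(f"position {fpos} outside block window")
        if self.strand == "+":
            return fpos - self.fstart
        return self.fend - 1 - fpos


@dataclass
class PseudoGenome:
    """Reverse-assembled reference for one candidate: block D then block U."""

    seq: str
    block_d: Block
    block_u: Block

    @property
    def len_d(self) -> int:
        return self.block_d.length

    @property
    def len_u(self) -> int:
        return self.block_u.length

    def to_genome(self, pseudo_pos: int) -> tuple[str, int]:
        """Map a pseudo coordinate to (chrom, forward position)."""
        if pseudo_pos < self.len_d:
            return self.block_d.chrom, self.block_d.to_genome(pseudo_pos)
        off = pseudo_pos - self.len_d
        if off < self.len_u:
            return self.block_u.chrom, self.block_u.to_genome(off)
        raise IndexError(f"pseudo position {pseudo_pos} outside both blocks")

    def from_genome(self, fpos: int, block: str) -> int:
        """Inverse map; ``block`` selects 'D' or 'U'."""
        if block == "D":
            return self.block_d.from_genome(fpos)
        if block == "U":
            return self.len_d + self.block_u.from_genome(fpos)
        raise ValueError(f"unknown block {block!r}")


def build_pseudo_genome(candidate: CandidateRead, genome: Genome,
                        cfg: PipelineConfig) -> PseudoGenome:
    """Concatenate the downstream and upstream flanks of a candidate.

    On '+': block D starts at the head-anchor start H and extends
    ``flank_len`` bases downstream; block U ends at the tail-anchor end
    (T + anchor_len) and extends ``flank_len`` bases upstream.  On '-' the
    construction is mirrored on the reverse complement.  Blocks are
    truncated (never padded) at chromosome edges, so the total length is
    at most ``pseudo_len`` and exactly ``pseudo_len`` away from the edges.
    """
    k = cfg.anchor_len
    fl = cfg.flank_len
    h, t = candidate.head_hit, candidate.tail_hit
    chrom = h.chrom
    L = genome.length(chrom)
    if h.strand == "+":
        d = Block(chrom, h.pos, min(L, h.pos + fl), "+")
        u = Block(chrom, max(0, t.pos + k - fl), t.pos + k, "+")
        seq = genome.fetch(chrom, d.fstart, d.fend) + genome.fetch(chrom, u.fstart, u.fend)
    else:
        d = Block(chrom, max(0, h.pos + k - fl), h.pos + k, "-")
        u = Block(chrom, t.pos, min(L, t.pos + fl), "-")
        seq = revcomp(genome.fetch(chrom, d.fstart, d.fend)) + \
            revcomp(genome.fetch(chrom, u.fstart, u.fend))
    if d.length < fl or u.length < fl:
        log.debug("pseudo-genome truncated at chromosome edge (%d + %d bases)",
                  d.length, u.length)
    return PseudoGenome(seq, d, u)


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------

@dataclass
class BackspliceJunction:
    """A resolved backsplice in normalized genomic coordinates.

    ``acceptor`` is the leftmost and ``donor`` the rightmost base of the
    circle on the forward strand (``acceptor <= donor``); for '-' circles
    the sense-strand donor/acceptor roles are swapped relative to these
    names.
    """

    chrom: str
    strand: str
    acceptor: int
    donor: int
    read_id: str
    aligned_fraction: float
    gtag_ok: bool

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.acceptor, self.donor)


@dataclass(frozen=True)
class AlignmentRejection:
    read_id: str
    reason: str


def _junction_from_split(candidate: CandidateRead, pseudo: PseudoGenome,
                         split: int) -> tuple[int, int]:
    """Normalized (acceptor, donor) forward positions for a read split."""
    n = len(candidate.sequence)
    donor_chrom, g1 = pseudo.to_genome(split - 1)                   # last 5'-segment base
    _, g2 = pseudo.to_genome(pseudo.len_d + pseudo.len_u - (n - split))  # first 3'-segment base
    return (min(g1, g2), max(g1, g2))


def back_transform(pseudo_pos: int, pseudo: PseudoGenome) -> tuple[str, int]:
    """Genomic (chrom, forward position) of a pseudo coordinate."""
    return pseudo.to_genome(pseudo_pos)


def spliced_align(candidate: CandidateRead, pseudo: PseudoGenome,
                  genome: Genome, cfg: PipelineConfig
                  ) -> BackspliceJunction | AlignmentRejection:
    """Resolve the backsplice by exhaustive split-point scanning.

    The 5' segment ``read[:s]`` is aligned ungapped from the start of
    block D, the 3' segment ``read[s:]`` ungapped to the end of block U;
    the split ``s`` maximizing total matches wins.  Accepted when
    ``matches / len(read) >= min_identity``.  Among tied splits (junction
    homology) a split whose genomic junction carries the GT..AG signal is
    preferred, then the leftmost in read coordinates.
    """
    read = candidate.sequence
    n = len(read)
    k = cfg.anchor_len
    len_d, len_u = pseudo.len_d, pseudo.len_u
    d_seq = pseudo.seq[:len_d]
    u_seq = pseudo.seq[len_d:]

    # prefix matches of read vs block D, suffix matches vs block U end
    lim1 = min(n, len_d)
    m1 = [0] * (n + 1)
    for i in range(lim1):
        m1[i + 1] = m1[i] + (read[i] == d_seq[i])
    for i in range(lim1, n):
        m1[i + 1] = m1[i]
    lim2 = min(n, len_u)
    m2 = [0] * (n + 1)
    for j in range(lim2):
        m2[j + 1] = m2[j] + (read[n - 1 - j] == u_seq[len_u - 1 - j])
    for j in range(lim2, n):
        m2[j + 1] = m2[j]

    splits = [s for s in range(k, n - k + 1)
              if s <= len_d and (n - s) <= len_u]
    if not splits:
        return AlignmentRejection(candidate.read_id, "no-valid-split")
    scores = {s: min(m1[s], s) + m2[n - s] for s in splits}
    # m1 already caps at lim1; min() above is defensive for truncated blocks
    best = max(scores.values())
    if best / n < cfg.min_identity:
        return AlignmentRejection(candidate.read_id, "low-identity")
    ties = sorted(s for s, v in scores.items() if v == best)

    strand = candidate.head_hit.strand
    chosen = None
    chosen_sig = False
    for s in ties:
        acc, don = _junction_from_split(candidate, pseudo, s)
        if backsplice_signal_ok(genome, candidate.head_hit.chrom, acc, don, strand):
            chosen, chosen_sig = s, True
            break
    if chosen is None:
        chosen = ties[0]
    acc, don = _junction_from_split(candidate, pseudo, chosen)
    if not chosen_sig:
        chosen_sig = backsplice_signal_ok(genome, candidate.head_hit.chrom,
                                          acc, don, strand)
    return BackspliceJunction(
        chrom=candidate.head_hit.chrom, strand=strand, acceptor=acc, donor=don,
        read_id=candidate.read_id, aligned_fraction=best / n, gtag_ok=chosen_sig)
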