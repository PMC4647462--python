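"""Mechanism and function analyses around called circRNAs.

Three analyses: (1) inverted-repeat detection — maximal exact
reverse-complement matches (>= 18 bp by default) between the 500-bp
genomic flanks of a backsplice, the signature of intron-pairing-driven
circularization; (2) MITE overlap — a call is flagged when *both* flanks
overlap a miniature inverted-repeat transposable element; (3) rule-based
miRNA target-mimic prediction on circular exonic sequences: perfect
seed pairing (miRNA positions 2-8), exactly one 3-nt bulge on the circRNA
side opposite miRNA positions 9-12, no other gaps, and at most 3 weighted
mismatches elsewhere with G:U counted as 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .circ_calling import CircRNACall
from .io_core import Genome, revcomp

log = logging.getLogger("ricircle")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FlankConfig:
    flank_window: int = 500
    min_complement: int = 18
    mite_min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.min_complement > self.flank_window:
            raise ValueError("min_complement cannot exceed flank_window")
        if self.flank_window < 1 or self.mite_min_overlap < 1:
            raise ValueError("window and overlap must be positive")


@dataclass
class MimicConfig:
    """Target-mimic pairing rules.

    miRNA positions are 1-based from the 5' end.  ``seed_lo..seed_hi``
    must pair perfectly; the single ``bulge_len``-nt bulge sits on the
    circRNA side between miRNA positions ``bulge_lo`` and ``bulge_hi``;
    weighted mismatches outside the bulge are capped at ``max_mismatch``
    with G:U wobbles costing ``gu_weight``.
    """

    seed_lo: int = 2
    seed_hi: int = 8
    bulge_len: int = 3
    bulge_lo: int = 9
    bulge_hi: int = 12
    max_mismatch: float = 3.0
    gu_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.seed_hi >= self.bulge_lo:
            raise ValueError("seed region must end before the bulge region")
        if self.gu_weight < 0 or self.max_mismatch < 0:
            raise ValueError("weights must be >= 0")


# ---------------------------------------------------------------------------
# Flanking complementary sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplementPair:
    """A maximal reverse-complement match between the two flanks.

    ``up_start``/``down_start`` are genomic forward-strand positions of
    the match in the upstream and downstream flank; ``length`` >=
    ``min_complement``; ``seq`` is the upstream-flank forward sequence.
    """

    up_start: int
    down_start: int
    length: int
    seq: str


def find_flanking_complements(call: CircRNACall, genome: Genome,
                              cfg: FlankConfig) -> list[ComplementPair]:
    """Maximal exact reverse-complement matches between backsplice flanks.

    The upstream flank is the ``flank_window`` bases before the acceptor,
    the downstream flank the same window after the donor (both truncated
    at chromosome ends).  A hit of length L means an L-mer of the upstream
    flank whose reverse complement occurs in the downstream flank — an
    inverted repeat bracketing the circle.
    """
    w = cfg.flank_window
    up_g0 = max(0, call.start - w)
    up = genome.fetch(call.chrom, up_g0, call.start)
    down_g0 = call.end + 1
    down = genome.fetch(call.chrom, down_g0, down_g0 + w)
    k = cfg.min_complement
    if len(up) < k or len(down) < k:
        return []
    rcd = revcomp(down)  # match up vs rcd as plain common substrings

    seeds: dict[str, list[int]] = {}
    for i in range(len(up) - k + 1):
        seeds.setdefault(up[i:i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()
    for j in range(len(rcd) - k + 1):
        word = rcd[j:j + k]
        for i in seeds.get(word, ()):
            a, b = i, j
            while a > 0 and b > 0 and up[a - 1] == rcd[b - 1]:
                a -= 1
                b -= 1
            e1, e2 = i + k, j + k
            while e1 < len(up) and e2 < len(rcd) and up[e1] == rcd[e2]:
                e1 += 1
                e2 += 1
            found.add((a, b, e1 - a))
    out = []
    for a, b, ln in sorted(found):
        # rcd interval [b, b+ln) maps to down interval [len(down)-b-ln, len(down)-b)
        down_local = len(down) - b - ln
        out.append(ComplementPair(up_start=up_g0 + a,
                                  down_start=down_g0 + down_local,
                                  length=ln, seq=up[a:a + ln]))
    return out


# ---------------------------------------------------------------------------
# MITE overlap
# ---------------------------------------------------------------------------

def mite_overlap(calls: Sequence[CircRNACall],
                 mites: Sequence[tuple[str, int, int, str]],
                 cfg: FlankConfig) -> list[str]:
    """IDs of calls whose *both* flanks overlap a MITE interval.

    ``mites`` are BED-style (chrom, start, end, name) half-open intervals;
    an overlap of at least ``mite_min_overlap`` bases with each of the two
    ``flank_window`` windows is required.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _name in mites:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def flank_hit(chrom: str, lo: int, hi: int) -> bool:
        tree = trees.get(chrom)
        if tree is None or hi <= lo:
            return False
        return any(min(iv.end, hi) - max(iv.begin, lo) >= cfg.mite_min_overlap
                   for iv in tree.overlap(lo, hi))

    w = cfg.flank_window
    flagged = []
    for c in calls:
        up = (max(0, c.start - w), c.start)
        down = (c.end + 1, c.end + 1 + w)
        if flank_hit(c.chrom, *up) and flank_hit(c.chrom, *down):
            flagged.append(c.id)
    return flagged


# ---------------------------------------------------------------------------
# miRNA target mimics
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pair_cost(m: str, t: str, gu_weight: float) -> float:
    """0 for Watson-Crick, gu_weight for G:U wobble, 1 otherwise."""
    if _COMP.get(m) == t:
        return 0.0
    if (m == "G" and t == "T") or (m == "T" and t == "G"):
        return gu_weight
    return 1.0


@dataclass(frozen=True)
class MimicSite:
    """One predicted miRNA-binding site on a circular sequence."""

    circ_id: str
    mirna_id: str
    position: int          # offset of the site's 5' end on the circle
    bulge_after: int       # miRNA position after which the bulge sits
    weighted_mismatches: float
    diagram: str


def _site_alignment(mirna: str, target: str, bulge_after: int,
                    cfg: MimicConfig) -> float | None:
    """Weighted mismatches for one bulge placement, or None if seed fails.

    ``target`` has length len(miRNA) + bulge_len and is given 5'->3'; the
    miRNA pairs antiparallel, so miRNA position p meets the target's
    p-th base from the 3' end, shifted by the bulge beyond ``bulge_after``.
    """
    L = len(mirna)
    t_rev = target[::-1]
    cost = 0.0
    for p in range(1, L + 1):
        ti = (p - 1) if p <= bulge_after else (p - 1 + cfg.bulge_len)
        c = _pair_cost(mirna[p - 1], t_rev[ti], cfg.gu_weight)
        if cfg.seed_lo <= p <= cfg.seed_hi:
            if c > 0.0:
                return None  # seed must be perfectly Watson-Crick paired
        else:
            cost += c
    return cost


def _diagram(mirna: str, target: str, bulge_after: int, cfg: MimicConfig) -> str:
    t_rev = target[::-1]
    marks = []
    for p in range(1, len(mirna) + 1):
        ti = (p - 1) if p <= bulge_after else (p - 1 + cfg.bulge_len)
        c = _pair_cost(mirna[p - 1], t_rev[ti], cfg.gu_weight)
        marks.append("|" if c == 0.0 else ("o" if c < 1.0 else "."))
        if p == bulge_after:
            marks.append("(" + t_rev[p:p + cfg.bulge_len][::-1] + ")")
    return f"5'-{mirna}-3' :: {''.join(marks)}"


def predict_mimics(circ_id: str, circ_seq: str,
                   mirnas: Sequence[tuple[str, str]],
                   cfg: MimicConfig | None = None,
                   wrap: bool = True) -> list[MimicSite]:
    """Scan a circular exonic sequence for miRNA target-mimic sites.

    ``mirnas`` are (id, sequence 5'->3'); U/T are normalized.  The scan
    wraps across the backsplice by default (sites may span the junction).
    Rules: perfect Watson-Crick seed at miRNA positions ``seed_lo..seed_hi``;
    exactly one ``bulge_len``-nt bulge on the circRNA side between miRNA
    positions ``bulge_lo`` and ``bulge_hi``; no other gap; weighted
    mismatches elsewhere <= ``max_mismatch`` (G:U = ``gu_weight``).  At
    most one site is emitted per circle offset — the bulge placement with
    the fewest weighted mismatches (smallest placement on ties).
    """
    cfg = cfg or MimicConfig()
    sites: list[MimicSite] = []
    S = circ_seq.upper().replace("U", "T")
    n = len(S)
    for mid, mseq in mirnas:
        m = mseq.upper().replace("U", "T")
        L = len(m)
        if L < cfg.bulge_hi + 2:
            log.warning("miRNA %s shorter than %d nt: skipped", mid, cfg.bulge_hi + 2)
            continue
        site_len = L + cfg.bulge_len
        if n < site_len and not wrap:
            continue
        scan = S + S[:site_len - 1] if wrap else S
        n_offsets = n if wrap else n - site_len + 1
        if wrap and n < site_len:
            scan = (S * (site_len // n + 2))[:n + site_len - 1]
        for o in range(max(0, n_offsets)):
            target = scan[o:o + site_len]
            if len(target) < site_len:
                continue
            best: tuple[float, int] | None = None
            for b in range(cfg.bulge_lo, cfg.bulge_hi):
                cost = _site_alignment(m, target, b, cfg)
                if cost is not None and cost <= cfg.max_mismatch:
                    if best is None or (cost, b) < best:
                        best = (cost, b)
            if best is not None:
                cost, b = best
                sites.append(MimicSite(
                    circ_id=circ_id, mirna_id=mid, position=o, bulge_after=b,
                    weighted_mismatches=cost,
                    diagram=_diagram(m, target, b, cfg)))
    return sites


def read_mirna_fasta(path) -> list[tuple[str, str]]:
    """Mature miRNA FASTA, U normalized to T."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return out
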