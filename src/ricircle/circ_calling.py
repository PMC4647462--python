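"""CircRNA calling: mate consistency, read support and splice-signal filters.

Resolved junctions are filtered read-by-read (the pair's other mate must be
explainable by a circle: unmapped, or mapped within the circle span,
possibly across the backsplice itself), grouped by exact junction
coordinates, required to carry at least ``min_support`` independent
supporting reads, checked for the canonical GT..AG signal, and emitted as
stable, coordinate-ordered calls.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .candidate_detection import GenomeIndex, PipelineConfig, _placements_from_hits, \
    _score_placement
from .io_core import Genome, backsplice_signal_ok
from .junction_resolution import BackspliceJunction

log = logging.getLogger("ricircle")


@dataclass
class CircRNACall:
    """An identified circRNA (normalized forward-strand coordinates)."""

    id: str
    chrom: str
    strand: str
    start: int  # acceptor: leftmost circle base, 0-based
    end: int    # donor: rightmost circle base, 0-based (inclusive)
    support: int
    gtag_ok: bool
    samples: list[str] = field(default_factory=list)
    read_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def span_interval(self) -> tuple[int, int]:
        """Half-open genomic interval covered by the circle."""
        return (self.start, self.end + 1)


# ---------------------------------------------------------------------------
# Mate filter
# ---------------------------------------------------------------------------

def mate_filter(junction: BackspliceJunction, mate: str | None,
                index: GenomeIndex, cfg: PipelineConfig) -> bool:
    """Keep a junction read unless its mate is confidently placed outside.

    The mate is probed with the same anchor-seed machinery as the read
    itself.  Decision rule: drop iff the mate's best unique placement —
    either a full colinear placement or unique terminal-anchor evidence —
    lies even partly outside ``[acceptor, donor]`` or on another
    chromosome; keep when the mate is unmapped, ambiguous, or maps within
    the span (including across the backsplice, where the mate's two
    anchors land chiastically inside the circle).
    """
    if mate is None:
        return True
    k = cfg.anchor_len
    if len(mate) < 2 * k:
        return True  # unmappable with this machinery
    head, tail = mate[:k], mate[-k:]
    h_hits = index.lookup(head, limit=cfg.max_anchor_hits)
    t_hits = index.lookup(tail, limit=cfg.max_anchor_hits)
    lo, hi = junction.acceptor, junction.donor + 1  # half-open span

    def window_inside(hit) -> bool:
        return (hit.chrom == junction.chrom and lo <= hit.pos
                and hit.pos + k <= hi)

    unique_h = h_hits[0] if len(h_hits) == 1 else None
    unique_t = t_hits[0] if len(t_hits) == 1 else None
    if unique_h is None and unique_t is None:
        return True  # unmapped or ambiguous
    # try a confident full colinear placement first
    if unique_h is not None and unique_t is not None:
        placements = _placements_from_hits(len(mate), k, [unique_h], [unique_t])
        best = None
        for chrom, strand, start in placements:
            m, aligned, _ = _score_placement(mate, index.genome, chrom, strand, start)
            if m / len(mate) >= cfg.min_identity:
                best = (chrom, start) if best is None else "ambiguous"
        if best not in (None, "ambiguous"):
            chrom, start = best
            return (chrom == junction.chrom and lo <= start
                    and start + len(mate) <= hi)
    # otherwise judge by the unique anchors individually
    for hit in (unique_h, unique_t):
        if hit is not None and not window_inside(hit):
            return False
    return True


# ---------------------------------------------------------------------------
# Merging and calling
# ---------------------------------------------------------------------------

def _chrom_number(chrom: str, names: Sequence[str]) -> int:
    m = re.search(r"(\d+)$", chrom)
    if m:
        return int(m.group(1))
    return names.index(chrom) + 1


def merge_and_call(junctions: Iterable[BackspliceJunction], genome: Genome,
                   cfg: PipelineConfig, sample: str = "sample1",
                   dedup_fragments: bool = False) -> list[CircRNACall]:
    """Group junctions, apply support and GT..AG filters, assign stable IDs.

    Support counts distinct read identifiers per exact (chrom, strand,
    acceptor, donor) group; ``dedup_fragments`` additionally collapses the
    mate-suffixed reads of one fragment to a single supporter.  The splice
    signal is re-evaluated on the genome; junctions whose flanks run off a
    chromosome end fail the check and are dropped when ``require_gtag``.
    IDs follow ``<prefix><chrom:02d>circ<serial:05d>`` in coordinate order
    per chromosome.
    """
    groups: dict[tuple[str, str, int, int], set[str]] = {}
    for j in junctions:
        rid = j.read_id
        if dedup_fragments:
            rid = re.sub(r"/[12]$", "", rid)
        groups.setdefault(j.key, set()).add(rid)

    calls: list[CircRNACall] = []
    for (chrom, strand, acc, don), readers in groups.items():
        if len(readers) < cfg.min_support:
            continue
        sig = backsplice_signal_ok(genome, chrom, acc, don, strand)
        if cfg.require_gtag and not sig:
            log.debug("junction %s:%d-%d(%s) dropped: no GT..AG signal",
                      chrom, acc, don, strand)
            continue
        calls.append(CircRNACall(id="", chrom=chrom, strand=strand, start=acc,
                                 end=don, support=len(readers), gtag_ok=sig,
                                 samples=[sample], read_ids=sorted(readers)))

    names = genome.names
    calls.sort(key=lambda c: (names.index(c.chrom), c.start, c.end, c.strand))
    serial: dict[str, int] = {}
    for c in calls:
        serial[c.chrom] = serial.get(c.chrom, 0) + 1
        c.id = f"{cfg.id_prefix}{_chrom_number(c.chrom, names):02d}" \
               f"circ{serial[c.chrom]:05d}"
    return calls


def compare_call_sets(call_sets: dict[str, Sequence[CircRNACall]]
                      ) -> dict[str, object]:
    """Exact-junction Venn partition of two or more labeled call sets.

    Returns ``{"regions": {frozenset labels: count}, "at_least": {m: count},
    "union": n, "per_set": {...}}``; membership is exact (chrom, strand,
    acceptor, donor) identity.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets to compare")
    keysets = {label: {c.key for c in calls} for label, calls in call_sets.items()}
    union = set().union(*keysets.values())
    regions: dict[frozenset, int] = {}
    labels = list(keysets)
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = 0
    membership_counts: dict[int, int] = {}
    for key in union:
        members = frozenset(l for l in labels if key in keysets[l])
        regions[members] += 1
        m = len(members)
        membership_counts[m] = membership_counts.get(m, 0) + 1
    at_least = {m: sum(v for mm, v in membership_counts.items() if mm >= m)
                for m in range(1, len(labels) + 1)}
    return {"regions": regions, "at_least": at_least, "union": len(union),
            "per_set": {l: len(s) for l, s in keysets.items()}}


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_calls(calls: Sequence[CircRNACall], path: str | Path) -> None:
    """Calls TSV: 1-based inclusive start/end."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tstrand\tsupport\tgtag\tsamples\n")
        for c in calls:
            fh.write(f"{c.id}\t{c.chrom}\t{c.start + 1}\t{c.end + 1}\t{c.strand}\t"
                     f"{c.support}\t{'yes' if c.gtag_ok else 'no'}\t"
                     f"{','.join(c.samples)}\n")


def read_calls(path: str | Path) -> list[CircRNACall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: missing calls header")
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            calls.append(CircRNACall(
                id=f[0], chrom=f[1], start=int(f[2]) - 1, end=int(f[3]) - 1,
                strand=f[4], support=int(f[5]), gtag_ok=f[6] == "yes",
                samples=f[7].split(",") if len(f) > 7 and f[7] else []))
    return calls


def calls_to_bed(calls: Sequence[CircRNACall]
                 ) -> list[tuple[str, int, int, str, int, str]]:
    """BED6 rows (0-based half-open; score = supporting reads)."""
    return [(c.chrom, c.start, c.end + 1, c.id, c.support, c.strand)
            for c in calls]
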