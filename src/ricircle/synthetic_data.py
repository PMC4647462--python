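"""Synthetic genomes, gene models and stranded paired-end read libraries.

This module emulates the study design that the detection pipeline targets:
a multi-chromosome plant-like genome carrying multi-exon gene models with
canonical GT..AG introns, expressed as linear transcripts plus a
configurable fraction of circularized exon runs, sequenced as stranded
2x100 bp read pairs.  It also builds the "designed backsplice read" data
sets used for sensitivity/FDR benchmarking: head-to-tail chimeras made by
reverse-assembling terminal segments (20-80 bp) of two different exons of
one transcript.

Everything is deterministic under ``SimConfig.rng_seed``: the same
configuration yields byte-identical FASTQ output and truth sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_core import (
    Genome,
    GeneModel,
    ReadPair,
    partition_transcript,
    revcomp,
)

log = logging.getLogger("ricircle")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic data generator.

    Ranges are inclusive (lo, hi) tuples.  ``intron_len`` is bounded well
    below 5 kb so that, as in the real annotation the pipeline mirrors,
    effectively all introns fit inside the 5.1-kb pseudo-genome flanks.
    ``orientation_accuracy`` is the fraction of pairs emitted with the
    correct mate-1-sense convention (real libraries showed 0.927-0.983).
    """

    n_chroms: int = 2
    chrom_len: int = 200_000
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 15)
    exon_len: tuple[int, int] = (80, 400)
    intron_len: tuple[int, int] = (60, 1_000)
    ncrna_fraction: float = 0.1
    read_len: int = 100
    fragment_len: tuple[float, float] = (300.0, 50.0)  # mean, sd
    error_rate: float = 0.0
    orientation_accuracy: float = 1.0
    circ_fraction: float = 0.05
    seg_len_range: tuple[int, int] = (20, 80)
    n_designed_sites: int = 1_500
    n_datasets: int = 5
    reads_per_site: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "seg_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: empty or invalid range ({lo}, {hi})")
        if self.seg_len_range[0] < 20:
            raise ValueError("seg_len_range lower bound must be >= anchor length (20)")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need >= 2 exons")
        if self.n_chroms < 1 or self.chrom_len < 1:
            raise ValueError("need at least one non-empty chromosome")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.orientation_accuracy <= 1.0):
            raise ValueError("orientation_accuracy must be in [0, 1]")
        if not (0.0 <= self.circ_fraction <= 1.0):
            raise ValueError("circ_fraction must be in [0, 1]")
        if self.read_len < 40:
            raise ValueError("read_len must be >= 40 (two non-overlapping anchors)")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, rng_seed=int(seed))


# ---------------------------------------------------------------------------
# Truth set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEntry:
    chrom: str
    strand: str
    acceptor: int  # 0-based position of the leftmost circle base
    donor: int     # 0-based position of the rightmost circle base
    transcript_id: str
    n_reads: int

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.acceptor, self.donor)


@dataclass
class TruthSet:
    """Designed/simulated junctions with per-junction emitted-read counts."""

    entries: list[TruthEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> set[tuple[str, str, int, int]]:
        return {e.key for e in self.entries}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstrand\tacceptor\tdonor\ttranscript_id\tn_reads\n")
            for e in self.entries:
                fh.write(f"{e.chrom}\t{e.strand}\t{e.acceptor + 1}\t{e.donor + 1}\t"
                         f"{e.transcript_id}\t{e.n_reads}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthSet":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):
                raise ValueError(f"{path}: missing truth-set header")
            for raw in fh:
                c, s, a, d, t, n = raw.rstrip("\n").split("\t")
                entries.append(TruthEntry(c, s, int(a) - 1, int(d) - 1, t, int(n)))
        return cls(entries)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Uniform-composition random chromosomes of the configured size."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.rng_seed)
    chroms: dict[str, str] = {}
    for i in range(cfg.n_chroms):
        draw = rng.integers(0, 4, size=cfg.chrom_len)
        chroms[f"chr{i + 1}"] = _BASES[draw].tobytes().decode()
    return Genome(chroms)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def generate_gene_models(
    genome: Genome, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, list[GeneModel]]:
    """Place non-overlapping multi-exon genes and enforce GT..AG introns.

    Returns a new :class:`Genome` in which every intron's terminal
    dinucleotides have been rewritten to the canonical splice signal on the
    transcript's strand (``GT..AG`` in sense coordinates; ``CT..AC`` as seen
    on the forward strand for minus-strand genes), together with the models.
    Raises if the genome cannot host the requested gene count.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    seqs = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    names = genome.names

    models: list[GeneModel] = []
    chrom_i = 0
    cursor = int(rng.integers(200, 2_000))
    for g in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        ex_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, size=n_ex)
        in_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, size=n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        # advance to a chromosome with room
        while chrom_i < len(names) and cursor + span + 200 > genome.length(names[chrom_i]):
            chrom_i += 1
            cursor = int(rng.integers(200, 2_000))
        if chrom_i >= len(names):
            raise ValueError(
                f"genome too small: placed {g} of {cfg.n_genes} requested genes")
        chrom = names[chrom_i]
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "ncRNA" if rng.random() < cfg.ncrna_fraction else "coding"

        exons: list[tuple[int, int]] = []
        pos = cursor
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        gid = f"GENE{g + 1:04d}"
        model = GeneModel(gene_id=gid, transcript_id=f"{gid}.1", chrom=chrom,
                          strand=strand, exons=exons, biotype=biotype)

        # canonical splice signal, sense orientation
        buf = seqs[chrom]
        for (s, e) in model.introns():
            if strand == "+":
                buf[s:s + 2] = b"GT"
                buf[e - 2:e] = b"AG"
            else:
                buf[s:s + 2] = b"CT"
                buf[e - 2:e] = b"AC"

        if biotype == "coding":
            tlen = model.transcript_length()
            u5 = int(rng.integers(0, min(200, tlen // 4) + 1))
            u3 = int(rng.integers(0, min(200, tlen // 4) + 1))
            partition_transcript(model, u5, u3)
        models.append(model)
        cursor = pos + int(rng.integers(200, 2_000))

    new_genome = Genome({name: buf.decode() for name, buf in seqs.items()})
    return new_genome, models


# ---------------------------------------------------------------------------
# ssRNA-seq library
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only sequencing errors."""
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    buf = bytearray(seq, "ascii")
    for p in pos:
        old = buf[p]
        choices = [b for b in b"ACGT" if b != old]
        buf[p] = choices[int(rng.integers(0, 3))]
    return buf.decode()


def _internal_runs(model: GeneModel) -> list[tuple[int, int]]:
    """Exon index pairs (i, j), i < j, with introns on both genomic sides.

    Restricting circles to intron-flanked boundaries keeps every simulated
    junction compatible with the GT..AG splice-signal filter.
    """
    n = model.n_exons
    return [(i, j) for i in range(1, n - 1) for j in range(i + 1, n - 1)]


def _circle_truth_coords(model: GeneModel, i: int, j: int) -> tuple[int, int]:
    return model.exons[i][0], model.exons[j][1] - 1


@dataclass
class FragmentRecord:
    """Provenance log entry for one simulated fragment (testing aid)."""

    frag_id: str
    source: str            # transcript or circle id
    circular: bool
    start: int             # position on the (possibly circular) template
    length: int
    crosses_junction: tuple[bool, bool]  # per emitted mate


def simulate_ssrna_reads(
    genome: Genome,
    models: Sequence[GeneModel],
    cfg: SimConfig,
    n_pairs: int,
    rng: np.random.Generator | None = None,
    log_fragments: bool = False,
) -> tuple[list[ReadPair], TruthSet, list[FragmentRecord]]:
    """Stranded paired-end fragments from linear and circular templates.

    A fraction ``cfg.circ_fraction`` of fragments is drawn from circular
    templates (intron-flanked exon runs of multi-exon genes) treated as
    circles: fragment windows may wrap across the backsplice.  Mate 1
    carries the transcript-sense sequence with probability
    ``cfg.orientation_accuracy``.  The truth set records every circular
    template's junction and how many emitted mates cross it.
    """
    cfg.validate()
    if not models:
        raise ValueError("no gene models supplied")
    rng = rng or np.random.default_rng(cfg.rng_seed + 2)
    rl = cfg.read_len

    linear = [(m, m.spliced_seq(genome)) for m in models
              if m.transcript_length() >= rl]
    if not linear:
        raise ValueError("no transcript is long enough for the read length")

    circles: list[tuple[GeneModel, int, int, str]] = []
    if cfg.circ_fraction > 0.0:
        eligible = [m for m in models if _internal_runs(m)]
        n_circ = max(1, round(0.2 * len(eligible)))
        for m in eligible[:n_circ] if n_circ >= len(eligible) else \
                [eligible[k] for k in rng.choice(len(eligible), n_circ, replace=False)]:
            runs = _internal_runs(m)
            i, j = runs[int(rng.integers(0, len(runs)))]
            circles.append((m, i, j, m.circle_seq(genome, i, j)))

    crossing_counts = [0] * len(circles)
    pairs: list[ReadPair] = []
    frag_log: list[FragmentRecord] = []
    mean, sd = cfg.fragment_len

    for k in range(n_pairs):
        frag_id = f"frag{k:07d}"
        use_circle = circles and rng.random() < cfg.circ_fraction
        if use_circle:
            ci = int(rng.integers(0, len(circles)))
            model, i, j, template = circles[ci]
            L = len(template)
            flen = int(np.clip(rng.normal(mean, sd), rl, max(rl, L)))
            start = int(rng.integers(0, L))
            frag = (template + template)[start:start + flen]
            source = f"{model.transcript_id}:circ{i}-{j}"
        else:
            li = int(rng.integers(0, len(linear)))
            model, template = linear[li]
            L = len(template)
            flen = int(np.clip(rng.normal(mean, sd), rl, L))
            start = int(rng.integers(0, L - flen + 1))
            frag = template[start:start + flen]
            source = model.transcript_id

        s1 = frag[:rl]
        s2 = revcomp(frag[-rl:])
        cross1 = cross2 = False
        if use_circle:
            L = len(template)
            cross1 = start + rl > L
            m2_start = start + flen - rl
            cross2 = m2_start < L < start + flen
            if cross1:
                crossing_counts[ci] += 1
            if cross2:
                crossing_counts[ci] += 1
        s1 = _apply_errors(s1, cfg.error_rate, rng)
        s2 = _apply_errors(s2, cfg.error_rate, rng)
        if rng.random() >= cfg.orientation_accuracy:
            s1, s2 = s2, s1
        pairs.append((frag_id, s1, s2))
        if log_fragments:
            frag_log.append(FragmentRecord(frag_id, source, bool(use_circle),
                                           start, flen, (cross1, cross2)))

    entries = []
    for (model, i, j, _), n_cross in zip(circles, crossing_counts):
        acc, don = _circle_truth_coords(model, i, j)
        entries.append(TruthEntry(model.chrom, model.strand, acc, don,
                                  model.transcript_id, n_cross))
    return pairs, TruthSet(entries), frag_log


# ---------------------------------------------------------------------------
# Designed backsplice reads (simulation testing)
# ---------------------------------------------------------------------------

def simulate_backsplice_reads(
    models: Sequence[GeneModel],
    genome: Genome,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    mate_mode: str = "inside",
) -> tuple[list[ReadPair], TruthSet]:
    """Designed head-to-tail chimeras for sensitivity/FDR benchmarking.

    For each designed site, a circle over two (or more) intron-flanked
    exons of one transcript is chosen and ``cfg.reads_per_site`` chimeric
    reads are emitted, each the concatenation of a 3'-terminal segment of
    the circle's last sense exon and a 5'-terminal segment of its first
    sense exon, with segment lengths drawn from ``cfg.seg_len_range``.
    Sites are unique by junction coordinates.

    ``mate_mode='inside'`` synthesizes each chimera's mate from inside the
    circle (so the mate filter is neutral); ``'random'`` places mates at
    random genomic positions to exercise the filter.

    Returns fewer sites than requested (with a log message) only when the
    model set cannot host enough distinct intron-flanked junctions.
    """
    cfg.validate()
    if mate_mode not in ("inside", "random"):
        raise ValueError(f"unknown mate_mode {mate_mode!r}")
    rng = rng or np.random.default_rng(cfg.rng_seed + 3)
    lo, hi = cfg.seg_len_range
    rl = cfg.read_len

    candidates = [(m, _internal_runs(m)) for m in models]
    candidates = [(m, runs) for m, runs in candidates if runs]
    if not candidates:
        raise ValueError("no transcript offers an intron-flanked exon pair "
                         "(need >= 4 exons)")

    seen: set[tuple[str, str, int, int]] = set()
    pairs: list[ReadPair] = []
    entries: list[TruthEntry] = []
    n_skipped = 0
    attempts = 0
    max_attempts = cfg.n_designed_sites * 50
    site_serial = 0

    while len(entries) < cfg.n_designed_sites and attempts < max_attempts:
        attempts += 1
        m, runs = candidates[int(rng.integers(0, len(candidates)))]
        i, j = runs[int(rng.integers(0, len(runs)))]
        acc, don = _circle_truth_coords(m, i, j)
        key = (m.chrom, m.strand, acc, don)
        if key in seen:
            continue
        sense = m.circle_seq(genome, i, j)
        first_len = (m.exons[i][1] - m.exons[i][0]) if m.strand == "+" else \
            (m.exons[j][1] - m.exons[j][0])
        last_len = (m.exons[j][1] - m.exons[j][0]) if m.strand == "+" else \
            (m.exons[i][1] - m.exons[i][0])
        if first_len < lo or last_len < lo:
            n_skipped += 1
            log.debug("designed site skipped: terminal exon shorter than %d bp", lo)
            continue
        seen.add(key)
        site_serial += 1
        for r in range(cfg.reads_per_site):
            l1 = int(rng.integers(lo, min(hi, last_len) + 1))
            l2 = int(rng.integers(lo, min(hi, first_len) + 1))
            read = sense[-l1:] + sense[:l2]
            if mate_mode == "inside":
                mstart = int(rng.integers(0, len(sense) - rl + 1)) \
                    if len(sense) > rl else 0
                mate = revcomp(sense[mstart:mstart + rl]) if len(sense) >= rl \
                    else revcomp(sense)
            else:
                chrom = genome.names[int(rng.integers(0, len(genome.names)))]
                gpos = int(rng.integers(0, genome.length(chrom) - rl + 1))
                mate = revcomp(genome.fetch(chrom, gpos, gpos + rl))
            read = _apply_errors(read, cfg.error_rate, rng)
            mate = _apply_errors(mate, cfg.error_rate, rng)
            pairs.append((f"site{site_serial:05d}r{r + 1}", read, mate))
        entries.append(TruthEntry(m.chrom, m.strand, acc, don, m.transcript_id,
                                  cfg.reads_per_site))

    missing = cfg.n_designed_sites - len(entries)
    if missing > 0:
        log.warning("designed-site request not met: %d of %d sites placed "
                    "(%d skips, junction space exhausted)",
                    len(entries), cfg.n_designed_sites, n_skipped)
    return pairs, TruthSet(entries)
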