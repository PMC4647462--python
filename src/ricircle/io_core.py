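"""Shared I/O, sequence utilities, gene-model container and configuration.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open, on the forward strand of the
reference.  Conversions happen only at file boundaries:

* GFF3 and the calls/truth TSVs are 1-based inclusive,
* BED stays 0-based half-open.

A backsplice junction is always stored *normalized*: ``acceptor`` is the
genomic position of the leftmost base of the circle and ``donor`` the
position of its rightmost base, regardless of strand.  For a minus-strand
circle the biological acceptor/donor roles are therefore swapped relative
to these names; the strand field disambiguates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO

log = logging.getLogger("ricircle")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware, case preserved)."""
    return seq.translate(_RC)[::-1]


class FileFormatError(ValueError):
    """Raised for malformed records, carrying file and line context."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Ordered chromosome set with uppercase sequences.

    ``chroms`` maps name -> sequence; insertion order is the canonical
    chromosome order used for ID assignment and output.
    """

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.chroms) == 0:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` clipped to the chromosome."""
        seq = self.chroms[chrom]
        return seq[max(0, start):max(0, end)]

    def items(self) -> Iterable[tuple[str, str]]:
        return self.chroms.items()


def read_fasta(path: str | Path) -> Genome:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FileFormatError(f"{path}: duplicate sequence name {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise FileFormatError(f"{path}: no FASTA records found")
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ pairs
# ---------------------------------------------------------------------------

ReadPair = tuple[str, str, str]  # (fragment id, mate-1 seq, mate-2 seq)


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load a paired FASTQ library into memory.

    Mate files must be position-matched; a length mismatch is an error.
    """
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise FileFormatError(
            f"mismatched FASTQ pair: {path1} has {len(r1)} reads, {path2} has {len(r2)}"
        )
    pairs: list[ReadPair] = []
    for a, b in zip(r1, r2):
        name = a.id
        for suffix in ("/1", "/2", ".1", ".2"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        pairs.append((name, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def write_fastq_pair(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` (Q40 throughout)."""
    p1 = Path(f"{prefix}_1.fastq")
    p2 = Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """A transcript with ordered exons and a CDS/UTR partition.

    ``exons`` are genomic-order, sorted, non-overlapping half-open
    intervals.  ``cds`` / ``utr5`` / ``utr3`` are genomic sub-intervals of
    the exons (empty for ncRNA).  ``strand`` is '+' or '-'; for '-'
    transcripts the sense order of exons is the reverse of genomic order.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = self.exons
        if not ex:
            raise ValueError("transcript without exons")
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"exons not sorted/non-overlapping: {ex}")

    # -- geometry -----------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[Interval]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    def sense_exons(self) -> list[Interval]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    # -- sequence -----------------------------------------------------------
    def spliced_seq(self, genome: Genome) -> str:
        """Mature (sense-strand) transcript sequence."""
        s = "".join(genome.fetch(self.chrom, a, b) for a, b in self.exons)
        return s if self.strand == "+" else revcomp(s)

    def circle_seq(self, genome: Genome, i: int, j: int) -> str:
        """Sense sequence of a circle over exons ``i..j`` (genomic indices)."""
        s = "".join(genome.fetch(self.chrom, a, b) for a, b in self.exons[i:j + 1])
        return s if self.strand == "+" else revcomp(s)


def _to_genomic(model: GeneModel, t_start: int, t_end: int) -> list[Interval]:
    """Map a sense transcript interval [t_start, t_end) onto genomic intervals."""
    out: list[Interval] = []
    pos = 0
    for a, b in model.sense_exons():
        ln = b - a
        lo, hi = max(t_start, pos), min(t_end, pos + ln)
        if lo < hi:
            if model.strand == "+":
                out.append((a + (lo - pos), a + (hi - pos)))
            else:
                out.append((b - (hi - pos), b - (lo - pos)))
        pos += ln
    out.sort()
    return out


def partition_transcript(model: GeneModel, utr5_len: int, utr3_len: int) -> None:
    """Assign CDS/UTR intervals from sense-coordinate UTR lengths (in place)."""
    tlen = model.transcript_length()
    if utr5_len + utr3_len >= tlen:
        raise ValueError("UTRs exceed transcript length")
    model.utr5 = _to_genomic(model, 0, utr5_len)
    model.cds = _to_genomic(model, utr5_len, tlen - utr3_len)
    model.utr3 = _to_genomic(model, tlen - utr3_len, tlen)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TX_TYPE = {"coding": "mRNA", "ncRNA": "ncRNA"}


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Serialize gene models as GFF3 (1-based inclusive coordinates)."""

    def line(chrom, ftype, s, e, strand, attrs):
        return f"{chrom}\tricircle\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"

    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, txs in by_gene.items():
            g0 = min(t.start for t in txs)
            g1 = max(t.end for t in txs)
            m0 = txs[0]
            fh.write(line(m0.chrom, "gene", g0, g1, m0.strand,
                          f"ID={gid};biotype={m0.biotype}"))
            for t in txs:
                ttype = _TX_TYPE.get(t.biotype, "mRNA")
                fh.write(line(t.chrom, ttype, t.start, t.end, t.strand,
                              f"ID={t.transcript_id};Parent={gid}"))
                for k, (a, b) in enumerate(t.exons):
                    fh.write(line(t.chrom, "exon", a, b, t.strand,
                                  f"ID={t.transcript_id}.exon{k + 1};Parent={t.transcript_id}"))
                for name, ivs in (("CDS", t.cds), ("five_prime_UTR", t.utr5),
                                  ("three_prime_UTR", t.utr3)):
                    for k, (a, b) in enumerate(ivs):
                        fh.write(line(t.chrom, name, a, b, t.strand,
                                      f"ID={t.transcript_id}.{name}{k + 1};Parent={t.transcript_id}"))


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models: list[GeneModel] = []
    for ttype, biotype in (("mRNA", "coding"), ("ncRNA", "ncRNA")):
        for tx in db.features_of_type(ttype):
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(tx.id):
                iv = (child.start - 1, child.end)  # GFF3 1-based incl -> half-open
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            parents = [p.id for p in db.parents(tx.id, featuretype="gene")]
            gene_id = parents[0] if parents else tx.id
            models.append(GeneModel(
                gene_id=gene_id, transcript_id=tx.id, chrom=tx.seqid,
                strand=tx.strand, exons=sorted(exons), cds=sorted(cds),
                utr5=sorted(utr5), utr3=sorted(utr3), biotype=biotype))
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED (>=3 columns), 0-based half-open.  Returns (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            s = raw.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t") if "\t" in s else s.split()
            if len(fields) < 3:
                raise FileFormatError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{ln}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise FileFormatError(f"{path}:{ln}: bad interval {start}..{end}")
            name = fields[3] if len(fields) > 3 else f"feature{ln}"
            out.append((fields[0], start, end, name))
    return out


def write_bed(records: Iterable[tuple[str, int, int, str, int, str]],
              path: str | Path) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Splice signal
# ---------------------------------------------------------------------------

def backsplice_signal_ok(genome: Genome, chrom: str, left: int, right: int,
                         strand: str) -> bool:
    """Canonical GT..AG (GU/AG in RNA) check for a backsplice junction.

    ``left``/``right`` are the normalized circle endpoints (0-based positions
    of the first and last circle base).  A spliceosomal backsplice removes
    the intron downstream of the sense donor and upstream of the sense
    acceptor, so on '+' the genome must read ``AG | circle | GT``; on '-'
    the same signal on the sense strand appears as ``AC | circle | CT`` on
    the forward strand.  Junctions whose flanks run off the chromosome fail.
    """
    seq = genome[chrom]
    if left - 2 < 0 or right + 3 > len(seq):
        return False
    before = seq[left - 2:left]
    after = seq[right + 1:right + 3]
    if strand == "+":
        return before == "AG" and after == "GT"
    return before == "AC" and after == "CT"


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Aggregate configuration for a full run, YAML round-trippable.

    Sub-configurations are stored as plain dicts of overrides so that the
    file only needs to mention values that differ from the defaults.
    """

    sim: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)
    flank: dict = field(default_factory=dict)
    mimic: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FileFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
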