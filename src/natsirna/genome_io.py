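"""Standard-format I/O and perfect-match read placement.

Coordinates are 0-based half-open everywhere inside the package; GFF3 is
converted at the boundary (1-based inclusive on disk) and user-facing
reports print 1-based inclusive.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import revcomp

log = logging.getLogger(__name__)

BIOTYPES = {
    "protein_coding",
    "other_RNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "ta_siRNA",
    "transposon",
}

MIN_READ_LEN = 17
MAX_READ_LEN = 28


class AnnotationError(ValueError):
    """Malformed or inconsistent genome annotation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Chromosome name -> uppercase nucleotide string (ACGTN)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} contains non-ACGTN symbols {bad}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path | TextIO) -> "Genome":
        handle = open(path) if isinstance(path, (str, Path)) else path
        try:
            seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
        finally:
            if isinstance(path, (str, Path)):
                handle.close()
        return cls(seqs)

    def to_fasta(self, path: str | Path | TextIO) -> None:
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in self.sequences.items()]
        if isinstance(path, (str, Path)):
            with open(path, "w") as fh:
                SeqIO.write(records, fh, "fasta")
        else:
            SeqIO.write(records, path, "fasta")


@dataclass
class GeneModel:
    """A stranded, exon-structured gene locus (representative transcript)."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.span[0] >= self.span[1]:
            raise ValueError(f"{self.gene_id}: empty span {self.span}")
        if not self.exons:
            self.exons = [self.span]
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < self.span[0] or e > self.span[1]:
                raise AnnotationError(f"{self.gene_id}: exon ({s},{e}) outside gene span {self.span}")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        for utr in (self.utr5, self.utr3):
            if utr and not (self.span[0] <= utr[0] < utr[1] <= self.span[1]):
                raise AnnotationError(f"{self.gene_id}: UTR {utr} outside span {self.span}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Span minus exons (derived)."""
        out = []
        cursor = self.span[0]
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.span[1]:
            out.append((cursor, self.span[1]))
        return out

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end (position just outside transcription)."""
        return self.span[1] if self.strand == "+" else self.span[0]

    def five_prime(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]


@dataclass
class RawRead:
    """A collapsed sequencing read: identical inserts summed into copies."""

    read_id: str
    sequence: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass
class MappedRead:
    """A perfect-match placement of a read on the genome.

    ``length`` defaults to the sequence length; BED input may carry an
    opaque name in ``sequence``, in which case the interval length rules.
    """

    sequence: str
    chrom: str
    start: int
    strand: str
    copies: int = 1
    library_id: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            self.length = len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class Library:
    """Metadata for one small-RNA library.

    ``control_id`` names the matched control library for a treatment
    library (None for controls themselves); ``total_mapped`` is the
    genome-mapped copy total used as the reads-per-million denominator.
    """

    library_id: str
    species: str = ""
    condition: str = ""
    control_id: str | None = None
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped < 0:
            raise ValueError("total_mapped must be >= 0")


def validate_library_controls(libraries: Iterable[Library]) -> None:
    """Reject cyclic control chains (control mapping must be acyclic)."""
    by_id = {lib.library_id: lib for lib in libraries}
    for lib in by_id.values():
        seen = set()
        cur: str | None = lib.library_id
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cyclic control mapping through library {cur!r}")
            seen.add(cur)
            cur = by_id[cur].control_id if cur in by_id else None


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------


def _prevalidate_gff(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(f"GFF3 line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationError(f"GFF3 line {lineno}: non-numeric coordinates") from exc
        if start < 1 or end < start:
            raise AnnotationError(f"GFF3 line {lineno}: invalid coordinate range {start}..{end}")
        if fields[6] not in "+-.":
            raise AnnotationError(f"GFF3 line {lineno}: invalid strand {fields[6]!r}")


def parse_annotation(gff: str | Path | TextIO) -> list[GeneModel]:
    """Read a GFF3 gene/mRNA/exon/UTR hierarchy into GeneModels.

    One model per gene; the representative transcript is the longest mRNA
    (genomic span). Coordinates are converted 1-based inclusive -> 0-based
    half-open. Single-level gene records (no mRNA children) become
    single-exon models over the gene span.
    """
    if isinstance(gff, (str, Path)) and Path(str(gff)).exists():
        text = Path(gff).read_text()
    elif isinstance(gff, (str, Path)):
        text = str(gff)
    else:
        text = gff.read()
    _prevalidate_gff(text)
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if mrnas:
            rep = max(mrnas, key=lambda m: (m.end - m.start + 1, m.id))
            span = (rep.start - 1, rep.end)
            exons = [(e.start - 1, e.end) for e in db.children(rep, featuretype="exon")]
            utr5s = [(u.start - 1, u.end) for u in db.children(rep, featuretype="five_prime_UTR")]
            utr3s = [(u.start - 1, u.end) for u in db.children(rep, featuretype="three_prime_UTR")]
        else:
            span = (gene.start - 1, gene.end)
            exons, utr5s, utr3s = [span], [], []
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                span=span,
                exons=exons or [span],
                biotype=biotype,
                utr5=utr5s[0] if utr5s else None,
                utr3=utr3s[0] if utr3s else None,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path | TextIO) -> None:
    """Emit a gene/mRNA/exon/UTR GFF3 (1-based inclusive on disk)."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
        s1, e1 = g.span[0] + 1, g.span[1]
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        out.write(f"{g.chrom}\tnatsirna\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n")
        mrna_id = f"{g.gene_id}.1"
        out.write(f"{g.chrom}\tnatsirna\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
        for i, (xs, xe) in enumerate(g.exons, 1):
            out.write(
                f"{g.chrom}\tnatsirna\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
            )
        for utr, ftype in ((g.utr5, "five_prime_UTR"), (g.utr3, "three_prime_UTR")):
            if utr:
                out.write(
                    f"{g.chrom}\tnatsirna\t{ftype}\t{utr[0] + 1}\t{utr[1]}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.{ftype};Parent={mrna_id}\n"
                )
    text = out.getvalue()
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


# ---------------------------------------------------------------------------
# Raw reads: parsing, adaptor trimming, collapsing
# ---------------------------------------------------------------------------


def read_sequences(path: str | Path | TextIO, fmt: str | None = None) -> Iterator[RawRead]:
    """Stream reads from FASTQ or FASTA (format inferred from the extension)."""
    if fmt is None:
        name = str(path if isinstance(path, (str, Path)) else getattr(path, "name", ""))
        fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        for rec in SeqIO.parse(handle, fmt):
            yield RawRead(rec.id, str(rec.seq).upper())
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def trim_and_filter(
    reads: Iterable[RawRead],
    adaptor: str | None = None,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    require_adaptor: bool = False,
    seed_len: int = 8,
) -> list[RawRead]:
    """Trim 3' adaptors, apply the 17-28 nt length window, collapse duplicates.

    The adaptor is located by the first occurrence of its leading
    ``seed_len``-nt seed; reads without a detectable adaptor are kept
    untrimmed (when already in the length window) unless
    ``require_adaptor`` is set. Identical insert sequences are collapsed
    with summed copies, conserving total copy number.
    """
    if adaptor is not None and not adaptor:
        raise ValueError("adaptor must be non-empty when trimming is requested")
    seed = adaptor[:seed_len] if adaptor else None
    counts: dict[str, int] = {}
    for read in reads:
        insert = read.sequence
        if seed:
            idx = insert.find(seed)
            if idx >= 0:
                insert = insert[:idx]
            elif require_adaptor:
                continue
        if not (min_len <= len(insert) <= max_len):
            continue
        counts[insert] = counts.get(insert, 0) + read.copies
    return [
        RawRead(read_id=f"r{i}_x{c}", sequence=s, copies=c)
        for i, (s, c) in enumerate(sorted(counts.items()), 1)
    ]


# ---------------------------------------------------------------------------
# Exact-match placement
# ---------------------------------------------------------------------------


class KmerIndex:
    """Seed-and-verify exact matcher over an in-memory genome.

    Every k-mer start position is indexed; a query is located by looking
    up its leading k-mer and verifying the full sequence, so all perfect
    placements (multi-mapping included) are reported and nothing else.
    """

    def __init__(self, genome: Genome, k: int = 12):
        if k < 1:
            raise ValueError("k must be positive")
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def find(self, query: str) -> list[tuple[str, int]]:
        """All exact forward-strand placements of the query."""
        if len(query) < self.k or "N" in query:
            # fall back to a direct scan for very short queries
            if "N" in query:
                return []
            hits = []
            for chrom, seq in self.genome.sequences.items():
                pos = seq.find(query)
                while pos >= 0:
                    hits.append((chrom, pos))
                    pos = seq.find(query, pos + 1)
            return hits
        hits = []
        for chrom, pos in self._index.get(query[: self.k], ()):
            if self.genome.sequences[chrom][pos : pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits


def map_reads_exact(
    reads: Iterable[RawRead],
    genome: Genome,
    library_id: str = "",
    index: KmerIndex | None = None,
    unique_only: bool = False,
) -> list[MappedRead]:
    """Place reads at every perfect-match locus (no mismatches).

    Reads containing N are not placed. A minus-strand placement means the
    genome's forward strand at the locus equals the read's reverse
    complement; the stored sequence is the read as sequenced. With
    ``unique_only``, reads hitting more than one locus are dropped.
    """
    idx = index or KmerIndex(genome)
    mapped: list[MappedRead] = []
    for read in reads:
        if "N" in read.sequence:
            continue
        placements = [(c, p, "+") for c, p in idx.find(read.sequence)]
        placements += [(c, p, "-") for c, p in idx.find(revcomp(read.sequence))]
        if unique_only and len(placements) != 1:
            continue
        for chrom, pos, strand in placements:
            mapped.append(
                MappedRead(
                    sequence=read.sequence,
                    chrom=chrom,
                    start=pos,
                    strand=strand,
                    copies=read.copies,
                    library_id=library_id,
                )
            )
    mapped.sort(key=lambda m: (m.chrom, m.start, m.strand, m.sequence))
    return mapped


# ---------------------------------------------------------------------------
# BED6 interchange
# ---------------------------------------------------------------------------


def load_bed(
    bed: str | Path | TextIO, library_id: str = ""
) -> tuple[list[MappedRead], int]:
    """Read BED6 mapped reads (name=sequence, score=copies).

    Records without a +/- strand are skipped; the skip count is returned
    and logged. BED's 0-based half-open convention matches the internal
    one, so coordinates pass through unchanged.
    """
    handle = open(bed) if isinstance(bed, (str, Path)) else bed
    reads: list[MappedRead] = []
    skipped = 0
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6 or fields[5] not in "+-":
                skipped += 1
                continue
            chrom, start, end, name, score, strand = fields[:6]
            start_i, end_i = int(start), int(end)
            reads.append(
                MappedRead(
                    sequence=name,
                    chrom=chrom,
                    start=start_i,
                    strand=strand,
                    copies=int(score),
                    library_id=library_id,
                    length=end_i - start_i,
                )
            )
    finally:
        if isinstance(bed, (str, Path)):
            handle.close()
    if skipped:
        log.warning("load_bed: skipped %d records without a +/- strand", skipped)
    return reads, skipped


def write_bed(reads: Iterable[MappedRead], path: str | Path | TextIO) -> None:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.sequence}\t{r.copies}\t{r.strand}\n" for r in reads
    ]
    if isinstance(path, (str, Path)):
        Path(path).write_text("".join(lines))
    else:
        path.writelines(lines)
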