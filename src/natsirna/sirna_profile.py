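"""Assign mapped small-RNA reads to cis-NAT pairs and regions, normalize to
reads-per-million, and summarize per-pair siRNA production.

A read counts toward a pair when its alignment intersects either gene
span. Zone is ``overlap`` only when the alignment is fully contained in
the overlap interval (boundary-straddling reads fall to ``non_overlap``,
keeping zone counts disjoint and conservative). Structure is evaluated on
the host gene whose strand matches the read, with precedence
junction > intron > exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import Library, MappedRead
from .nat_discovery import NatPair

PROFILE_COLUMNS = [
    "pair_id",
    "library_id",
    "sequence",
    "chrom",
    "start",
    "length",
    "strand",
    "copies",
    "zone",
    "structure",
    "origin_gene",
    "length_class",
    "first_nt",
]

MAX_READ_SPAN = 40  # upper bound on alignment length used for window queries


def length_class(n: int) -> str:
    if 20 <= n <= 22:
        return "20-22"
    if 23 <= n <= 28:
        return "23-28"
    return "other"


def first_nt(sequence: str) -> str:
    """5'-first nucleotide in RNA alphabet (T reported as U)."""
    return "U" if sequence[:1] == "T" else sequence[:1]


def _covered(read_iv: tuple[int, int], intervals: Sequence[tuple[int, int]]) -> int:
    s, e = read_iv
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)


def assign_read(pair: NatPair, read: MappedRead) -> tuple[str, str, str] | None:
    """(zone, structure, origin_gene_id) for one read, or None if unassigned."""
    iv = (read.start, read.end)
    if read.chrom != pair.chrom:
        return None
    if not any(max(g.span[0], iv[0]) < min(g.span[1], iv[1]) for g in pair.genes):
        return None
    zone = (
        "overlap"
        if pair.overlap[0] <= iv[0] and iv[1] <= pair.overlap[1]
        else "non_overlap"
    )
    host = pair.gene_for_strand(read.strand)
    if not (max(host.span[0], iv[0]) < min(host.span[1], iv[1])):
        host = pair.gene_a if host is pair.gene_b else pair.gene_b
    exonic = _covered(iv, host.exons)
    intronic = _covered(iv, host.introns)
    if exonic and intronic:
        structure = "junction"
    elif intronic and not exonic:
        structure = "intron"
    else:
        structure = "exon"
    origin = pair.gene_for_strand(read.strand)
    return zone, structure, origin.gene_id


def assign_reads(pair: NatPair, reads: Iterable[MappedRead]) -> list[tuple[MappedRead, str, str, str]]:
    """Per-read region assignments for one pair: (read, zone, structure, origin)."""
    out = []
    for read in reads:
        tag = assign_read(pair, read)
        if tag is not None:
            out.append((read, *tag))
    return out


def build_profile(pairs: Sequence[NatPair], reads: Sequence[MappedRead]) -> pd.DataFrame:
    """One row per (pair, assigned read) with region/strand/length/first-nt strata.

    Reads are matched to pairs by a sorted window query per chromosome, so
    cost scales with pairs + assigned reads rather than pairs x reads.
    """
    by_chrom: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)
    starts = {c: np.array([r.start for r in lst]) for c, lst in by_chrom.items()}

    rows = []
    for pair in pairs:
        if pair.chrom not in by_chrom:
            continue
        lo, hi = pair.union_span
        arr = starts[pair.chrom]
        i0 = int(np.searchsorted(arr, lo - MAX_READ_SPAN, side="left"))
        i1 = int(np.searchsorted(arr, hi, side="left"))
        for read in by_chrom[pair.chrom][i0:i1]:
            tag = assign_read(pair, read)
            if tag is None:
                continue
            zone, structure, origin = tag
            rows.append(
                (
                    pair.pair_id,
                    read.library_id,
                    read.sequence,
                    read.chrom,
                    read.start,
                    read.length,
                    read.strand,
                    read.copies,
                    zone,
                    structure,
                    origin,
                    length_class(read.length),
                    first_nt(read.sequence),
                )
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def normalize_per_million(profile: pd.DataFrame, libraries: Mapping[str, Library]) -> pd.DataFrame:
    """Add an ``rpm`` column: copies x 1e6 / library total_mapped."""
    out = profile.copy()
    factors = {}
    for lib_id in out["library_id"].unique() if len(out) else []:
        lib = libraries[lib_id]
        if lib.total_mapped <= 0:
            raise ValueError(f"empty library: {lib_id!r} has total_mapped = 0")
        factors[lib_id] = 1e6 / lib.total_mapped
    out["rpm"] = (
        out["copies"] * out["library_id"].map(factors) if len(out) else pd.Series(dtype=float)
    )
    return out


@dataclass
class PairSummary:
    """Per-pair flags mirroring the headline siRNA-production columns."""

    pair_id: str
    or_rpm_sum: float
    passes_10rpm: bool
    exclusive_or: bool
    or_enriched_2x: bool
    strand_bias_ratio: float
    strand_biased: bool
    total_rpm: float = 0.0
    total_copies: int = 0
    unique_sequences: int = 0


def summarize_pair(
    pair: NatPair,
    profile: pd.DataFrame,
    rpm_min: float = 10.0,
    bias_ratio: float = 2.0,
    bias_zero_floor: float = 5.0,
) -> PairSummary:
    """Collapse a normalized per-read profile into the pair's summary flags.

    * ``or_rpm_sum``: summed overlap-region rpm across libraries; the pair
      passes at >= ``rpm_min``.
    * ``or_enriched_2x``: overlap density (rpm/nt) more than twice the
      non-overlap density.
    * strand bias: max/min of whole-pair per-strand rpm, strict > 2; a
      zero side counts as biased only when the nonzero side reaches
      ``bias_zero_floor`` rpm, to avoid single-read artifacts.
    """
    rows = profile[profile["pair_id"] == pair.pair_id]
    or_rpm = float(rows.loc[rows["zone"] == "overlap", "rpm"].sum())
    non_rpm = float(rows.loc[rows["zone"] == "non_overlap", "rpm"].sum())
    exclusive = len(rows) > 0 and non_rpm == 0.0

    d_o = or_rpm / pair.overlap_len
    l_g = pair.nonoverlap_len
    d_g = non_rpm / l_g if l_g > 0 else 0.0
    enriched = d_o > 2.0 * d_g if d_g > 0 else d_o > 0.0

    plus = float(rows.loc[rows["strand"] == "+", "rpm"].sum())
    minus = float(rows.loc[rows["strand"] == "-", "rpm"].sum())
    hi, lo = max(plus, minus), min(plus, minus)
    if lo > 0:
        ratio = hi / lo
        biased = ratio > bias_ratio
    elif hi > 0:
        ratio = float("inf")
        biased = hi >= bias_zero_floor
    else:
        ratio = 1.0
        biased = False

    return PairSummary(
        pair_id=pair.pair_id,
        or_rpm_sum=or_rpm,
        passes_10rpm=or_rpm >= rpm_min,
        exclusive_or=exclusive,
        or_enriched_2x=enriched,
        strand_bias_ratio=ratio,
        strand_biased=biased,
        total_rpm=or_rpm + non_rpm,
        total_copies=int(rows["copies"].sum()),
        unique_sequences=int(rows["sequence"].nunique()),
    )


def size_and_first_nt_tables(reads: Iterable[MappedRead]) -> dict[str, pd.Series]:
    """Unique-read (distinct sequence) fractions by length, size class, first nt.

    Each table sums to 1 over its categories when any reads are present.
    """
    seqs = {r.sequence for r in reads}
    lengths = pd.Series([len(s) for s in seqs], dtype=int)
    firsts = pd.Series([first_nt(s) for s in seqs])
    classes = pd.Series([length_class(len(s)) for s in seqs])
    n = len(seqs)

    def frac(series: pd.Series, index: list) -> pd.Series:
        counts = series.value_counts().reindex(index, fill_value=0)
        return counts / n if n else counts.astype(float)

    return {
        "length": frac(lengths, list(range(17, 29))),
        "size_class": frac(classes, ["20-22", "23-28", "other"]),
        "first_nt": frac(firsts, ["A", "C", "G", "U"]),
    }


def region_accounting(profile: pd.DataFrame) -> pd.DataFrame:
    """Total and unique read counts by region, in the nested order
    entire / introns-in-entire / overlap / introns-in-overlap."""

    def tally(rows: pd.DataFrame) -> tuple[int, int]:
        return int(rows["copies"].sum()), int(rows["sequence"].nunique())

    entire = tally(profile)
    introns_entire = tally(profile[profile["structure"] == "intron"])
    ov = profile[profile["zone"] == "overlap"]
    or_counts = tally(ov)
    introns_or = tally(ov[ov["structure"] == "intron"])
    return pd.DataFrame(
        [
            ("entire_NATs", *entire),
            ("introns_in_entire", *introns_entire),
            ("OR_of_NATs", *or_counts),
            ("introns_in_OR", *introns_or),
        ],
        columns=["region", "total", "unique"],
    )
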