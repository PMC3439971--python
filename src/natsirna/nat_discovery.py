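"""cis-NAT pair discovery, topology classification, and the exclusion filter.

A cis-NAT pair is two genes on opposite strands of the same chromosome
whose genomic spans overlap by more than ``min_overlap`` nucleotides
(strictly; a 25-nt overlap does not qualify at the default). Topologies:
convergent (3'-3' overlap), divergent (5'-5'), and enclosed (one span
entirely inside the other).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .genome_io import BIOTYPES, GeneModel
from .util import contains, overlap_interval

DEFAULT_EXCLUDED_BIOTYPES = frozenset(
    {"rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "ta_siRNA", "transposon"}
)


@dataclass
class NatPair:
    """Two overlapping opposite-strand genes; gene_a has the lower start."""

    pair_id: str
    gene_a: GeneModel
    gene_b: GeneModel
    topology: str
    overlap: tuple[int, int]

    @property
    def overlap_len(self) -> int:
        return self.overlap[1] - self.overlap[0]

    @property
    def chrom(self) -> str:
        return self.gene_a.chrom

    @property
    def union_span(self) -> tuple[int, int]:
        return (
            min(self.gene_a.span[0], self.gene_b.span[0]),
            max(self.gene_a.span[1], self.gene_b.span[1]),
        )

    @property
    def genes(self) -> tuple[GeneModel, GeneModel]:
        return (self.gene_a, self.gene_b)

    def gene_for_strand(self, strand: str) -> GeneModel:
        return self.gene_a if self.gene_a.strand == strand else self.gene_b

    @property
    def nonoverlap_len(self) -> int:
        """Total non-overlap length across both genes."""
        return (self.gene_a.length - self.overlap_len) + (self.gene_b.length - self.overlap_len)


@dataclass
class ExclusionPolicy:
    """Biotype-based pair exclusion with an explicit retain allowlist.

    Pairs in which either gene carries an excluded biotype are removed
    (structural-RNA and transposon loci are degradation/sRNA hotspots that
    would mask genuine nat-siRNA signal); the allowlist overrides, which
    models case-by-case manual retention decisions.
    """

    excluded_biotypes: frozenset[str] = DEFAULT_EXCLUDED_BIOTYPES
    retain_pair_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.excluded_biotypes) - BIOTYPES
        if unknown:
            raise ValueError(f"unknown biotype label(s) in exclusion policy: {sorted(unknown)}")


def _topology(plus: GeneModel, minus: GeneModel) -> str:
    if contains(plus.span, minus.span) or contains(minus.span, plus.span):
        return "enclosed"
    # partial overlap: the left gene's strand decides which ends meet
    if plus.span[0] < minus.span[0]:
        return "convergent"  # + gene's 3' end and - gene's 3' end inside the overlap
    return "divergent"


def make_pair(gene_a: GeneModel, gene_b: GeneModel) -> NatPair | None:
    """Build a NatPair from two genes, or None if they do not qualify."""
    if gene_a.chrom != gene_b.chrom or gene_a.strand == gene_b.strand:
        return None
    ov = overlap_interval(gene_a.span, gene_b.span)
    if ov is None:
        return None
    a, b = sorted((gene_a, gene_b), key=lambda g: (g.span[0], g.span[1], g.gene_id))
    plus = a if a.strand == "+" else b
    minus = b if plus is a else a
    return NatPair(
        pair_id=f"{a.gene_id}|{b.gene_id}",
        gene_a=a,
        gene_b=b,
        topology=_topology(plus, minus),
        overlap=ov,
    )


def find_nat_pairs(genes: Iterable[GeneModel], min_overlap: int = 25) -> list[NatPair]:
    """All opposite-strand same-chromosome pairs overlapping > min_overlap nt.

    Output is independent of input gene order: pairs are sorted by
    chromosome then overlap start. Each qualifying pair is emitted once.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[NatPair] = []
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.span[0], g.span[1], g.gene_id))
        for i, gi in enumerate(gs):
            for gj in gs[i + 1 :]:
                if gj.span[0] >= gi.span[1] - min_overlap:
                    break  # sorted by start: no later gene can overlap enough
                pair = make_pair(gi, gj)
                if pair is not None and pair.overlap_len > min_overlap:
                    pairs.append(pair)
    pairs.sort(key=lambda p: (p.chrom, p.overlap[0], p.pair_id))
    return pairs


def apply_exclusions(
    pairs: Sequence[NatPair], policy: ExclusionPolicy | None = None
) -> tuple[list[NatPair], list[tuple[NatPair, str]]]:
    """Partition pairs into (retained, excluded-with-reason) under the policy."""
    policy = policy or ExclusionPolicy()
    retained: list[NatPair] = []
    excluded: list[tuple[NatPair, str]] = []
    for pair in pairs:
        reasons = [
            g.biotype for g in pair.genes if g.biotype in policy.excluded_biotypes
        ]
        if reasons and pair.pair_id not in policy.retain_pair_ids:
            excluded.append((pair, ",".join(sorted(set(reasons)))))
        else:
            retained.append(pair)
    return retained, excluded


def write_pairs_tsv(
    pairs: Sequence[NatPair],
    excluded: Sequence[tuple[NatPair, str]],
    path: str | TextIO,
) -> None:
    """Pair table with 1-based inclusive printed coordinates."""
    import io
    from pathlib import Path

    out = io.StringIO()
    out.write(
        "pair_id\tgene_a\tgene_b\tchrom\ttopology\toverlap_start\toverlap_end\t"
        "overlap_len\texcluded\treason\n"
    )
    rows = [(p, "N", "") for p in pairs] + [(p, "Y", r) for p, r in excluded]
    rows.sort(key=lambda t: (t[0].chrom, t[0].overlap[0], t[0].pair_id))
    for p, flag, reason in rows:
        out.write(
            f"{p.pair_id}\t{p.gene_a.gene_id}\t{p.gene_b.gene_id}\t{p.chrom}\t{p.topology}\t"
            f"{p.overlap[0] + 1}\t{p.overlap[1]}\t{p.overlap_len}\t{flag}\t{reason}\n"
        )
    if isinstance(path, str):
        Path(path).write_text(out.getvalue())
    else:
        path.write(out.getvalue())
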