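"""Greedy 10-nt read clustering and site-specific vs distributed calls.

Reads mapped to a cis-NAT are swept from the 5' end of the pair's union
span (lower genomic coordinate): the first unclustered read founds a
cluster and every read whose first-nt position lies within the next 10 nt
joins it. Clusters with more than five reads (copies) are retained. A
pair is site-specific when it has no more than ten retained clusters AND
more than half of all its reads fall inside them; otherwise distributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import MappedRead


@dataclass
class Cluster:
    anchor: int
    window_len: int
    positions: list[int]
    n_reads: int

    @property
    def window(self) -> tuple[int, int]:
        return (self.anchor, self.anchor + self.window_len)


@dataclass
class PatternCall:
    pair_id: str
    n_clusters: int
    frac_in_clusters: float
    label: str
    total_copies: int


def cluster_reads(
    positions_with_copies: Iterable[tuple[int, int]], window_len: int = 10
) -> list[Cluster]:
    """Greedy left-to-right windowing of first-nt positions.

    Positions are sorted ascending before the sweep; copies weight
    ``n_reads``. All clusters are returned (retention is a separate
    filter), with pairwise disjoint windows.
    """
    items = sorted(positions_with_copies)
    clusters: list[Cluster] = []
    current: Cluster | None = None
    for pos, copies in items:
        if current is not None and pos < current.anchor + window_len:
            current.positions.append(pos)
            current.n_reads += copies
        else:
            current = Cluster(anchor=pos, window_len=window_len, positions=[pos], n_reads=copies)
            clusters.append(current)
    return clusters


def retained_clusters(clusters: Sequence[Cluster], min_reads: int = 6) -> list[Cluster]:
    """Clusters with more than five reads (strict: exactly 5 is discarded)."""
    return [c for c in clusters if c.n_reads >= min_reads]


def classify_pattern(
    clusters: Sequence[Cluster],
    total_copies: int,
    pair_id: str = "",
    max_clusters: int = 10,
    frac_min: float = 0.5,
    min_cluster_reads: int = 6,
) -> PatternCall:
    """Site-specific iff <= max_clusters retained clusters hold > frac_min of reads.

    ``total_copies`` is the denominator: all reads mapped to the whole
    cis-NAT, including reads in discarded clusters.
    """
    if total_copies <= 0:
        raise ValueError(f"no reads for pair {pair_id!r}")
    kept = retained_clusters(clusters, min_reads=min_cluster_reads)
    in_clusters = sum(c.n_reads for c in kept)
    frac = in_clusters / total_copies
    label = "site_specific" if len(kept) <= max_clusters and frac > frac_min else "distributed"
    return PatternCall(
        pair_id=pair_id,
        n_clusters=len(kept),
        frac_in_clusters=frac,
        label=label,
        total_copies=total_copies,
    )


def classify_pair_reads(
    pair_id: str,
    reads: Iterable[MappedRead],
    window_len: int = 10,
    max_clusters: int = 10,
    frac_min: float = 0.5,
    min_cluster_reads: int = 6,
) -> PatternCall:
    """Cluster + classify reads mapped to one pair (both strands pooled)."""
    pos_copies = [(r.start, r.copies) for r in reads]
    total = sum(c for _, c in pos_copies)
    clusters = cluster_reads(pos_copies, window_len=window_len)
    return classify_pattern(
        clusters,
        total,
        pair_id=pair_id,
        max_clusters=max_clusters,
        frac_min=frac_min,
        min_cluster_reads=min_cluster_reads,
    )
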