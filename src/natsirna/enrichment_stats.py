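"""Overlap-region enrichment statistics.

For each cis-NAT pair the density of small-RNA loci (distinct
(sequence, start, strand) mapping events per nucleotide) is computed for
the overlap region (N_o / L_o) and the pooled non-overlap remainder of
both genes (N_g / L_g). Pairs that spawn sRNAs are compared with a
one-tail paired two-sample t-test (alternative: overlap denser), and the
ratio of mean densities A_o / A_g is the enrichment score. A resampling
comparison draws size-matched windows from non-NAT genes to ask whether
NAT overlaps out-produce ordinary genic regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneModel, MappedRead
from .nat_discovery import NatPair


@dataclass
class DensityRecord:
    pair_id: str
    n_overlap: int
    len_overlap: int
    n_nonoverlap: int
    len_nonoverlap: int

    @property
    def d_o(self) -> float:
        return self.n_overlap / self.len_overlap

    @property
    def d_g(self) -> float | None:
        if self.len_nonoverlap == 0:
            return None
        return self.n_nonoverlap / self.len_nonoverlap

    @property
    def testable(self) -> bool:
        """In the test only when the pair spawns sRNAs and both densities exist."""
        return self.len_nonoverlap > 0 and (self.n_overlap + self.n_nonoverlap) > 0


@dataclass
class EnrichmentResult:
    t_stat: float
    dof: int
    p_one_tail: float
    a_o: float
    a_g: float

    @property
    def score(self) -> float:
        """Enrichment score A_o / A_g (inf when the non-overlap mean is 0)."""
        return self.a_o / self.a_g if self.a_g > 0 else float("inf")


@dataclass
class ResamplingResult:
    a_o: float
    a_u_samples: np.ndarray
    n_perm: int
    seed: int

    @property
    def p_empirical(self) -> float:
        """Plain frequency of resampled means exceeding the observed one.

        Can be exactly 0; (k+1)/(n+1) is a less biased alternative but the
        plain frequency is the convention followed here.
        """
        return float(np.sum(self.a_u_samples > self.a_o)) / self.n_perm


def sirna_loci(reads: Iterable[MappedRead], count_copies: bool = False) -> dict[tuple, int]:
    """Distinct (sequence, start, strand) loci, optionally weighted by copies."""
    loci: dict[tuple, int] = {}
    for r in reads:
        key = (r.sequence, r.chrom, r.start, r.strand)
        loci[key] = loci.get(key, 0) + r.copies if count_copies else 1
    return loci


def pair_density(
    pair: NatPair, reads: Iterable[MappedRead], count_copies: bool = False
) -> DensityRecord:
    """Locus densities of one pair from reads in the combined libraries.

    A locus is counted toward the overlap when fully contained in it, and
    toward the non-overlap remainder when it intersects either gene span
    otherwise. Duplicate copies of one sequence at one locus count once
    unless ``count_copies``.
    """
    n_o = 0
    n_g = 0
    seen: set[tuple] = set()
    for r in reads:
        if r.chrom != pair.chrom:
            continue
        if not any(max(g.span[0], r.start) < min(g.span[1], r.end) for g in pair.genes):
            continue
        key = (r.sequence, r.start, r.strand)
        weight = r.copies if count_copies else 1
        if not count_copies:
            if key in seen:
                continue
            seen.add(key)
        if pair.overlap[0] <= r.start and r.end <= pair.overlap[1]:
            n_o += weight
        else:
            n_g += weight
    return DensityRecord(
        pair_id=pair.pair_id,
        n_overlap=n_o,
        len_overlap=pair.overlap_len,
        n_nonoverlap=n_g,
        len_nonoverlap=pair.nonoverlap_len,
    )


def pair_densities(
    pairs: Sequence[NatPair], reads: Sequence[MappedRead], count_copies: bool = False
) -> list[DensityRecord]:
    """pair_density for many pairs with a sorted window query per chromosome."""
    by_chrom: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)
    starts = {c: np.array([r.start for r in lst]) for c, lst in by_chrom.items()}
    records = []
    for pair in pairs:
        subset: Sequence[MappedRead] = ()
        if pair.chrom in by_chrom:
            lo, hi = pair.union_span
            arr = starts[pair.chrom]
            i0 = int(np.searchsorted(arr, lo - 40, side="left"))
            i1 = int(np.searchsorted(arr, hi, side="left"))
            subset = by_chrom[pair.chrom][i0:i1]
        records.append(pair_density(pair, subset, count_copies=count_copies))
    return records


def paired_density_test(records: Sequence[DensityRecord]) -> EnrichmentResult:
    """One-tail paired two-sample t-test of d_o vs d_g over testable pairs.

    Degenerate zero-variance differences are resolved by the sign of the
    mean difference (p = 0 / 0.5 / 1 for positive / zero / negative).
    """
    usable = [r for r in records if r.testable]
    if len(usable) < 2:
        raise ValueError(f"insufficient pairs for the paired test: {len(usable)} testable")
    d_o = np.array([r.d_o for r in usable])
    d_g = np.array([r.d_g for r in usable])
    diffs = d_o - d_g
    dof = len(usable) - 1
    if np.allclose(diffs.std(ddof=1), 0.0):
        mean = diffs.mean()
        if mean > 0:
            t, p = float("inf"), 0.0
        elif mean < 0:
            t, p = float("-inf"), 1.0
        else:
            t, p = 0.0, 0.5
    else:
        res = stats.ttest_rel(d_o, d_g, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    return EnrichmentResult(
        t_stat=t, dof=dof, p_one_tail=p, a_o=float(d_o.mean()), a_g=float(d_g.mean())
    )


def resampling_comparison(
    target_regions: Sequence[tuple[int, int]],
    candidate_pool: Sequence[GeneModel],
    loci_positions: Mapping[str, np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
) -> ResamplingResult:
    """Compare target region densities with size-matched random genic windows.

    ``target_regions`` are (length, n_loci) pairs (e.g. overlap regions of
    convergent NATs); ``candidate_pool`` supplies non-NAT genes from which
    windows of exactly each target length are drawn uniformly (a window
    may extend past a short gene's end — clipped/extended matching).
    ``loci_positions`` maps chromosome to the sorted first-nt positions of
    distinct sRNA loci. The empirical p is the frequency of resampled
    means A_u exceeding the observed mean A_o; deterministic given seed.
    """
    if not candidate_pool:
        lengths = sorted({length for length, _ in target_regions})
        raise ValueError(f"candidate pool is empty; unmatched target lengths: {lengths}")
    rng = np.random.default_rng(seed)
    a_o = float(np.mean([n / length for length, n in target_regions]))

    pool = sorted(candidate_pool, key=lambda g: (g.chrom, g.span[0], g.gene_id))
    pool_lens = np.array([g.length for g in pool])
    sorted_loci = {c: np.asarray(pos) for c, pos in loci_positions.items()}

    samples = np.empty(n_perm)
    for i in range(n_perm):
        densities = []
        for length, _ in target_regions:
            fits = np.flatnonzero(pool_lens >= length)
            gi = int(rng.choice(fits)) if fits.size else int(rng.integers(len(pool)))
            gene = pool[gi]
            max_off = max(1, gene.length - length + 1)
            start = gene.span[0] + int(rng.integers(max_off))
            pos = sorted_loci.get(gene.chrom, np.empty(0))
            n = int(np.searchsorted(pos, start + length) - np.searchsorted(pos, start))
            densities.append(n / length)
        samples[i] = np.mean(densities)
    return ResamplingResult(a_o=a_o, a_u_samples=samples, n_perm=n_perm, seed=seed)


def loci_position_index(reads: Iterable[MappedRead]) -> dict[str, np.ndarray]:
    """Sorted first-nt positions of distinct loci per chromosome."""
    seen: dict[str, set[tuple]] = {}
    for r in reads:
        seen.setdefault(r.chrom, set()).add((r.sequence, r.start, r.strand))
    return {c: np.sort(np.array([k[1] for k in keys])) for c, keys in seen.items()}
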