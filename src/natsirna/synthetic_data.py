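"""Synthetic genomes, NAT annotations, stranded sRNA libraries, and
expression matrices with known ground truth.

The generator emulates the statistical structure the analysis assumes:
NAT pairs of all three topologies, overlap-region read enrichment at a
configurable factor, hotspot (site-specific) vs uniform (distributed)
read placement, strand bias, the 20-22 / 23-28 nt size mixture,
per-condition abundance shifts against a mock control, and an expression
matrix with spiked up-regulated genes. Everything is deterministic given
the master seed; each component draws from a named substream so stages
can be regenerated independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Genome, Library, MappedRead, write_bed, write_gff3
from .nat_discovery import make_pair
from .util import revcomp, substream

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class HotspotSpec:
    """Site-specific placement: ``fraction`` of a pair's reads start within
    ``k`` windows of ``width`` nt inside the overlap."""

    k: int = 2
    width: int = 8
    fraction: float = 0.8


@dataclass
class LibrarySpec:
    condition: str
    depth: int = 50_000
    control: str | None = None  # condition name of the matched control


@dataclass
class ExpressionSpec:
    n_genes: int = 1000
    n_spiked: int = 50
    effect: float = 2.0  # fold change of spiked genes in the mutant group
    noise_sd: float = 0.25  # log2 units
    replicates: int = 5
    baseline_log2: tuple[float, float] = (6.0, 10.0)


def default_libraries() -> list[LibrarySpec]:
    """Mock control plus the three abiotic stress conditions."""
    return [
        LibrarySpec("mock"),
        LibrarySpec("salt", control="mock"),
        LibrarySpec("cold", control="mock"),
        LibrarySpec("drought", control="mock"),
    ]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_convergent: int = 4
    n_divergent: int = 3
    n_enclosed: int = 3
    gene_len_range: tuple[int, int] = (800, 2000)
    overlap_len_range: tuple[int, int] = (100, 400)
    n_decoys: int = 20
    n_excluded_pairs: int = 0
    enrichment_factor: float = 6.0
    default_pattern: HotspotSpec | None = None  # None -> uniform (distributed)
    patterns: dict[int, HotspotSpec | None] = field(default_factory=dict)  # per pair index
    strand_bias: float = 3.0
    size_mix: tuple[float, float] = (0.5, 0.5)  # weights for 20-22 / 23-28 nt
    first_nt_dist: dict[str, float] | None = None
    reads_per_pair: float = 200.0
    decoy_reads: bool = True  # give non-NAT genes baseline-density reads
    libraries: list[LibrarySpec] = field(default_factory=default_libraries)
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    intron_prob: float = 0.5
    gap_range: tuple[int, int] = (200, 500)
    chrom: str = "chr1"
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def __post_init__(self) -> None:
        if self.overlap_len_range[0] <= 25:
            raise ValueError(
                "overlap_len_range minimum must exceed 25 nt; shorter overlaps are "
                "undiscoverable by pair discovery"
            )
        if self.overlap_len_range[1] > self.gene_len_range[0] - 50:
            raise ValueError("infeasible geometry: overlaps must fit inside the shortest gene")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        if not np.isclose(sum(self.size_mix), 1.0):
            raise ValueError("size_mix weights must sum to 1")

    @property
    def n_pairs(self) -> int:
        return self.n_convergent + self.n_divergent + self.n_enclosed

    def pattern_for(self, pair_index: int) -> HotspotSpec | None:
        return self.patterns.get(pair_index, self.default_pattern)


@dataclass
class GroundTruth:
    pairs: pd.DataFrame  # pair_id, topology, enrichment, pattern, strand_bias
    hotspots: dict[str, list[int]]  # pair_id -> hotspot anchor positions
    condition_effects: dict[str, dict[str, float]]
    spiked_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _maybe_intron(rng: np.random.Generator, span: tuple[int, int], prob: float) -> list[tuple[int, int]]:
    s, e = span
    length = e - s
    if rng.random() >= prob or length < 300:
        return [span]
    ilen = int(length * 0.15)
    istart = s + int(length * 0.4)
    return [(s, istart), (istart + ilen, e)]


def generate_genome_and_annotation(
    config: SyntheticConfig,
) -> tuple[Genome, list[GeneModel], GroundTruth]:
    """Plant NAT pairs of each topology plus decoy genes on a random chromosome."""
    rng = substream(config.seed, "genome")
    cursor = int(rng.integers(*config.gap_range))
    genes: list[GeneModel] = []
    truth_rows = []

    topologies = (
        ["convergent"] * config.n_convergent
        + ["divergent"] * config.n_divergent
        + ["enclosed"] * config.n_enclosed
    )
    excluded_biotypes = ["tRNA", "rRNA", "snoRNA", "miRNA", "transposon"]

    def add_pair(i: int, topology: str, biotype_b: str = "protein_coding") -> None:
        nonlocal cursor
        la = int(rng.integers(*config.gene_len_range))
        lb = int(rng.integers(*config.gene_len_range))
        lov = min(int(rng.integers(*config.overlap_len_range)), min(la, lb) - 50)
        if topology == "convergent":
            sa, strand_a = cursor, "+"
            sb, strand_b = cursor + la - lov, "-"
            spans = [(sa, sa + la), (sb, sb + lb)]
        elif topology == "divergent":
            sa, strand_a = cursor, "-"
            sb, strand_b = cursor + la - lov, "+"
            spans = [(sa, sa + la), (sb, sb + lb)]
        else:  # enclosed: gene b inside gene a
            lb = lov
            sa, strand_a = cursor, "+" if rng.random() < 0.5 else "-"
            strand_b = "-" if strand_a == "+" else "+"
            sb = sa + int(rng.integers(1, la - lb))
            spans = [(sa, sa + la), (sb, sb + lb)]
        ga = GeneModel(
            gene_id=f"NATG{i:04d}A",
            chrom=config.chrom,
            strand=strand_a,
            span=spans[0],
            exons=_maybe_intron(rng, spans[0], config.intron_prob),
        )
        gb = GeneModel(
            gene_id=f"NATG{i:04d}B",
            chrom=config.chrom,
            strand=strand_b,
            span=spans[1],
            exons=_maybe_intron(rng, spans[1], config.intron_prob),
            biotype=biotype_b,
        )
        genes.extend([ga, gb])
        pair = make_pair(ga, gb)
        assert pair is not None and pair.topology == topology
        truth_rows.append(
            {
                "pair_id": pair.pair_id,
                "topology": topology,
                "enrichment": config.enrichment_factor,
                "pattern": "site_specific" if config.pattern_for(i) else "distributed",
                "strand_bias": config.strand_bias,
                "excluded": biotype_b != "protein_coding",
            }
        )
        cursor = max(s[1] for s in spans) + int(rng.integers(*config.gap_range))

    for i, topo in enumerate(topologies):
        add_pair(i, topo)
    for j in range(config.n_excluded_pairs):
        add_pair(config.n_pairs + j, "convergent", biotype_b=str(rng.choice(excluded_biotypes)))

    for d in range(config.n_decoys):
        length = int(rng.integers(*config.gene_len_range))
        strand = "+" if rng.random() < 0.5 else "-"
        span = (cursor, cursor + length)
        utr_len = max(30, int(length * 0.15))
        left = (span[0], span[0] + utr_len)
        right = (span[1] - utr_len, span[1])
        genes.append(
            GeneModel(
                gene_id=f"DECOY{d:04d}",
                chrom=config.chrom,
                strand=strand,
                span=span,
                exons=_maybe_intron(rng, span, config.intron_prob),
                utr5=left if strand == "+" else right,
                utr3=right if strand == "+" else left,
            )
        )
        cursor = span[1] + int(rng.integers(*config.gap_range))

    genome = Genome({config.chrom: _random_sequence(rng, cursor + int(rng.integers(*config.gap_range)))})

    # hotspot anchors live inside each pair's overlap, clear of its edges
    hs_rng = substream(config.seed, "hotspots")
    hotspots: dict[str, list[int]] = {}
    for i, row in enumerate(truth_rows):
        spec = config.pattern_for(i) if not row["excluded"] else None
        if spec is None:
            continue
        pair = make_pair(genes[2 * i], genes[2 * i + 1])
        assert pair is not None
        lo = pair.overlap[0] + 5
        hi = pair.overlap[1] - 40
        anchors = sorted(int(a) for a in hs_rng.integers(lo, max(lo + 1, hi), spec.k))
        hotspots[row["pair_id"]] = anchors

    truth = GroundTruth(
        pairs=pd.DataFrame(truth_rows),
        hotspots=hotspots,
        condition_effects=dict(config.condition_effects),
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _nonoverlap_segments(pair) -> list[tuple[int, int]]:
    segs = []
    for g in pair.genes:
        if g.span[0] < pair.overlap[0]:
            segs.append((g.span[0], pair.overlap[0]))
        if g.span[1] > pair.overlap[1]:
            segs.append((pair.overlap[1], g.span[1]))
    return segs


def _draw_length(rng: np.random.Generator, size_mix: tuple[float, float]) -> int:
    if rng.random() < size_mix[0]:
        return int(rng.integers(20, 23))
    return int(rng.integers(23, 29))


def _effect_multiplier(effects: dict[str, float] | None, condition: str) -> float:
    if not effects or condition not in effects:
        return 1.0
    fc = effects[condition]
    return fc if fc >= 1 else 1.0 / abs(fc)


def simulate_reads(
    config: SyntheticConfig,
    genome: Genome,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
) -> tuple[dict[str, list[MappedRead]], dict[str, Library]]:
    """Per-library mapped reads honouring the configured enrichment,
    pattern, bias, size mixture, and condition effects.

    Read start positions fall inside the overlap with probability
    E*L_o / (E*L_o + L_g) (density ratio E), or into hotspot windows for
    site-specific pairs. Intergenic background reads top each library up
    to its configured depth.
    """
    chrom_seq = genome.sequences[config.chrom]
    pairs = []
    for i in range(len(truth.pairs)):
        pair = make_pair(genes[2 * i], genes[2 * i + 1])
        assert pair is not None
        pairs.append(pair)

    gene_spans = sorted(g.span for g in genes)
    gaps, prev = [], 0
    for s, e in gene_spans:
        if s > prev + 60:
            gaps.append((prev + 10, s - 40))
        prev = max(prev, e)
    if len(chrom_seq) > prev + 60:
        gaps.append((prev + 10, len(chrom_seq) - 40))
    gap_lens = np.array([e - s for s, e in gaps], dtype=float)

    plus_prob = config.strand_bias / (1.0 + config.strand_bias)
    reads_by_lib: dict[str, list[MappedRead]] = {}
    libraries: dict[str, Library] = {}

    for spec in config.libraries:
        lib_id = spec.condition
        rng = substream(config.seed, f"reads:{lib_id}")
        reads: list[MappedRead] = []
        if spec.depth <= 0:
            log.warning("library %s has depth 0; emitting an empty library", lib_id)
            reads_by_lib[lib_id] = []
            libraries[lib_id] = Library(
                library_id=lib_id, condition=spec.condition,
                control_id=spec.control, total_mapped=0,
            )
            continue

        for i, pair in enumerate(pairs):
            row = truth.pairs.iloc[i]
            effects = truth.condition_effects.get(row["pair_id"])
            expected = config.reads_per_pair * _effect_multiplier(effects, spec.condition)
            n_reads = int(rng.poisson(expected))
            spot_anchors = truth.hotspots.get(row["pair_id"])
            spec_i = config.pattern_for(i)
            lo_ov, hi_ov = pair.overlap
            l_o = pair.overlap_len
            l_g = pair.nonoverlap_len
            p_ov = (
                config.enrichment_factor * l_o / (config.enrichment_factor * l_o + l_g)
                if (config.enrichment_factor * l_o + l_g) > 0
                else 1.0
            )
            segs = _nonoverlap_segments(pair)
            seg_lens = np.array([e - s for s, e in segs], dtype=float)

            for _ in range(n_reads):
                length = _draw_length(rng, config.size_mix)
                if spot_anchors and spec_i and rng.random() < spec_i.fraction:
                    anchor = spot_anchors[int(rng.integers(len(spot_anchors)))]
                    start = anchor + int(rng.integers(spec_i.width))
                elif rng.random() < p_ov and hi_ov - lo_ov > length:
                    start = int(rng.integers(lo_ov, hi_ov - length))
                else:
                    usable = seg_lens > length
                    if not usable.any():
                        start = int(rng.integers(lo_ov, hi_ov - length))
                    else:
                        w = np.where(usable, seg_lens, 0.0)
                        si = int(rng.choice(len(segs), p=w / w.sum()))
                        s, e = segs[si]
                        start = int(rng.integers(s, e - length))
                strand = "+" if rng.random() < plus_prob else "-"
                ref = chrom_seq[start : start + length]
                reads.append(
                    MappedRead(
                        sequence=ref if strand == "+" else revcomp(ref),
                        chrom=config.chrom,
                        start=start,
                        strand=strand,
                        copies=1,
                        library_id=lib_id,
                    )
                )

        # decoy genes carry the genomic baseline density (whole-pair density
        # at E ~ 1), so resampling comparisons against non-NAT genes are
        # meaningful rather than trivially zero
        if config.decoy_reads:
            mean_pair_len = sum(config.gene_len_range) - sum(config.overlap_len_range) / 2
            baseline = config.reads_per_pair / mean_pair_len
            for g in genes:
                if not g.gene_id.startswith("DECOY"):
                    continue
                for _ in range(int(rng.poisson(baseline * g.length))):
                    length = _draw_length(rng, config.size_mix)
                    start = int(rng.integers(g.span[0], g.span[1] - length))
                    strand = "+" if rng.random() < 0.5 else "-"
                    ref = chrom_seq[start : start + length]
                    reads.append(
                        MappedRead(
                            sequence=ref if strand == "+" else revcomp(ref),
                            chrom=config.chrom,
                            start=start,
                            strand=strand,
                            copies=1,
                            library_id=lib_id,
                        )
                    )

        n_bg = spec.depth - len(reads)
        if n_bg > 0 and len(gaps):
            choices = rng.choice(len(gaps), size=n_bg, p=gap_lens / gap_lens.sum())
            for gi in choices:
                s, e = gaps[int(gi)]
                length = _draw_length(rng, config.size_mix)
                start = int(rng.integers(s, max(s + 1, e - length)))
                strand = "+" if rng.random() < 0.5 else "-"
                ref = chrom_seq[start : start + length]
                reads.append(
                    MappedRead(
                        sequence=ref if strand == "+" else revcomp(ref),
                        chrom=config.chrom,
                        start=start,
                        strand=strand,
                        copies=1,
                        library_id=lib_id,
                    )
                )

        reads.sort(key=lambda r: (r.start, r.strand, r.sequence))
        reads_by_lib[lib_id] = reads
        libraries[lib_id] = Library(
            library_id=lib_id,
            condition=spec.condition,
            control_id=spec.control,
            total_mapped=sum(r.copies for r in reads),
        )
    return reads_by_lib, libraries


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str]], list[str]]:
    """Log-normal expression with spiked up-regulated genes in the mutant group.

    Returns (matrix, replicate pairing, spiked gene ids); the matrix has
    one column per sample named ``mutant_j`` / ``control_j``.
    """
    spec = config.expression
    if spec.replicates < 2:
        raise ValueError("expression simulation needs >= 2 replicates")
    rng = substream(config.seed, "expression")
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    spiked_idx = rng.choice(spec.n_genes, size=spec.n_spiked, replace=False)
    spiked = sorted(genes[i] for i in spiked_idx)
    baseline = rng.uniform(*spec.baseline_log2, spec.n_genes)
    shift = np.zeros(spec.n_genes)
    shift[spiked_idx] = np.log2(spec.effect)

    data = {}
    pairing = []
    for j in range(1, spec.replicates + 1):
        data[f"mutant_{j}"] = np.exp2(baseline + shift + rng.normal(0, spec.noise_sd, spec.n_genes))
        data[f"control_{j}"] = np.exp2(baseline + rng.normal(0, spec.noise_sd, spec.n_genes))
        pairing.append((f"mutant_{j}", f"control_{j}"))
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return matrix, pairing, spiked


# ---------------------------------------------------------------------------
# Disk emission
# ---------------------------------------------------------------------------


def write_fastq(reads: Iterable[MappedRead], path: str | Path) -> None:
    """Emit reads as FASTQ, one record per copy (copies encoded by repetition)."""
    with open(path, "w") as fh:
        n = 0
        for r in reads:
            for _ in range(r.copies):
                n += 1
                fh.write(f"@sr{n}\n{r.sequence}\n+\n{'I' * r.length}\n")


def emit_dataset(config: SyntheticConfig, outdir: str | Path) -> Path:
    """Generate everything and write genome.fa, ann.gff3, per-library
    FASTQ + BED, libraries.tsv, expr.tsv, and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome_and_annotation(config)
    genome.to_fasta(outdir / "genome.fa")
    write_gff3(genes, outdir / "ann.gff3")

    reads_by_lib, libraries = simulate_reads(config, genome, genes, truth)
    lib_rows = []
    for lib_id, reads in sorted(reads_by_lib.items()):
        write_fastq(reads, outdir / f"lib_{lib_id}.fq")
        write_bed(reads, outdir / f"lib_{lib_id}.bed")
        lib = libraries[lib_id]
        lib_rows.append(
            (lib.library_id, lib.condition, lib.control_id or "", lib.total_mapped)
        )
    pd.DataFrame(
        lib_rows, columns=["library_id", "condition", "control_id", "total_mapped"]
    ).to_csv(outdir / "libraries.tsv", sep="\t", index=False)

    matrix, pairing, spiked = simulate_expression(config)
    matrix.to_csv(outdir / "expr.tsv", sep="\t")
    truth.spiked_genes = spiked

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.pairs.to_csv(truth_dir / "pairs.tsv", sep="\t", index=False)
    pd.Series(spiked, name="gene").to_csv(truth_dir / "spiked_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p, ",".join(map(str, a))) for p, a in sorted(truth.hotspots.items())],
        columns=["pair_id", "anchors"],
    ).to_csv(truth_dir / "hotspots.tsv", sep="\t", index=False)
    return outdir
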