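"""genome_io: GFF3 parsing, trimming/collapsing, exact mapping, BED round trip."""

import io

import numpy as np
import pytest

from natsirna.genome_io import (
    AnnotationError,
    Genome,
    KmerIndex,
    RawRead,
    load_bed,
    map_reads_exact,
    parse_annotation,
    trim_and_filter,
    write_bed,
)
from natsirna.util import revcomp

GFF_HEADER = "##gff-version 3\n"


def gff_gene(gene_id, start, end, strand="+", exons=None, mrnas=None):
    """1-based inclusive GFF3 text for one gene."""
    lines = [f"chr1\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"]
    mrnas = mrnas or [(start, end, exons or [(start, end)])]
    for i, (ms, me, mexons) in enumerate(mrnas, 1):
        mid = f"{gene_id}.m{i}"
        lines.append(f"chr1\tsrc\tmRNA\t{ms}\t{me}\t.\t{strand}\t.\tID={mid};Parent={gene_id}")
        for j, (xs, xe) in enumerate(mexons, 1):
            lines.append(
                f"chr1\tsrc\texon\t{xs}\t{xe}\t.\t{strand}\t.\tID={mid}.e{j};Parent={mid}"
            )
    return "\n".join(lines) + "\n"


class TestParseAnnotation:
    def test_coordinate_conversion_single_exon(self):
        genes = parse_annotation(GFF_HEADER + gff_gene("g1", 1, 100))
        (g,) = genes
        assert g.span == (0, 100)
        assert g.introns == []

    def test_intron_derived_from_exon_gaps(self):
        genes = parse_annotation(GFF_HEADER + gff_gene("g1", 1, 120, exons=[(1, 50), (81, 120)]))
        (g,) = genes
        assert g.introns == [(50, 80)]

    def test_longest_transcript_is_representative(self):
        text = GFF_HEADER + gff_gene(
            "g1", 1, 500, mrnas=[(1, 300, [(1, 300)]), (1, 500, [(1, 500)])]
        )
        (g,) = parse_annotation(text)
        assert g.span == (0, 500)

    def test_exon_outside_gene_span_names_gene(self):
        text = GFF_HEADER + gff_gene("gBAD", 100, 200, mrnas=[(100, 200, [(50, 150)])])
        with pytest.raises(AnnotationError, match="gBAD"):
            parse_annotation(text)

    def test_malformed_line_reports_line_number(self):
        text = GFF_HEADER + "chr1\tsrc\tgene\t1\t100\t.\t+\n"  # 8 fields
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotation(text)

    def test_non_numeric_coordinates_rejected(self):
        text = GFF_HEADER + "chr1\tsrc\tgene\tone\t100\t.\t+\t.\tID=g1\n"
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotation(text)


class TestTrimAndFilter:
    ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"

    @pytest.mark.parametrize(
        "insert_len,kept",
        [(16, False), (17, True), (28, True), (29, False)],
    )
    def test_length_window_boundaries(self, insert_len, kept):
        insert = "AC" * 15
        raw = [RawRead("r1", insert[:insert_len] + self.ADAPTOR)]
        out = trim_and_filter(raw, adaptor=self.ADAPTOR)
        assert (len(out) == 1) == kept
        if kept:
            assert out[0].sequence == insert[:insert_len]

    def test_identical_inserts_collapse_with_summed_copies(self):
        seq = "ACGTACGTACGTACGTACGTA"
        out = trim_and_filter([RawRead("a", seq), RawRead("b", seq)])
        assert len(out) == 1 and out[0].copies == 2

    def test_copy_conservation_through_collapsing(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(30)]
        raw = [RawRead(f"r{i}", seqs[rng.integers(len(seqs))], copies=int(rng.integers(1, 5)))
               for i in range(200)]
        out = trim_and_filter(raw)
        assert sum(r.copies for r in out) == sum(r.copies for r in raw)

    def test_read_without_adaptor_kept_untrimmed_unless_required(self):
        raw = [RawRead("r1", "ACGTACGTACGTACGTACGTA")]
        assert len(trim_and_filter(raw, adaptor=self.ADAPTOR)) == 1
        assert trim_and_filter(raw, adaptor=self.ADAPTOR, require_adaptor=True) == []

    def test_empty_input_is_empty_output(self):
        assert trim_and_filter([]) == []

    def test_empty_adaptor_rejected(self):
        with pytest.raises(ValueError):
            trim_and_filter([RawRead("r", "ACGT" * 6)], adaptor="")


def brute_force_placements(genome: Genome, query: str):
    """Independent all-substring scan over both strands."""
    hits = []
    for chrom, seq in genome.sequences.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            for i in range(len(seq) - len(q) + 1):
                if seq[i : i + len(q)] == q:
                    hits.append((chrom, i, strand))
    return sorted(hits)


class TestExactMapper:
    def test_forward_hits_found_by_seed_and_verify(self):
        genome = Genome({"c": "ACGTACGTAC"})
        hits = KmerIndex(genome, k=4).find("GTACG")
        assert hits == [("c", 2)]

    def test_reverse_complement_hit_reported_on_minus_strand(self):
        genome = Genome({"c": "ACGTACGTACGTACGTACGTACGT"})
        query = revcomp(genome.sequences["c"][3:24])
        mapped = map_reads_exact([RawRead("r", query)], genome)
        assert [(m.start, m.strand) for m in mapped if m.strand == "-"] == [(3, "-")]

    def test_single_mismatch_yields_zero_hits(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 500))
        genome = Genome({"c": seq})
        query = seq[100:121]
        mutated = query[:10] + ("A" if query[10] != "A" else "C") + query[11:]
        if not brute_force_placements(genome, mutated):
            assert map_reads_exact([RawRead("r", mutated)], genome) == []

    def test_reads_with_n_are_not_placed(self):
        genome = Genome({"c": "ACGTACGTACGTACGTACGTACGT"})
        assert map_reads_exact([RawRead("r", "ACGTACGTACGTACGTACGN")], genome) == []

    def test_agrees_with_substring_scan_on_random_genome(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        genome = Genome({"c": seq})
        idx = KmerIndex(genome)
        for _ in range(50):
            if rng.random() < 0.7:
                start = int(rng.integers(0, 1970))
                q = seq[start : start + int(rng.integers(17, 29))]
                if rng.random() < 0.5:
                    q = revcomp(q)
            else:
                q = "".join(rng.choice(list("ACGT"), int(rng.integers(17, 29))))
            mapped = map_reads_exact([RawRead("r", q)], genome, index=idx)
            assert sorted((m.chrom, m.start, m.strand) for m in mapped) == brute_force_placements(
                genome, q
            )

    def test_multi_mapping_reported_at_every_locus(self):
        unit = "ACGTACGTACGTACGTACGTA"
        genome = Genome({"c": unit + "CCCCC" + unit})
        mapped = map_reads_exact([RawRead("r", unit, copies=3)], genome)
        plus = [m for m in mapped if m.strand == "+"]
        assert [m.start for m in plus] == [0, 26]
        assert all(m.copies == 3 for m in plus)
        assert map_reads_exact([RawRead("r", unit)], genome, unique_only=True) == []


class TestBed:
    def test_field_mapping_and_interval_length(self):
        reads, skipped = load_bed(io.StringIO("chr1\t100\t121\tseqX\t3\t+\n"), library_id="L")
        (r,) = reads
        assert (r.start, r.length, r.copies, r.strand, r.library_id) == (100, 21, 3, "+", "L")
        assert skipped == 0

    def test_missing_strand_skipped_with_warning_count(self):
        reads, skipped = load_bed(io.StringIO("chr1\t100\t121\tseqX\t3\t.\n"))
        assert reads == [] and skipped == 1

    def test_empty_file(self):
        assert load_bed(io.StringIO("")) == ([], 0)

    def test_round_trip_record_for_record(self, tmp_path):
        from natsirna.genome_io import MappedRead

        rng = np.random.default_rng(3)
        originals = [
            MappedRead(
                sequence="".join(rng.choice(list("ACGT"), int(rng.integers(17, 29)))),
                chrom=f"chr{rng.integers(1, 3)}",
                start=int(rng.integers(0, 5000)),
                strand="+-"[int(rng.integers(2))],
                copies=int(rng.integers(1, 9)),
            )
            for _ in range(40)
        ]
        path = tmp_path / "x.bed"
        write_bed(originals, path)
        loaded, skipped = load_bed(path, library_id="L1")
        assert skipped == 0
        assert [(r.chrom, r.start, r.end, r.sequence, r.copies, r.strand) for r in loaded] == [
            (o.chrom, o.start, o.end, o.sequence, o.copies, o.strand) for o in originals
        ]


class TestGenomeValidation:
    def test_rejects_empty_and_non_acgtn(self):
        with pytest.raises(ValueError):
            Genome({"c": ""})
        with pytest.raises(ValueError):
            Genome({"c": "ACGU"})
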