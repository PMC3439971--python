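"""enrichment_stats: density records, paired t-test, resampling comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from natsirna.enrichment_stats import (
    DensityRecord,
    loci_position_index,
    pair_densities,
    pair_density,
    paired_density_test,
    resampling_comparison,
)
from tests.conftest import gene, read


def textbook_paired_t(x, y):
    """Independent oracle: the paired two-sample t formula, one-tail p."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 1.0 - stats.t.cdf(t, df=n - 1)
    return t, p


class TestPairDensity:
    def test_density_arithmetic(self, convergent_pair):
        # overlap [900,1000): 5 loci; elsewhere in the genes: 9 loci
        reads = [read(900 + 2 * i, seq="A" * 20 + "ACGT"[i % 4], strand="+") for i in range(5)]
        reads += [read(100 + 50 * i, seq="C" * 20 + "ACGT"[i % 4]) for i in range(9)]
        rec = pair_density(convergent_pair, reads)
        assert (rec.n_overlap, rec.n_nonoverlap) == (5, 9)
        assert rec.d_o == pytest.approx(5 / 100)
        assert rec.d_g == pytest.approx(9 / 1700)

    def test_duplicate_copies_at_one_locus_count_once(self, convergent_pair):
        reads = [read(920, seq="A" * 21, copies=5), read(920, seq="A" * 21, copies=3)]
        rec = pair_density(convergent_pair, reads)
        assert rec.n_overlap == 1
        rec_c = pair_density(convergent_pair, reads, count_copies=True)
        assert rec_c.n_overlap == 8

    def test_pair_without_srnas_is_not_testable(self, convergent_pair):
        rec = pair_density(convergent_pair, [])
        assert rec.d_o == 0 and not rec.testable

    def test_zero_nonoverlap_length_flagged_non_testable(self):
        rec = DensityRecord("p", n_overlap=3, len_overlap=100, n_nonoverlap=0, len_nonoverlap=0)
        assert rec.d_g is None and not rec.testable

    def test_batched_densities_equal_per_pair_calls(self, convergent_pair, intron_pair):
        rng = np.random.default_rng(3)
        reads = [
            read(int(rng.integers(0, 1800)), strand="+-"[int(rng.integers(2))],
                 seq="".join(rng.choice(list("ACGT"), 21)))
            for _ in range(200)
        ]
        pairs = [convergent_pair, intron_pair]
        batched = pair_densities(pairs, reads)
        single = [pair_density(p, reads) for p in pairs]
        assert [(r.n_overlap, r.n_nonoverlap) for r in batched] == [
            (r.n_overlap, r.n_nonoverlap) for r in single
        ]


class TestPairedTest:
    def test_identical_densities_give_t0_p_half_score_1(self):
        recs = [
            DensityRecord(f"p{i}", n_overlap=2, len_overlap=100, n_nonoverlap=20, len_nonoverlap=1000)
            for i in range(5)
        ]
        res = paired_density_test(recs)
        assert res.t_stat == 0.0 and res.p_one_tail == 0.5 and res.score == 1.0

    def test_hand_computed_example(self):
        # d_o = (.5,.6,.7), d_g = (.1,.2,.1) -> t = 7, dof 2, score 4.5
        recs = [
            DensityRecord("a", 50, 100, 10, 100),
            DensityRecord("b", 60, 100, 20, 100),
            DensityRecord("c", 70, 100, 10, 100),
        ]
        res = paired_density_test(recs)
        assert res.t_stat == pytest.approx(7.0, abs=1e-12)
        assert res.dof == 2
        assert res.score == pytest.approx(4.5)

    def test_matches_textbook_formula_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            d_o = rng.random(n)
            d_g = rng.random(n)
            recs = [
                DensityRecord(f"p{i}", int(d_o[i] * 1e6), 10**6, int(d_g[i] * 1e6), 10**6)
                for i in range(n)
            ]
            res = paired_density_test(recs)
            t_ref, p_ref = textbook_paired_t([r.d_o for r in recs], [r.d_g for r in recs])
            assert res.t_stat == pytest.approx(t_ref, abs=1e-10)
            assert res.p_one_tail == pytest.approx(p_ref, abs=1e-10)

    def test_insufficient_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            paired_density_test([DensityRecord("p", 1, 100, 1, 100)])

    def test_zero_variance_positive_difference_gives_p0(self):
        recs = [DensityRecord(f"p{i}", 10, 100, 10, 1000) for i in range(4)]
        res = paired_density_test(recs)
        assert res.p_one_tail == 0.0 and res.t_stat == float("inf")


class TestResampling:
    def _pool(self, n=30, length=1000, gap=500):
        return [gene(f"d{i}", i * (length + gap), i * (length + gap) + length) for i in range(n)]

    def test_zero_read_pool_with_positive_target_gives_p0(self):
        res = resampling_comparison(
            [(100, 5), (200, 8)], self._pool(), {"chr1": np.array([])}, n_perm=200, seed=1
        )
        assert res.p_empirical == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        loci = {"chr1": np.sort(rng.integers(0, 45000, 400))}
        targets = [(150, 3), (300, 7)]
        a = resampling_comparison(targets, self._pool(), loci, n_perm=300, seed=9)
        b = resampling_comparison(targets, self._pool(), loci, n_perm=300, seed=9)
        assert np.array_equal(a.a_u_samples, b.a_u_samples)
        assert a.p_empirical == b.p_empirical

    def test_self_like_targets_give_intermediate_p(self):
        # targets drawn from the same density regime as the pool: p near 0.5
        rng = np.random.default_rng(5)
        pool = self._pool(n=50)
        positions = np.sort(
            np.concatenate([rng.integers(g.span[0], g.span[1], 20) for g in pool])
        )
        loci = {"chr1": positions}
        targets = []
        for g in pool[:10]:
            length = 400
            start = g.span[0] + 100
            n = int(np.searchsorted(positions, start + length) - np.searchsorted(positions, start))
            targets.append((length, n))
        res = resampling_comparison(targets, pool, loci, n_perm=1000, seed=3)
        assert 0.2 < res.p_empirical < 0.8

    def test_empty_pool_lists_unmatched_lengths(self):
        with pytest.raises(ValueError, match="150"):
            resampling_comparison([(150, 2)], [], {"chr1": np.array([])}, n_perm=10, seed=0)

    def test_p_decreases_with_simulated_enrichment(self):
        from natsirna.nat_discovery import find_nat_pairs
        from natsirna.synthetic_data import LibrarySpec, SyntheticConfig, generate_genome_and_annotation, simulate_reads

        # the comparison is per-topology (convergent overlaps vs ordinary
        # genic windows), so only convergent pairs are simulated
        med_p = {}
        for E in (1.0, 6.0):
            ps = []
            for seed in range(5):
                cfg = SyntheticConfig(
                    seed=seed, n_convergent=30, n_divergent=0, n_enclosed=0,
                    n_decoys=40, enrichment_factor=E, reads_per_pair=120.0,
                    libraries=[LibrarySpec("mock", depth=4200)],
                )
                genome, genes, truth = generate_genome_and_annotation(cfg)
                reads, _ = simulate_reads(cfg, genome, genes, truth)
                all_reads = reads["mock"]
                pairs = find_nat_pairs(genes)
                recs = pair_densities(pairs, all_reads)
                targets = [(r.len_overlap, r.n_overlap) for r in recs]
                pool = [g for g in genes if g.gene_id.startswith("DECOY")]
                res = resampling_comparison(
                    targets, pool, loci_position_index(all_reads), n_perm=500, seed=seed
                )
                ps.append(res.p_empirical)
            med_p[E] = float(np.median(ps))
        assert med_p[6.0] < med_p[1.0]
        assert med_p[6.0] <= 0.05


class TestParameterRecovery:
    def test_null_enrichment_p_values_are_uniform(self):
        """Under E = 1 the paired-test p-values follow U(0,1) (KS p > 0.01)."""
        from natsirna.nat_discovery import find_nat_pairs
        from natsirna.synthetic_data import LibrarySpec, SyntheticConfig, generate_genome_and_annotation, simulate_reads

        ps = []
        for seed in range(200):
            cfg = SyntheticConfig(
                seed=seed, n_convergent=10, n_divergent=10, n_enclosed=10,
                n_decoys=0, enrichment_factor=1.0, reads_per_pair=150.0,
                libraries=[LibrarySpec("mock", depth=4500)],
            )
            genome, genes, truth = generate_genome_and_annotation(cfg)
            reads, _ = simulate_reads(cfg, genome, genes, truth)
            pairs = find_nat_pairs(genes)
            res = paired_density_test(pair_densities(pairs, reads["mock"]))
            ps.append(res.p_one_tail)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
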