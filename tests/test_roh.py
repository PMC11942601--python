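import numpy as np
import pytest

from rohped.roh import (
    RohParams,
    RohSegment,
    classify_lengths,
    detect_roh,
    min_snp_count,
    params_from_data,
    per_individual_stats,
)

from conftest import make_gm
from oracles import oracle_detect_roh

SMALL = RohParams(window_snps=15, min_snps_in_roh=30, min_length_kb=1000)


class TestMinSnpCount:
    @pytest.mark.parametrize("alpha,het,n_snps,n_indiv,expected", [
        (0.05, 0.273, 64_373, 675, 64),
        (1.0, 0.5, 1, 1, 0),
        (0.05, 0.5, 1, 1, 4),  # ln(0.05)/ln(0.5) = 4.32, floored
    ])
    def test_examples(self, alpha, het, n_snps, n_indiv, expected):
        l, _ = min_snp_count(alpha, het, n_snps, n_indiv)
        assert l == expected

    def test_derived_min_length(self):
        _, min_len = min_snp_count(0.05, 0.273, 64_373, 675, mean_spacing_kb=34.84)
        assert min_len == 2230

    @pytest.mark.parametrize("het", [0.0, 1.0])
    def test_degenerate_heterozygosity_rejected(self, het):
        with pytest.raises(ValueError):
            min_snp_count(0.05, het, 100, 10)

    def test_params_from_data(self):
        p = params_from_data(0.05, 0.273, 64_373, 675, 34.84)
        assert p.min_snps_in_roh == 64
        assert p.min_length_kb == 2230


class TestDetect:
    def test_pure_homozygous_run(self):
        gm = make_gm(np.zeros((1, 100), dtype=np.int8), spacing=50_000)  # 5 Mb
        segs = detect_roh(gm, SMALL)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snps) == (50_000, 5_000_000, 100)

    def test_alternating_heterozygotes(self):
        gm = make_gm(np.tile([0, 1], 50).reshape(1, 100).astype(np.int8))
        assert detect_roh(gm, SMALL) == []

    def test_single_interior_heterozygote_retained(self):
        geno = np.zeros(90, dtype=np.int8)
        geno[44] = 1
        pos = (np.arange(90) + 1) * 34_000  # ~3 Mb tract
        gm = make_gm(geno.reshape(1, -1), positions=pos)
        segs = detect_roh(gm, SMALL)
        assert len(segs) == 1
        expect = oracle_detect_roh(list(geno), list(pos), SMALL)
        assert [(s.start_bp, s.end_bp, s.n_snps) for s in segs] == expect

    def test_short_chromosome_yields_nothing(self):
        gm = make_gm(np.zeros((1, 10), dtype=np.int8))
        assert detect_roh(gm, SMALL) == []

    def test_split_at_large_gap(self):
        pos = np.concatenate([(np.arange(50) + 1) * 30_000,
                              1_500_000 + 600_000 + (np.arange(50) + 1) * 30_000])
        gm = make_gm(np.zeros((1, 100), dtype=np.int8), positions=pos)
        params = RohParams(min_snps_in_roh=30, min_length_kb=1000, max_gap_kb=500)
        segs = detect_roh(gm, params)
        assert len(segs) == 2

    def test_matches_exhaustive_oracle_on_random_fixtures(self, rng):
        params = RohParams(window_snps=10, min_snps_in_roh=20, min_length_kb=500,
                           max_gap_kb=300, window_hit_fraction=0.05)
        for _ in range(40):
            n = int(rng.integers(50, 400))
            # homozygosity-enriched genotypes with hom blocks
            geno = rng.choice([0, 1, 2, -1], size=n, p=[0.42, 0.12, 0.42, 0.04]).astype(np.int8)
            if rng.random() < 0.8:
                a = int(rng.integers(0, max(n - 40, 1)))
                b = min(n, a + int(rng.integers(30, 120)))
                geno[a:b] = rng.choice([0, 2], size=b - a)
            pos = np.cumsum(rng.integers(5_000, 60_000, n))
            gm = make_gm(geno.reshape(1, -1), positions=pos)
            got = [(s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(gm, params)]
            assert got == oracle_detect_roh(list(geno), list(pos), params)

    def test_min_length_monotonicity(self, sim_genotypes):
        base = params_from_data(0.05, 0.3, sim_genotypes.n_snps, sim_genotypes.n_samples, 30.0)
        loose = detect_roh(sim_genotypes, base)
        from dataclasses import replace
        strict = detect_roh(sim_genotypes, replace(base, min_length_kb=base.min_length_kb * 2))
        assert len(strict) <= len(loose)

    def test_invariant_to_individual_order(self, sim_genotypes):
        idx = np.arange(sim_genotypes.n_samples)[::-1]
        flipped = sim_genotypes.subset(sample_idx=idx)
        a = {(s.individual, s.chrom, s.start_bp, s.end_bp) for s in detect_roh(sim_genotypes, SMALL)}
        b = {(s.individual, s.chrom, s.start_bp, s.end_bp) for s in detect_roh(flipped, SMALL)}
        assert a == b


def seg(ind, length_mb, chrom=1, start=1_000_000):
    start = int(start)
    return RohSegment(ind, chrom, start, start + int(length_mb * 1e6) - 1, 100)


class TestClassify:
    def test_percentages_from_counts(self):
        counts = {"2-4": 5, "4-8": 3, "8-16": 1, "16-32": 1, ">32": 0}
        segments = []
        rep = {"2-4": 3, "4-8": 5, "8-16": 10, "16-32": 20, ">32": 40}
        for label, n in counts.items():
            for k in range(n):
                segments.append(seg(f"i{label}{k}", rep[label]))
        table = classify_lengths(segments)
        assert table["n_roh"].sum() == 10
        assert table["percent"].sum() == pytest.approx(100.0)
        assert table.set_index("length_class").loc["2-4", "percent"] == pytest.approx(50.0)

    def test_empty_input_all_zero(self):
        table = classify_lengths([])
        assert (table["n_roh"] == 0).all()

    def test_boundary_membership_half_open(self):
        table = classify_lengths([seg("x", 10.0)]).set_index("length_class")
        assert table.loc["8-16", "n_roh"] == 1
        table = classify_lengths([seg("x", 8.0)]).set_index("length_class")
        assert table.loc["8-16", "n_roh"] == 1 and table.loc["4-8", "n_roh"] == 0


class TestPerIndividual:
    def test_two_segments(self):
        stats = per_individual_stats([seg("x", 3.0), seg("x", 5.0, chrom=2)], ["x"])
        row = stats.loc["x"]
        assert row["n_roh"] == 2
        assert row["mean_length_mb"] == pytest.approx(4.0)
        assert row["combined_length_mb"] == pytest.approx(8.0)

    def test_no_segments_reports_zero(self):
        stats = per_individual_stats([seg("x", 3.0)], ["x", "y"])
        assert tuple(stats.loc["y"]) == (0, 0, 0)

    def test_matches_planted_truth(self, sim_population):
        gm, _, truth = sim_population
        from rohped.roh import detect_roh, params_from_data
        params = params_from_data(0.05, 0.3, gm.n_snps, gm.n_samples, 30.0)
        stats = per_individual_stats(detect_roh(gm, params), gm.samples)
        # combined ROH length tracks the true autozygous fraction
        t = truth.true_f[stats.index] * truth.genome_covered_bp / 1e6
        detected = stats["combined_length_mb"]
        assert np.corrcoef(detected, t)[0, 1] > 0.95
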