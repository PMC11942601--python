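import numpy as np
import pytest

from rohped import islands as isl
from rohped.roh import RohSegment

from conftest import make_gm
from oracles import oracle_incidence


def track_from(counts, n_indiv, spacing=50_000):
    """Build an IncidenceTrack directly from per-SNP counts (one chromosome)."""
    segs = []
    pos = (np.arange(len(counts)) + 1) * spacing
    for ind in range(max(counts)):
        # individual `ind` covers SNP j iff counts[j] > ind
        mask = np.array(counts) > ind
        start = None
        for j, ok in enumerate(list(mask) + [False]):
            if ok and start is None:
                start = j
            elif not ok and start is not None:
                segs.append(RohSegment(f"i{ind}", 1, int(pos[start]), int(pos[j - 1]), j - start))
                start = None
    gm = make_gm(np.zeros((n_indiv, len(counts)), dtype=np.int8), positions=pos)
    return isl.incidence(segs, gm.markers, n_indiv), segs, gm


class TestIncidence:
    def test_single_individual_fraction(self):
        gm = make_gm(np.zeros((4, 10), dtype=np.int8))
        segs = [RohSegment("ind0", 1, 100_000, 250_000, 4)]
        track = isl.incidence(segs, gm.markers, 4)
        frac = track.df["fraction"].to_numpy()
        np.testing.assert_allclose(frac[1:5], 0.25)
        assert (frac[[0, 5, 6]] == 0).all()

    def test_all_individuals_share_segment(self):
        gm = make_gm(np.zeros((3, 10), dtype=np.int8))
        segs = [RohSegment(f"ind{i}", 1, 100_000, 300_000, 5) for i in range(3)]
        track = isl.incidence(segs, gm.markers, 3)
        assert (track.df["fraction"][1:6] == 1.0).all()

    def test_matches_quadratic_oracle(self, rng):
        gm = make_gm(np.zeros((6, 40), dtype=np.int8))
        segs = []
        for i in range(6):
            for _ in range(rng.integers(0, 4)):
                a = int(rng.integers(0, 35))
                b = int(rng.integers(a, 40))
                pos = gm.markers.positions
                segs.append(RohSegment(f"ind{i}", 1, int(pos[a]), int(pos[b]), b - a + 1))
        # individual segments may overlap; merge per individual to honor the invariant
        merged = {}
        for s in segs:
            merged.setdefault(s.individual, []).append(s)
        flat = []
        for ind, ss in merged.items():
            ss.sort(key=lambda s: s.start_bp)
            cur = ss[0]
            for s in ss[1:]:
                if s.start_bp <= cur.end_bp:
                    cur = RohSegment(ind, 1, cur.start_bp, max(cur.end_bp, s.end_bp), 0)
                else:
                    flat.append(cur)
                    cur = s
            flat.append(cur)
        track = isl.incidence(flat, gm.markers, 6)
        expected = oracle_incidence(flat, gm.markers.chroms, gm.markers.positions,
                                    [f"ind{i}" for i in range(6)])
        np.testing.assert_array_equal(track.df["count"].to_numpy(), expected)

    def test_count_conservation(self, rng):
        gm = make_gm(np.zeros((5, 60), dtype=np.int8))
        pos = gm.markers.positions
        segs = [RohSegment(f"ind{i}", 1, int(pos[i * 5]), int(pos[i * 5 + 9]), 10)
                for i in range(5)]
        track = isl.incidence(segs, gm.markers, 5)
        assert track.df["count"].sum() == sum(s.n_snps for s in segs)


class TestConsensus:
    def test_full_share_at_threshold_one(self):
        track, segs, gm = track_from([0, 0, 3, 3, 3, 0], n_indiv=3)
        regions = isl.consensus_roh(track, 1.0)
        assert len(regions) == 1
        pos = gm.markers.positions
        assert (regions[0].start_bp, regions[0].end_bp) == (pos[2], pos[4])
        assert regions[0].n_snps == 3

    def test_threshold_above_max_empty(self):
        track, _, _ = track_from([0, 1, 1, 0], n_indiv=4)
        assert isl.consensus_roh(track, 0.5) == []

    def test_lower_threshold_covers_higher(self):
        track, _, _ = track_from([0, 1, 2, 3, 2, 1, 0, 3, 3, 0], n_indiv=4)
        def cover(regions):
            out = set()
            for r in regions:
                out |= set(range(r.start_bp, r.end_bp + 1))
            return out
        low = cover(isl.consensus_roh(track, 0.25))
        high = cover(isl.consensus_roh(track, 0.75))
        assert high <= low

    def test_invalid_threshold(self):
        track, _, _ = track_from([1], n_indiv=1)
        with pytest.raises(ValueError):
            isl.consensus_roh(track, 0.0)


class TestPercentileIslands:
    def test_uniform_incidence_no_islands(self):
        track, _, _ = track_from([2] * 50, n_indiv=4)
        with pytest.warns(UserWarning, match="constant"):
            assert isl.percentile_islands(track, 99.0) == []

    def test_single_spike_recovered(self):
        counts = [1] * 200 + [5] * 3 + [1] * 200
        track, _, gm = track_from(counts, n_indiv=6)
        regions = isl.percentile_islands(track, 99.0)
        pos = gm.markers.positions
        assert [(r.start_bp, r.end_bp, r.n_snps) for r in regions] == [(pos[200], pos[202], 3)]

    def test_matches_sortbased_oracle_on_two_tier_track(self, rng):
        counts = list(rng.integers(0, 4, 300)) + list(rng.integers(4, 8, 3))
        rng.shuffle(counts)
        track, _, _ = track_from(counts, n_indiv=8)
        cut = np.percentile(np.array(counts), 99)
        expected_snps = {i for i, c in enumerate(counts) if c > cut}
        got = set()
        pos = track.df["pos_bp"].to_numpy()
        for r in isl.percentile_islands(track, 99.0):
            a = np.searchsorted(pos, r.start_bp)
            b = np.searchsorted(pos, r.end_bp)
            got |= set(range(a, b + 1))
        assert got == expected_snps

    def test_bridge_merging(self):
        counts = [0] * 400 + [9, 9, 0, 9, 9] + [0] * 400
        track, _, _ = track_from(counts, n_indiv=10)
        assert len(isl.percentile_islands(track, 99.0, max_bridge=0)) == 2
        assert len(isl.percentile_islands(track, 99.0, max_bridge=1)) == 1


class TestAnnotate:
    def region(self):
        return isl.IslandRegion(chrom=1, start_bp=1_000_000, end_bp=2_000_000, n_snps=10,
                                kind="percentile_island")

    def test_gff_overlap_counts_each_gene_once(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t900000\t1100000\t.\t+\t.\tID=g1;Name=ALPHA\n"
            "1\tsrc\tgene\t1500000\t1600000\t.\t+\t.\tID=g2;Name=BETA\n"
            "1\tsrc\tgene\t1550000\t1580000\t.\t+\t.\tID=g2b;Name=BETA\n"  # nested, same name
            "1\tsrc\tgene\t1900000\t2500000\t.\t+\t.\tID=g3;Name=GAMMA\n"
            "2\tsrc\tgene\t1000000\t2000000\t.\t+\t.\tID=g4;Name=OTHERCHROM\n"
        )
        out = isl.annotate([self.region()], gff)
        assert out[0].genes == ["ALPHA", "BETA", "GAMMA"]
        assert out[0].n_genes == 3

    def test_bed_annotation(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t999999\t1100000\tALPHA\n1\t5000000\t6000000\tFAR\n")
        out = isl.annotate([self.region()], bed)
        assert out[0].genes == ["ALPHA"]

    def test_empty_annotation_zero_genes(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("")
        out = isl.annotate([self.region()], bed)
        assert out[0].n_genes == 0

    def test_missing_file_leaves_unannotated(self):
        with pytest.warns(UserWarning, match="not found"):
            out = isl.annotate([self.region()], "/nonexistent/genes.gff3")
        assert out[0].genes is None
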