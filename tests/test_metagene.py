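"""Metagene profiling: strand handling, confound filter, ORF density, pooling."""

import numpy as np
import pytest

from pol3prox.annotations import GeneRecord, Genome
from pol3prox.metagene import (
    MetageneError,
    compute_profile,
    filter_flanked_genes,
    heatmap_matrix,
    mean_window_occupancy,
    orf_density,
    pearson_r,
)
from pol3prox.stats import DegenerateTestError

from conftest import constant_track, make_track, random_genes, reflect_gene, reflect_track


def naive_profile(track, genes, flank):
    """Per-gene per-offset double loop over the collapsed channel."""
    rows = []
    for gene in genes:
        length = track.genome.length(gene.chrom)
        anchor = gene.tss
        row = []
        ok = True
        for k in range(-flank, flank + 1):
            pos = anchor + k if gene.strand == "+" else anchor - k
            if pos < 0 or pos >= length:
                ok = False
                break
            p, c = track.collapsed(gene.chrom)
            i = np.searchsorted(p, pos)
            row.append(c[i] if i < p.size and p[i] == pos else 0.0)
        if ok:
            rows.append(row)
    return np.array(rows).mean(axis=0)


class TestComputeProfile:
    def test_constant_field(self, tiny_genome):
        track = constant_track(tiny_genome, 3.0)
        genes = [
            GeneRecord("a", "chrI", 15, 25, "+", "tRNA"),
            GeneRecord("b", "chrII", 20, 30, "-", "tRNA"),
        ]
        profile = compute_profile(track, genes, flank=10)
        np.testing.assert_allclose(profile.values, 3.0)

    def test_two_opposite_strand_genes_hand_computed(self):
        genome = Genome({"chrI": 40})
        counts = {p: (float(p), 0.0) for p in range(40)}  # value == position
        track = make_track(genome, {"chrI": counts})
        plus = GeneRecord("p", "chrI", 10, 20, "+", "tRNA")   # TSS 10
        minus = GeneRecord("m", "chrI", 20, 31, "-", "tRNA")  # TSS 30
        profile = compute_profile(track, [plus, minus], flank=5)
        # offset k reads 10+k on the plus gene and 30-k on the minus gene
        expected = [((10 + k) + (30 - k)) / 2 for k in range(-5, 6)]
        np.testing.assert_allclose(profile.values, expected)

    def test_matches_naive_double_loop(self, small_genome):
        rng = np.random.default_rng(11)
        genes = random_genes(rng, small_genome, 50)
        pos = rng.choice(80_000, 2_000, replace=False)
        track = make_track(
            small_genome,
            {
                "chrI": {int(p): (float(rng.integers(1, 5)), float(rng.integers(0, 3)))
                         for p in pos[:1000]},
                "chrII": {int(p): (float(rng.integers(1, 5)), 0.0) for p in pos[1000:]},
            },
        )
        profile = compute_profile(track, genes, flank=200)
        np.testing.assert_allclose(profile.values, naive_profile(track, genes, 200), atol=1e-9)

    def test_reflection_leaves_profile_identical(self, small_genome):
        rng = np.random.default_rng(12)
        genes = random_genes(rng, small_genome, 30)
        pos = rng.choice(70_000, 500, replace=False)
        track = make_track(
            small_genome, {"chrI": {int(p): (float(rng.integers(1, 6)), 0.0) for p in pos}}
        )
        lengths = small_genome.chrom_lengths
        rgenes = [reflect_gene(g, lengths[g.chrom]) for g in genes]
        a = compute_profile(track, genes, flank=150)
        b = compute_profile(reflect_track(track), rgenes, flank=150)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_out_of_bounds_genes_excluded(self, tiny_genome):
        track = constant_track(tiny_genome, 1.0)
        near_edge = GeneRecord("e", "chrI", 2, 12, "+", "tRNA")
        inner = GeneRecord("i", "chrI", 15, 25, "+", "tRNA")
        profile = compute_profile(track, [near_edge, inner], flank=10)
        assert profile.n_regions == 1
        assert profile.excluded == ["e"]
        with pytest.raises(MetageneError, match="excluded"):
            compute_profile(track, [near_edge], flank=10)

    def test_per_gene_matrix_means(self, tiny_genome):
        track = constant_track(tiny_genome, 2.0)
        genes = [GeneRecord("a", "chrI", 15, 25, "+", "tRNA")]
        profile = compute_profile(track, genes, flank=5, keep_matrix=True)
        np.testing.assert_allclose(profile.per_gene_matrix.mean(axis=0), profile.values,
                                   atol=1e-9)


class TestFilterFlankedGenes:
    def _trna(self, start=1000, end=1080):
        return GeneRecord("t", "chrI", start, end, "+", "tRNA")

    def _orf_with_end_at(self, pos, i=0):
        # boundary coordinate `pos` is this ORF's downstream end
        return GeneRecord(f"o{i}", "chrI", pos - 500, pos, "+", "ORF")

    def test_flanked_both_sides_removed(self):
        trna = self._trna()
        orfs = [self._orf_with_end_at(800, 0), self._orf_with_end_at(1330 + 500, 1)]
        orfs[1] = GeneRecord("o1", "chrI", 1330, 1900, "+", "ORF")  # start 250 bp downstream
        assert filter_flanked_genes([trna], orfs, window=300) == []

    def test_distant_ends_retained(self):
        trna = self._trna()
        orfs = [self._orf_with_end_at(600, 0), GeneRecord("o1", "chrI", 1480, 2000, "+", "ORF")]
        assert filter_flanked_genes([trna], orfs, window=300) == [trna]

    def test_one_sided_modes_differ(self):
        trna = self._trna()
        orfs = [self._orf_with_end_at(900, 0)]  # 100 bp upstream only
        assert filter_flanked_genes([trna], orfs, window=300, mode="both_sides") == [trna]
        assert filter_flanked_genes([trna], orfs, window=300, mode="either_side") == []

    def test_window_zero_retains_unless_touching(self):
        trna = self._trna()
        apart = [self._orf_with_end_at(999, 0)]
        assert filter_flanked_genes([trna], apart, window=0, mode="either_side") == [trna]
        touching = [self._orf_with_end_at(1000, 0)]
        assert filter_flanked_genes([trna], touching, window=0, mode="either_side") == []

    def test_both_sides_superset_of_either_side(self, small_genome):
        rng = np.random.default_rng(13)
        trnas = random_genes(rng, small_genome, 40)
        orfs = random_genes(rng, small_genome, 100, 500, 2000, "ORF", "o")
        both = {g.gene_id for g in filter_flanked_genes(trnas, orfs, 300, "both_sides")}
        either = {g.gene_id for g in filter_flanked_genes(trnas, orfs, 300, "either_side")}
        assert either <= both


class TestOrfDensity:
    def test_no_orfs_all_zero(self):
        trna = GeneRecord("t", "chrI", 1000, 1080, "+", "tRNA")
        dens = orf_density([trna], [])
        assert dens["upstream"].sum() == 0 and dens["downstream"].sum() == 0

    def test_hand_window_assignment(self):
        trna = GeneRecord("t", "chrI", 1000, 1080, "+", "tRNA")
        orf = GeneRecord("o", "chrI", 1230, 1900, "+", "ORF")  # starts 150 bp downstream
        dens = orf_density([trna], [orf], step=100, span=1000)
        assert dens["downstream"].tolist() == [0, 1] + [0] * 8
        assert dens["upstream"].sum() == 0

    def test_minus_strand_orientation(self):
        trna = GeneRecord("t", "chrI", 1000, 1080, "-", "tRNA")
        orf = GeneRecord("o", "chrI", 1230, 1900, "-", "ORF")
        dens = orf_density([trna], [orf], step=100, span=1000)
        # genome-right of a minus-strand gene is its upstream side
        assert dens["upstream"].tolist() == [0, 1] + [0] * 8

    def test_same_strand_filter(self):
        trna = GeneRecord("t", "chrI", 1000, 1080, "+", "tRNA")
        orf = GeneRecord("o", "chrI", 1230, 1900, "-", "ORF")
        assert orf_density([trna], [orf])["downstream"].sum() == 0
        assert orf_density([trna], [orf], same_strand=False)["downstream"].sum() == 1

    def test_totals_match_brute_force(self, small_genome):
        rng = np.random.default_rng(14)
        trnas = random_genes(rng, small_genome, 30)
        orfs = random_genes(rng, small_genome, 100, 500, 2000, "ORF", "o")
        span, step = 1000, 100
        dens = orf_density(trnas, orfs, step=step, span=span, same_strand=True)
        expected = 0
        for t in trnas:
            for o in orfs:
                if o.chrom != t.chrom or o.strand != t.strand:
                    continue
                dists = [
                    (t.start - p) if p < t.start else (p - t.end) if p >= t.end else 0
                    for p in (o.start, o.end)
                ]
                sides = [p < t.start or p >= t.end for p in (o.start, o.end)]
                d = min(dists)
                proximal_outside = sides[int(np.argmin(dists))]
                if proximal_outside and d < span:
                    expected += 1
        assert dens["upstream"].sum() + dens["downstream"].sum() == expected


class TestHeatmapMatrix:
    def test_constant_field(self, small_genome):
        track = constant_track(Genome({"chrI": 5000}), 4.0)
        genes = [GeneRecord("a", "chrI", 2000, 2100, "+", "tRNA")]
        hm = heatmap_matrix(track, genes, flank=100, body_bins=10, bin_size=10)
        np.testing.assert_allclose(hm.values, 4.0)

    def test_hand_pooled_single_gene(self):
        genome = Genome({"chrI": 400})
        track = make_track(genome, {"chrI": {p: (float(p % 7), 0.0) for p in range(400)}})
        gene = GeneRecord("g", "chrI", 150, 250, "+", "tRNA")
        hm = heatmap_matrix(track, [gene], flank=50, body_bins=10, bin_size=10)
        dense = np.array([float(p % 7) for p in range(100, 300)])
        expected = dense.reshape(-1, 10).mean(axis=1)
        np.testing.assert_allclose(hm.values[0], expected, atol=1e-9)

    def test_short_gene_interpolated(self):
        genome = Genome({"chrI": 1000})
        track = constant_track(genome, 1.0)
        gene = GeneRecord("g", "chrI", 500, 505, "+", "tRNA")  # 5 bp body, 10 bins
        hm = heatmap_matrix(track, [gene], flank=50, body_bins=10, bin_size=10)
        np.testing.assert_allclose(hm.values[0], 1.0)

    def test_flank_columns_consistent_with_profile(self, small_genome):
        rng = np.random.default_rng(15)
        genes = random_genes(rng, small_genome, 20, min_len=100, max_len=100)
        pos = rng.choice(70_000, 3_000, replace=False)
        track = make_track(
            small_genome, {"chrI": {int(p): (float(rng.integers(1, 4)), 0.0) for p in pos}}
        )
        bin_size = 10
        hm = heatmap_matrix(track, genes, flank=100, body_bins=10, bin_size=bin_size,
                            sort_rows=False)
        up_cols = hm.column_blocks()[0].mean(axis=0)
        # profile anchored at the TSS covers the same upstream flank positions
        profile = compute_profile(track, genes, flank=100, keep_matrix=True)
        pooled = profile.values[:100].reshape(-1, bin_size).mean(axis=1)
        np.testing.assert_allclose(up_cols, pooled, atol=1e-9)


class TestMeanWindowOccupancy:
    def test_constant_field(self, tiny_genome):
        track = constant_track(tiny_genome, 2.5)
        gene = GeneRecord("g", "chrI", 15, 25, "+", "tRNA")
        assert mean_window_occupancy(track, gene, -5, 5) == pytest.approx(2.5)

    def test_hand_computed(self):
        genome = Genome({"chrI": 10})
        track = make_track(genome, {"chrI": {p: (float(p), 0.0) for p in range(10)}})
        gene = GeneRecord("g", "chrI", 4, 8, "+", "tRNA")  # TSS 4
        assert mean_window_occupancy(track, gene, -2, 2) == pytest.approx(4.0)

    def test_minus_gene_equals_plus_on_mirror_track(self):
        genome = Genome({"chrI": 50})
        rng = np.random.default_rng(16)
        vals = rng.integers(0, 5, 50).astype(float)
        track = make_track(genome, {"chrI": {p: (vals[p], 0.0) for p in range(50)}})
        mirror = make_track(genome, {"chrI": {p: (vals[49 - p], 0.0) for p in range(50)}})
        plus = GeneRecord("p", "chrI", 20, 30, "+", "tRNA")
        minus = reflect_gene(plus, 50)
        assert mean_window_occupancy(track, plus, -5, 8) == pytest.approx(
            mean_window_occupancy(mirror, minus, -5, 8)
        )

    def test_truncated_at_bounds(self, tiny_genome):
        track = constant_track(tiny_genome, 1.0)
        gene = GeneRecord("g", "chrI", 2, 12, "+", "tRNA")
        assert mean_window_occupancy(track, gene, -10, 3) == pytest.approx(1.0)


class TestPearson:
    def test_identity_and_anti_identity(self):
        xs = [1.0, 2.0, 5.0, 9.0]
        assert pearson_r(xs, xs) == pytest.approx(1.0)
        assert pearson_r(xs, [-x for x in xs]) == pytest.approx(-1.0)

    def test_textbook_hand_value(self):
        # frozen from the textbook product-moment formula on (1,2,3,4)/(1,3,2,5)
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 5]) == pytest.approx(
            0.8315218406202999, abs=1e-12
        )

    def test_zero_variance_is_an_error(self):
        with pytest.raises(DegenerateTestError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestOrfDensityOverlapMode:
    def test_long_orf_spans_several_windows(self):
        trna = GeneRecord("t", "chrI", 1000, 1080, "+", "tRNA")
        orf = GeneRecord("o", "chrI", 1230, 1560, "+", "ORF")
        dens = orf_density([trna], [orf], step=100, span=1000, assign="overlap")
        # downstream offsets 150..479 cover windows [100,200) .. [400,500)
        assert dens["downstream"].tolist() == [0, 1, 1, 1, 1] + [0] * 5
        point = orf_density([trna], [orf], step=100, span=1000)
        assert point["downstream"].tolist() == [0, 1] + [0] * 8

    def test_minus_strand_overlap_orientation(self):
        trna = GeneRecord("t", "chrI", 1000, 1080, "-", "tRNA")
        orf = GeneRecord("o", "chrI", 1230, 1330, "-", "ORF")
        dens = orf_density([trna], [orf], step=100, span=1000, assign="overlap")
        assert dens["upstream"].tolist() == [0, 1, 1] + [0] * 7
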