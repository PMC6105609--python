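import numpy as np
import pytest

from sweepenrich import ld_annotation as la
from sweepenrich import synthetic_data as synth
from sweepenrich.io_formats import RegionSet

from conftest import (
    dense_partitioned_ld,
    dense_region_score,
    panel_with_corr,
)

# empirical correlation matrix for the 3-SNP toy: r^2 = .5, .1, .3 off-diagonal
TOY_C = np.array(
    [
        [1.0, np.sqrt(0.5), np.sqrt(0.1)],
        [np.sqrt(0.5), 1.0, np.sqrt(0.3)],
        [np.sqrt(0.1), np.sqrt(0.3), 1.0],
    ]
)


@pytest.fixture
def toy_panel():
    return panel_with_corr(TOY_C, pos=[1000, 2000, 3000], n_samples=12, seed=3)


class TestPairwiseR2:
    def test_self_is_one(self, toy_panel):
        assert la.pairwise_r2(toy_panel, 1)[1] == 1.0

    def test_duplicated_column(self):
        d = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
        panel = la.GenotypePanel(
            dosages=d,
            snp_id=np.array(["a", "b"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([10, 20]),
        )
        assert la.pairwise_r2(panel, 0)[1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_pearson_oracle(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0, 1, 1, 1, 1, 2], dtype=float)
        panel = la.GenotypePanel(
            dosages=np.column_stack([x, y]),
            snp_id=np.array(["a", "b"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([10, 20]),
        )
        expect = np.corrcoef(x, y)[0, 1] ** 2
        assert la.pairwise_r2(panel, 0)[1] == pytest.approx(expect, abs=1e-12)

    def test_window_excludes_distant(self, toy_panel):
        r2 = la.pairwise_r2(toy_panel, 0, window_bp=500)
        assert set(r2) == {0}

    def test_bad_index(self, toy_panel):
        with pytest.raises(IndexError):
            la.pairwise_r2(toy_panel, 99)


class TestLDWeightedRegionScore:
    def test_three_snp_toy(self, toy_panel):
        regions = RegionSet.from_intervals([("1", 999, 1000)], "HD")  # SNP1 only
        scores = la.ld_weighted_region_score(toy_panel, regions)
        np.testing.assert_allclose(scores, [1.0, 0.5, 0.0], atol=1e-10)

    def test_member_with_no_partners_scores_one(self):
        panel = panel_with_corr(np.eye(1) , pos=[100], n_samples=8)
        regions = RegionSet.from_intervals([("1", 0, 200)], "r")
        assert la.ld_weighted_region_score(panel, regions)[0] == 1.0

    def test_subthreshold_partner_scores_zero(self, toy_panel):
        # SNP3's only region partner is SNP1 with r^2 = 0.1 < 0.2
        regions = RegionSet.from_intervals([("1", 999, 1000)], "HD")
        assert la.ld_weighted_region_score(toy_panel, regions)[2] == 0.0

    def test_empty_regions_all_zero(self, toy_panel):
        regions = RegionSet.from_intervals([], "empty")
        assert (la.ld_weighted_region_score(toy_panel, regions) == 0).all()

    def test_whole_genome_identity(self, small_panel):
        """score with regions = whole genome equals 1 + sum of r^2 >= 0.2."""
        sub = small_panel.subset(np.arange(50))
        whole = RegionSet.from_intervals(
            [(c, 0, int(sub.pos[sl.stop - 1]) + 10) for c, sl in sub.chrom_slices()],
            "all",
        )
        scores = la.ld_weighted_region_score(sub, whole)
        expect = dense_region_score(sub, whole)
        np.testing.assert_allclose(scores, expect, atol=1e-10)
        assert (scores >= 1.0).all()

    def test_dense_oracle_equality(self, small_panel, small_tracks):
        sub = small_panel.subset(np.arange(50))
        scores = la.ld_weighted_region_score(sub, small_tracks["HD"])
        expect = dense_region_score(sub, small_tracks["HD"])
        np.testing.assert_allclose(scores, expect, atol=1e-10)

    def test_sample_permutation_invariance(self, small_panel, small_tracks):
        rng = np.random.default_rng(5)
        perm = small_panel.subset(np.arange(small_panel.n_snps))
        perm.dosages = perm.dosages[rng.permutation(perm.n_samples)]
        a = la.ld_weighted_region_score(small_panel, small_tracks["HD"])
        b = la.ld_weighted_region_score(perm, small_tracks["HD"])
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestPartitionedLDScores:
    def test_isolated_snp_large_n(self):
        rng = np.random.default_rng(0)
        panel = la.GenotypePanel(
            dosages=np.clip(rng.normal(1, 0.4, size=(5000, 1)), 0, 2),
            snp_id=np.array(["a"], dtype=object),
            chrom=np.array(["1"], dtype=object),
            pos=np.array([100]),
        )
        ann = la.AnnotationSet(["base"], np.ones((1, 1), dtype=np.int8),
                               np.ones((1, 1)))
        ld = la.partitioned_ld_scores(panel, ann)
        assert ld.ell[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_two_perfectly_correlated(self):
        x = np.array([0, 0, 1, 1, 2, 2, 0, 2], dtype=float)
        panel = la.GenotypePanel(
            dosages=np.column_stack([x, x]),
            snp_id=np.array(["a", "b"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([10, 20]),
        )
        ann = la.AnnotationSet(["c"], np.ones((2, 1), dtype=np.int8), np.ones((2, 1)))
        ld = la.partitioned_ld_scores(panel, ann)
        np.testing.assert_allclose(ld.ell[:, 0], [2.0, 2.0], atol=1e-10)

    def test_dense_oracle_five_snp_block(self):
        rng = np.random.default_rng(8)
        C = np.eye(5) * 0.4 + 0.6
        panel = panel_with_corr(C, pos=[100, 200, 300, 400, 500], n_samples=16)
        binary = rng.integers(0, 2, size=(5, 2)).astype(np.int8)
        binary[:, 0] = 1
        ann = la.AnnotationSet(["base", "c"], binary, binary.astype(float))
        ld = la.partitioned_ld_scores(panel, ann)
        ell, total = dense_partitioned_ld(panel, binary)
        np.testing.assert_allclose(ld.ell, ell, atol=1e-12)
        np.testing.assert_allclose(ld.ell_total, total, atol=1e-12)

    def test_dense_oracle_synthetic_panel(self, small_panel, small_tracks):
        idx = np.arange(50)  # M <= 50 sub-panel
        sub = small_panel.subset(idx)
        ann = la.binary_annotations(sub, {"HD": small_tracks["HD"]})
        ld = la.partitioned_ld_scores(sub, ann)
        ell, total = dense_partitioned_ld(sub, ann.binary)
        np.testing.assert_allclose(ld.ell, ell, atol=1e-10)
        np.testing.assert_allclose(ld.ell_total, total, atol=1e-10)

    def test_base_column_equals_ell_total(self, small_panel, small_tracks):
        ann = la.binary_annotations(sub := small_panel.subset(np.arange(60)),
                                    {"HD": small_tracks["HD"]})
        ld = la.partitioned_ld_scores(sub, ann)
        np.testing.assert_allclose(ld.column("base"), ld.ell_total, atol=1e-10)

    def test_additivity_over_disjoint_partition(self, small_panel):
        """ell summed over a disjoint partition equals ell for the union."""
        M = small_panel.n_snps
        half = RegionSet.from_intervals(
            [(c, 0, int(np.median(small_panel.pos[sl])))
             for c, sl in small_panel.chrom_slices()],
            "left",
        )
        left = half.contains(small_panel.chrom, small_panel.pos)
        binary = np.column_stack([left, ~left, np.ones(M, bool)]).astype(np.int8)
        ann = la.AnnotationSet(
            ["left", "right", "all"], binary, binary.astype(float)
        )
        ld = la.partitioned_ld_scores(small_panel, ann)
        np.testing.assert_allclose(
            ld.column("left") + ld.column("right"), ld.column("all"), atol=1e-10
        )

    def test_unknown_regression_snp_dropped(self, small_panel, small_tracks):
        ann = la.binary_annotations(small_panel, {"HD": small_tracks["HD"]})
        with pytest.warns(UserWarning, match="not found"):
            ld = la.partitioned_ld_scores(
                small_panel, ann,
                regression_snps=[small_panel.snp_id[0], "nonexistent"],
            )
        assert len(ld) == 1

    def test_too_few_samples(self, toy_panel):
        tiny = la.GenotypePanel(
            dosages=toy_panel.dosages[:2],
            snp_id=toy_panel.snp_id,
            chrom=toy_panel.chrom,
            pos=toy_panel.pos,
        )
        ann = la.AnnotationSet(["c"], np.ones((3, 1), dtype=np.int8), np.ones((3, 1)))
        with pytest.raises(ValueError, match="samples"):
            la.partitioned_ld_scores(tiny, ann)


class TestAnnotationSet:
    def test_weighted_geq_binary(self, small_panel, small_tracks):
        ann = la.build_annotations(
            small_panel,
            {k: v for k, v in small_tracks.items() if k != "genes"},
            intersections={"HDBrain": ("HD", "brain")},
        )
        assert (ann.weighted >= ann.binary - 1e-12).all()
        assert "HDBrain" in ann
        np.testing.assert_array_equal(
            ann.column("HDBrain"), ann.column("HD") * ann.column("brain")
        )

    def test_invalid_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            la.AnnotationSet(["a"], np.array([[2]]), np.array([[2.0]]))


class TestClassifyIntergenic:
    def _setup(self):
        # 4 SNPs: s0 in exon; s1 isolated far from everything; s2 not genic
        # but correlated with s3 which sits within 100kb of a gene.
        C = np.eye(4)
        C[2, 3] = C[3, 2] = np.sqrt(0.3)
        panel = panel_with_corr(
            C, pos=[100_000, 3_000_000, 5_000_000, 5_050_000], n_samples=12, seed=1
        )
        exon = RegionSet.from_intervals([("1", 99_000, 101_000)], "exon")
        empty = RegionSet.from_intervals([], "x")
        genes = RegionSet.from_intervals(
            [("1", 99_000, 101_000), ("1", 5_100_000, 5_200_000)], "genes"
        )
        tracks = {"exon": exon, "intron": empty, "utr3": empty, "utr5": empty}
        ann = la.build_annotations(panel, tracks, include_base=False)
        return panel, ann, {"genes": genes}

    def test_rules(self):
        panel, ann, context = self._setup()
        mask = la.classify_intergenic(ann, panel, context)
        assert not mask[0]  # in exon
        assert mask[1]  # isolated, no context overlap
        assert not mask[3]  # itself within gene+-100kb
        assert not mask[2]  # r^2 = 0.3 with s3, which tags the gene region
    def test_missing_genic_columns_error(self):
        panel, _, context = self._setup()
        ann = la.binary_annotations(panel, {})
        with pytest.raises(ValueError, match="genic"):
            la.classify_intergenic(ann, panel, context)


class TestMHCExclusion:
    def _panel(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = np.sqrt(0.15)
        return panel_with_corr(
            C, pos=[24_500_000, 25_200_000, 33_854_733], chrom="6",
            n_samples=12, seed=2,
        )

    def test_inside_interval_excluded(self):
        keep = la.mhc_exclusion_mask(self._panel())
        assert not keep[1] and not keep[2]

    def test_ld_partner_excluded(self):
        # 24.5 Mb SNP has r^2 = 0.15 > 0.1 with the 25.2 Mb excluded SNP
        keep = la.mhc_exclusion_mask(self._panel())
        assert not keep[0]

    def test_other_chromosome_kept(self):
        panel = panel_with_corr(
            np.eye(2), pos=[25_200_000, 30_000_000], chrom="1", n_samples=10
        )
        assert la.mhc_exclusion_mask(panel).all()

    def test_chr_prefix_recognized(self):
        panel = panel_with_corr(
            np.eye(1), pos=[30_000_000], chrom="chr6", n_samples=10
        )
        assert not la.mhc_exclusion_mask(panel)[0]


class TestLDPrune:
    def test_high_ld_pair_keeps_one(self):
        C = np.array([[1.0, np.sqrt(0.9)], [np.sqrt(0.9), 1.0]])
        panel = panel_with_corr(C, pos=[100, 200], n_samples=10)
        kept = la.ld_prune(panel, list(panel.snp_id), rng_seed=0)
        assert len(kept) == 1

    def test_independent_all_survive(self):
        panel = panel_with_corr(np.eye(4), pos=[100, 200, 300, 400], n_samples=12)
        kept = la.ld_prune(panel, list(panel.snp_id), rng_seed=0)
        assert sorted(kept) == sorted(panel.snp_id)

    def test_deterministic_given_seed(self, small_panel):
        ids = list(small_panel.snp_id[:10 * 4:4])
        a = la.ld_prune(small_panel, ids, rng_seed=11)
        b = la.ld_prune(small_panel, ids, rng_seed=11)
        assert a == b

    def test_result_has_no_pair_above_threshold(self, small_panel):
        ids = list(small_panel.snp_id[:80])
        kept = la.ld_prune(small_panel, ids, rng_seed=3)
        idx = small_panel.index_of(kept)
        sub = small_panel.subset(np.sort(idx))
        Xs = sub.standardized()
        r2 = (Xs.T @ Xs / sub.n_samples) ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() < la.LD_R2_FLOOR

    def test_empty_candidates(self, small_panel):
        assert la.ld_prune(small_panel, [], rng_seed=0) == []
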