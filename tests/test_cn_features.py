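import numpy as np
import pytest

import ecsubtypes as ec
from ecsubtypes.cn_features import (
    altered_length_per_mb,
    call_gain_loss,
    chromosome_counts,
    gene_counts,
    sample_counts,
)


def seg(chrom, start, end, cn):
    return ec.CNSegment(chrom, start, end, cn)


def profile(sid, segments, ploidy=2.0):
    return ec.CNProfile(sid, tuple(segments), ploidy)


@pytest.fixture
def spec():
    return ec.CNFeatureSpec()


@pytest.fixture
def genes():
    return ec.GeneModel(
        (
            ec.Gene("GA", "1", 1000, 2000),
            ec.Gene("GB", "1", 5000, 6000),
            ec.Gene("GC", "2", 1000, 2000),
        )
    )


class TestGainLossCalls:
    @pytest.mark.parametrize(
        "cn,ploidy,expected",
        [(4.0, 2.0, "gain"), (2.0, 2.0, "neutral"), (1.0, 2.0, "loss"),
         (2.5, 2.0, "gain"), (1.5, 2.0, "loss"), (2.4, 2.0, "neutral")],
    )
    def test_ploidy_relative_margins(self, cn, ploidy, expected, spec):
        assert call_gain_loss(seg("1", 1, 100, cn), ploidy, spec) == expected

    def test_scale_invariance_with_scaled_margins(self):
        """Doubling copy numbers, ploidy and margins leaves calls unchanged."""
        rng = np.random.default_rng(2)
        base_spec = ec.CNFeatureSpec()
        scaled_spec = ec.CNFeatureSpec(gain_margin=1.0, loss_margin=1.0)
        for _ in range(50):
            cn = float(rng.uniform(0, 5))
            s1 = seg("1", 1, 100, cn)
            s2 = seg("1", 1, 100, 2 * cn)
            assert call_gain_loss(s1, 2.0, base_spec) == call_gain_loss(s2, 4.0, scaled_spec)


class TestSampleAndChromosomeCounts:
    def test_sample_counts(self, spec):
        p = profile("s", [seg("1", 1, 100, 4), seg("1", 200, 300, 2), seg("1", 400, 500, 1)])
        assert sample_counts(p, spec) == (1, 1)

    def test_all_neutral(self, spec):
        p = profile("s", [seg("1", 1, 100, 2.0), seg("2", 1, 100, 2.2)])
        assert sample_counts(p, spec) == (0, 0)

    def test_absent_chromosomes_report_zero(self, spec):
        p = profile("s", [seg("1", 1, 100, 4)])
        cc = chromosome_counts(p, spec)
        assert cc["1"] == (1, 0)
        assert cc["2"] == (0, 0)
        assert set(cc) == set(ec.CHROMOSOMES)

    def test_unknown_chromosome_rejected(self, spec):
        p = profile("s", [seg("Y", 1, 100, 4)])
        with pytest.raises(ValueError, match="universe"):
            chromosome_counts(p, spec)

    def test_partition_identity_on_simulated_profiles(self, small_cohort, spec):
        """Per-chromosome counts sum to the per-sample counts."""
        for prof in list(small_cohort.profiles.values())[:20]:
            cc = chromosome_counts(prof, spec)
            total = tuple(np.sum(list(cc.values()), axis=0))
            assert total == sample_counts(prof, spec)


class TestGeneSelection:
    def test_frequency_ordering(self, genes, spec):
        # GA altered in both samples, GB in one, GC never
        p1 = profile("s1", [seg("1", 900, 2100, 4)])
        p2 = profile("s2", [seg("1", 900, 5500, 4)])
        selected = ec.select_top_genes([p1, p2], genes, spec)
        assert selected[0] == "GA"
        assert "GC" not in selected

    def test_tie_break_is_genomic_order(self, spec):
        gm = ec.GeneModel((ec.Gene("ZZ", "1", 100, 200), ec.Gene("AA", "2", 100, 200)))
        p = profile("s1", [seg("1", 50, 250, 4), seg("2", 50, 250, 4)])
        assert ec.select_top_genes([p], gm, spec) == ("ZZ", "AA")

    def test_truncation_to_altered_genes(self, genes):
        spec = ec.CNFeatureSpec(top_k_genes=25)
        p = profile("s1", [seg("1", 900, 2100, 4)])  # only GA altered
        assert ec.select_top_genes([p], genes, spec) == ("GA",)

    def test_empty_gene_model_rejected(self, spec):
        with pytest.raises(ValueError, match="empty gene model"):
            ec.select_top_genes([], ec.GeneModel(()), spec)


class TestGeneCounts:
    def test_spanning_gain(self, genes, spec):
        p = profile("s", [seg("1", 500, 3000, 4)])
        assert gene_counts(p, ("GA",), genes, spec)["GA"] == (1, 0)

    def test_abutting_segment_does_not_overlap(self, genes, spec):
        p = profile("s", [seg("1", 1, 999, 4)])  # ends at gene start - 1
        assert gene_counts(p, ("GA",), genes, spec)["GA"] == (0, 0)
        p = profile("s", [seg("1", 1, 1000, 4)])  # 1-base overlap counts
        assert gene_counts(p, ("GA",), genes, spec)["GA"] == (1, 0)

    def test_two_disjoint_segments_count_twice(self, genes, spec):
        p = profile("s", [seg("1", 900, 1200, 4), seg("1", 1500, 2100, 5)])
        assert gene_counts(p, ("GA",), genes, spec)["GA"] == (2, 0)


class TestAlteredLength:
    def test_density_arithmetic(self):
        spec = ec.CNFeatureSpec(genome_length_mb=3100)
        p = profile("s", [seg("1", 1, 31_000_000, 4)])
        assert altered_length_per_mb(p, spec) == pytest.approx(0.01)

    def test_all_neutral_zero(self, spec):
        p = profile("s", [seg("1", 1, 1000, 2.0)])
        assert altered_length_per_mb(p, spec) == 0.0

    def test_splitting_segment_invariant(self, spec):
        whole = profile("s", [seg("1", 1, 1000, 4)])
        halves = profile("s", [seg("1", 1, 500, 4), seg("1", 501, 1000, 4)])
        assert altered_length_per_mb(whole, spec) == pytest.approx(
            altered_length_per_mb(halves, spec)
        )


class TestFeatureMatrix:
    def test_feature_count_with_full_gene_list(self, small_cohort):
        """2 sample counts + 46 chromosome counts + 2k gene counts + ploidy
        + altered density."""
        spec = ec.CNFeatureSpec(top_k_genes=25)
        profiles = list(small_cohort.profiles.values())
        fm = ec.build_feature_matrix(profiles, small_cohort.gene_model, spec)
        assert len(fm.selected_genes) == 25
        assert fm.values.shape == (len(profiles), 2 + 46 + 50 + 2)
        assert len(fm.feature_names) == 100

    def test_row_permutation_only_permutes_rows(self, small_cohort):
        spec = ec.CNFeatureSpec()
        profiles = list(small_cohort.profiles.values())[:10]
        fm = ec.build_feature_matrix(profiles, small_cohort.gene_model, spec)
        fm_rev = ec.build_feature_matrix(
            profiles[::-1], small_cohort.gene_model, spec, fm.selected_genes
        )
        np.testing.assert_allclose(fm.values, fm_rev.values[::-1])

    def test_zero_segment_sample_is_all_zero_counts(self, small_cohort):
        spec = ec.CNFeatureSpec()
        empty = ec.CNProfile("empty", (), 2.5)
        fm = ec.build_feature_matrix(
            [empty], small_cohort.gene_model, spec, selected_genes=("G0001",)
        )
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["ploidy"] == 2.5
        assert row["sample_gains"] == 0 and row["altered_length_per_mb"] == 0

    def test_supplied_gene_list_never_reselected(self, small_cohort):
        spec = ec.CNFeatureSpec()
        profiles = list(small_cohort.profiles.values())[:10]
        fm = ec.build_feature_matrix(
            profiles, small_cohort.gene_model, spec, selected_genes=("G0007",)
        )
        assert fm.selected_genes == ("G0007",)

    def test_leakage_guard(self, small_cohort):
        """Held-out feature rows depend only on the training-fold gene list:
        altering a held-out profile outside the selected genes leaves its
        per-gene features unchanged."""
        spec = ec.CNFeatureSpec(top_k_genes=5)
        profiles = list(small_cohort.profiles.values())
        train, test = profiles[:40], profiles[40]
        extractor = ec.CNFeatureExtractor(gene_model=small_cohort.gene_model, top_k_genes=5)
        extractor.fit(train)
        selected = set(extractor.selected_genes_)
        by_id = {g.gene_id: g for g in small_cohort.gene_model}
        # a gene not selected and not overlapping any selected gene
        gsel = [by_id[g] for g in selected]
        unselected = next(
            g
            for g in small_cohort.gene_model
            if g.gene_id not in selected
            and not any(
                g.chromosome == s.chromosome and g.start <= s.end and s.start <= g.end
                for s in gsel
            )
        )
        base = ec.CNProfile("t", (), test.ploidy)
        extra = ec.CNProfile(
            "t",
            (ec.CNSegment(unselected.chromosome, unselected.start, unselected.end,
                          test.ploidy + 2.0),),
            test.ploidy,
        )
        row_base = extractor.transform([base])[0]
        row_extra = extractor.transform([extra])[0]
        gene_cols = [
            i for i, n in enumerate(extractor.feature_names_)
            if any(n.startswith(f"{g}_") for g in selected)
        ]
        np.testing.assert_allclose(row_base[gene_cols], row_extra[gene_cols])
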