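"""Variant-to-gene linking, gene feature fills and gene ranking."""

import numpy as np
import pandas as pd
import pytest

from mindrank.gene_prioritization import (
    CNV_ABSENT_FILL,
    GENE_FEATURES,
    MAX_LINK_DISTANCE,
    RVIS_ABSENT_FILL,
    GeneScoreSources,
    aggregate_variant_scores,
    assemble_gene_features,
    cnv_feature,
    dnm_feature,
    fit_emr,
    gtex_feature,
    haploinsufficiency_feature,
    link_variants_to_genes,
    load_gtex_table,
    phenolyzer_feature,
    rank_genes,
    rvis_feature,
    variant_gene_distance,
)
from mindrank.genomic_io import GeneAnnotation, GenomicVariant
from mindrank.missing_data import EmrConfig
from mindrank.scorer import init_model
from mindrank.variant_features import FeatureMatrix


class TestLinking:
    def test_boundary_inclusive_at_100kb(self):
        gene = GeneAnnotation("G1", "1", 200_000, 220_000)
        at_limit = GenomicVariant("1", 100_000, "A", "G")    # exactly 100 kb upstream
        links = link_variants_to_genes([at_limit], [gene])
        assert len(links) == 1 and links[0].distance == MAX_LINK_DISTANCE

    def test_one_bp_past_limit_not_linked(self):
        gene = GeneAnnotation("G1", "1", 200_000, 220_000)
        past = GenomicVariant("1", 99_999, "A", "G")  # 100,001 bp away
        assert link_variants_to_genes([past], [gene]) == []

    def test_inside_gene_body_distance_zero(self):
        gene = GeneAnnotation("G1", "1", 100, 200)
        v = GenomicVariant("1", 150, "A", "G")
        assert link_variants_to_genes([v], [gene])[0].distance == 0

    def test_variant_may_link_to_multiple_genes(self):
        genes = [GeneAnnotation("A", "1", 1000, 2000), GeneAnnotation("B", "1", 3000, 4000)]
        v = GenomicVariant("1", 2500, "A", "G")
        assert {l.gene_id for l in link_variants_to_genes([v], genes)} == {"A", "B"}

    def test_matches_brute_force_all_pairs_scan(self, rng):
        genes = [
            GeneAnnotation(f"G{i}", str(rng.integers(1, 3)), int(s), int(s) + 20_000)
            for i, s in enumerate(rng.integers(1, 2_000_000, size=50))
        ]
        variants = [
            GenomicVariant(str(rng.integers(1, 3)), int(p), "A", "G")
            for p in rng.integers(1, 2_100_000, size=2000)
        ]
        got = {(l.variant_key, l.gene_id) for l in link_variants_to_genes(variants, genes)}
        brute = {
            (v.key, g.gene_id)
            for v in variants
            for g in genes
            if (d := variant_gene_distance(v, g)) is not None and d <= MAX_LINK_DISTANCE
        }
        assert got == brute


class TestAggregation:
    def _setup(self):
        # G2 sits on another chromosome, so it can never be linked
        genes = [GeneAnnotation("G1", "1", 100, 200), GeneAnnotation("G2", "2", 5000, 6000)]
        v1, v2 = GenomicVariant("1", 150, "A", "G"), GenomicVariant("1", 160, "C", "T")
        links = link_variants_to_genes([v1, v2], genes)
        scores = {v1.key: 0.9, v2.key: 0.2}
        return genes, links, scores

    def test_max_and_mean_modes(self):
        genes, links, scores = self._setup()
        assert aggregate_variant_scores(links, scores, genes, "max")["G1"] == pytest.approx(0.9)
        assert aggregate_variant_scores(links, scores, genes, "mean")["G1"] == pytest.approx(0.55)

    def test_gene_without_linked_variant_scores_zero(self):
        genes, links, scores = self._setup()
        assert aggregate_variant_scores(links, scores, genes, "max")["G2"] == 0.0

    def test_invariant_under_link_shuffle(self, rng):
        genes, links, scores = self._setup()
        shuffled = [links[i] for i in rng.permutation(len(links))]
        for mode in ("max", "mean", "count-weighted"):
            assert aggregate_variant_scores(links, scores, genes, mode) == \
                aggregate_variant_scores(shuffled, scores, genes, mode)

    def test_unknown_mode_rejected(self):
        genes, links, scores = self._setup()
        with pytest.raises(ValueError, match="unknown aggregation"):
            aggregate_variant_scores(links, scores, genes, "median")


class TestFeatureFills:
    def test_gtex_transform_and_emr_fill(self):
        table = load_gtex_table(pd.DataFrame({"gene": ["A", "A", "B"], "q": [0.01, 0.04, 0.2]}))
        assert "B" not in table                      # q >= 0.05 rejected at load
        assert gtex_feature(table, "A", emr=0.4) == pytest.approx(0.99)
        assert gtex_feature(table, "Z", emr=0.4) == 0.4

    def test_rvis_absent_fill_is_zero(self):
        assert rvis_feature({}, "G") == RVIS_ABSENT_FILL == 0.0
        assert rvis_feature({"G": -1.2}, "G") == -1.2

    def test_phenolyzer_and_haplo_use_emr(self):
        assert phenolyzer_feature({"G": 0.77}, "G", emr=0.3) == 0.77
        assert phenolyzer_feature({}, "G", emr=0.3) == 0.3
        assert haploinsufficiency_feature({}, "G", emr=0.25) == 0.25

    def test_cnv_inverted_q_and_absent_half(self):
        assert cnv_feature({}, "G") == CNV_ABSENT_FILL == 0.5
        assert cnv_feature({"G": 0.02}, "G") == pytest.approx(0.98)
        # transform monotone decreasing in q
        assert cnv_feature({"G": 0.01}, "G") > cnv_feature({"G": 0.04}, "G")

    def test_dnm_minmax_normalization(self):
        counts = {"A": 0, "B": 3, "C": 6}
        norm = dnm_feature(counts, ["A", "B", "C", "D"])
        assert norm["A"] == 0.0 and norm["D"] == 0.0
        assert norm["C"] == 1.0
        assert norm["B"] == pytest.approx(0.5)
        # ordering preserved
        order = sorted(counts, key=counts.get)
        assert sorted(counts, key=lambda g: norm[g]) == order

    def test_negative_dnm_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            dnm_feature({"A": -1}, ["A"])


class TestAssemblyAndRanking:
    def _bundle(self):
        genes = [GeneAnnotation(f"G{i}", "1", 1000 * i + 1, 1000 * i + 500) for i in range(1, 6)]
        sources = GeneScoreSources(
            rvis={"G1": 0.8}, gtex={"G2": 0.99}, haploinsufficiency={"G3": 0.6},
            phenolyzer={"G4": 0.7}, cnv={"G5": 0.03}, dnm_counts={"G1": 2},
        )
        emr = fit_emr(sources, [g.gene_id for g in genes])
        feats = assemble_gene_features(genes, {"G1": 0.9}, sources, emr)
        return genes, feats, emr

    def test_every_feature_total_and_order_fixed(self):
        _, feats, emr = self._bundle()
        assert list(feats.columns) == list(GENE_FEATURES)
        assert not feats.mask.any()
        assert np.isfinite(feats.values).all()
        assert emr.emr["GTEx"] == pytest.approx(0.8)  # 4 of 5 genes absent

    def test_identical_features_identical_scores(self):
        _, feats, _ = self._bundle()
        model = init_model(7, (8,), dropout=0.0, seed=0)
        dup = FeatureMatrix(
            ["X", "Y"], list(GENE_FEATURES), np.vstack([feats.values[0], feats.values[0]])
        )
        ranked = rank_genes(dup, model)
        assert ranked["score"][0] == ranked["score"][1]
        assert list(ranked["gene"]) == ["X", "Y"]  # lexicographic tie-break

    def test_column_mismatch_is_loud_error(self):
        _, feats, _ = self._bundle()
        model = init_model(6, (8,), seed=0)
        dropped = FeatureMatrix(feats.keys, feats.columns[:-1], feats.values[:, :-1])
        with pytest.raises(ValueError, match="do not match"):
            rank_genes(dropped, model)

    def test_planted_disease_genes_ranked_above_chance(self, small_stage2, small_dataset):
        from mindrank.evaluation import PipelineSpec, auc, cross_validate
        from mindrank.rebalance import LabeledDataset
        from mindrank.scorer import TrainConfig

        s2 = small_stage2
        aug = s2.stage1_augmented
        from mindrank.variant_features import assemble_variant_features

        feats = assemble_variant_features(
            aug.variants, aug.score_tables, aug.eqtl_table, aug.mark_tracks
        )
        spec = PipelineSpec(train_config=TrainConfig(epochs=40), hidden_sizes=(16, 8))
        model, imp = spec.fit(LabeledDataset(feats, aug.labels), seed=0)
        vscores = dict(zip(feats.keys, spec.score(model, imp, feats)))
        links = link_variants_to_genes(list(aug.variants), s2.genes)
        per_gene = aggregate_variant_scores(links, vscores, s2.genes)
        emr = fit_emr(s2.sources, [g.gene_id for g in s2.genes])
        gf = assemble_gene_features(s2.genes, per_gene, s2.sources, emr)
        y = np.array([s2.gene_labels[g.gene_id] for g in s2.genes])
        gene_model = init_model(7, (), dropout=0.0, seed=0)
        # even before training, the planted construction must make disease
        # genes separable: check the aggregated variant-score feature alone
        assert auc(gf.column("variant_score"), y) > 0.5

    def test_every_disease_gene_has_nearby_variant_by_construction(self, small_stage2):
        s2 = small_stage2
        links = link_variants_to_genes(list(s2.stage1_augmented.variants), s2.genes)
        linked_genes = {l.gene_id for l in links}
        for gid, label in s2.gene_labels.items():
            if label == 1:
                assert gid in linked_genes
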