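"""Gene segmentation/aggregation, genome scanning, SNP enrichment and
feature-class assignment."""

import numpy as np
import pytest
from scipy import stats

from hmcnet.downstream import (
    DhmrCall,
    EnrichmentTable,
    GeneRecord,
    predict_gene_expression,
    scan_genome_dhmr,
    segment_gene_body,
    snp_enrichment,
    summarize_feature_distribution,
)
from hmcnet.intervals import GenomicInterval
from hmcnet.labeling import make_continuous_targets
from hmcnet.model import HmcModel
from hmcnet.pipeline import featurize


class TestSegmentGeneBody:
    def test_padding_partial_window(self):
        g = GeneRecord("g", GenomicInterval("chr1", 10_000, 12_500))
        ws = segment_gene_body(g)
        assert [(w.start, w.end) for w in ws] == [
            (10_000, 11_000), (11_000, 12_000), (12_000, 13_000)]

    def test_short_gene_padded_to_one_window(self):
        g = GeneRecord("g", GenomicInterval("chr1", 10_000, 10_800))
        ws = segment_gene_body(g)
        assert len(ws) == 1 and ws[0].length == 1000

    def test_exact_multiple_unpadded(self):
        g = GeneRecord("g", GenomicInterval("chr1", 10_000, 12_000))
        ws = segment_gene_body(g)
        assert len(ws) == 2 and ws[-1].end == 12_000

    @pytest.mark.parametrize("length", [1, 999, 1000, 1001, 5500, 10_000])
    def test_window_properties(self, length):
        g = GeneRecord("g", GenomicInterval("chr1", 50_000, 50_000 + length))
        ws = segment_gene_body(g)
        assert len(ws) == -(-length // 1000)
        assert all(w.length == 1000 for w in ws)
        for a, b in zip(ws, ws[1:]):
            assert a.end == b.start  # disjoint and consecutive
        assert ws[0].start == 50_000
        assert ws[-1].end >= 50_000 + length


@pytest.fixture(scope="module")
def cont_results(micro):
    """A quickly fitted continuous model on the micro dataset."""
    regions = micro.peaks
    examples = make_continuous_targets(regions, micro.hmc_reads)
    feats = featurize(micro, examples)
    seq, epi, y, chroms = feats
    model = HmcModel(None, epi, y, chroms=chroms, task="continuous",
                     modality="epi_only")
    return model.fit(max_epochs=2, patience=5, batch_size=8, seed=0)


class TestGeneAggregation:
    def test_equals_sum_of_window_predictions(self, micro, cont_results):
        genes = [GeneRecord(r.gene_id, GenomicInterval(r.chrom, r.start, r.end))
                 for r in micro.genes.itertuples(index=False)][:4]
        pred = predict_gene_expression(genes, cont_results, micro.genome,
                                       micro.mark_reads)
        from hmcnet.features import build_feature_pair
        for g in genes:
            total = 0.0
            for w in segment_gene_body(g):
                fp = build_feature_pair(w, micro.genome, micro.mark_reads)
                total += float(np.expm1(cont_results.predict_pairs([fp])[0]))
            assert pred[g.gene_id] == pytest.approx(total, rel=1e-6)

    def test_missing_chrom_skipped_with_warning(self, micro, cont_results):
        genes = [GeneRecord("lost", GenomicInterval("chrZ", 0, 2000))]
        with pytest.warns(UserWarning, match="missing chromosome"):
            pred = predict_gene_expression(genes, cont_results, micro.genome,
                                           micro.mark_reads)
        assert "lost" not in pred

    def test_requires_continuous_model(self, micro):
        examples = make_continuous_targets(micro.peaks, micro.hmc_reads)
        feats = featurize(micro, examples)
        model = HmcModel(None, feats[1], (feats[2] > feats[2].mean()).astype(float),
                         chroms=feats[3], task="binary", modality="epi_only")
        res = model.fit(max_epochs=1, patience=5, batch_size=8, seed=0)
        with pytest.raises(ValueError):
            predict_gene_expression([], res, micro.genome, micro.mark_reads)


@pytest.fixture(scope="module")
def diff_results(micro):
    from hmcnet.labeling import label_dhmrs
    examples = label_dhmrs(micro.diff_table)
    signals = {"case:m": micro.case_marks["acetyl_mark"],
               "control:m": micro.control_marks["acetyl_mark"]}
    order = ["case:m", "control:m"]
    feats = featurize(micro, examples, mark_signals=signals, mark_order=order)
    model = HmcModel(None, feats[1], feats[2], chroms=feats[3],
                     task="binary", modality="epi_only")
    return model.fit(max_epochs=1, patience=5, batch_size=8, seed=0)


class TestGenomeScan:
    def test_window_count_is_floor(self, micro, diff_results):
        genome = {"chr1": micro.genome["chr1"][:10_500]}
        calls = scan_genome_dhmr(diff_results, genome,
                                 {"m": micro.case_marks["acetyl_mark"]},
                                 {"m": micro.control_marks["acetyl_mark"]})
        assert len(calls) == 10
        assert calls[0].window.start == 0
        assert calls[-1].window.end == 10_000

    def test_probabilities_and_calls(self, micro, diff_results):
        genome = {"chr1": micro.genome["chr1"][:20_000]}
        calls = scan_genome_dhmr(diff_results, genome,
                                 {"m": micro.case_marks["acetyl_mark"]},
                                 {"m": micro.control_marks["acetyl_mark"]})
        for c in calls:
            assert 0.0 <= c.probability <= 1.0
            assert c.call == ("DhMR" if c.probability > 0.5 else "non-DhMR")

    def test_rejects_model_with_sequence_modality(self):
        from hmcnet.model import ModelSpec
        rng = np.random.default_rng(0)
        n = 40
        spec = ModelSpec(task="binary", modality="both", seq_len=320,
                         seq_filters=(4, 6, 8), seq_fc=(16, 8),
                         epi_filters=(3, 4, 5), epi_fc=(12, 6),
                         mfb_k=2, mfb_o=6, head_fc=(8, 4))
        seq = rng.random((n, 320, 4)).astype(np.float32)
        epi = [rng.random((n, 1, 41)).astype(np.float32)]
        y = (rng.random(n) < 0.5).astype(float)
        chroms = ["chr1"] * 20 + ["chr7"] * 10 + ["chr8"] * 10
        model = HmcModel(seq, epi, y, chroms=chroms, spec=spec)
        res = model.fit(max_epochs=1, patience=5, batch_size=8, seed=0)
        with pytest.raises(ValueError):
            scan_genome_dhmr(res, {}, {}, {})


def windows(chrom, starts, width=1000):
    return [GenomicInterval(chrom, s, s + width) for s in starts]


class TestSnpEnrichment:
    def test_odds_ratio_closed_form(self):
        assert EnrichmentTable(20, 80, 100, 900).odds_ratio() == 2.25

    def test_haldane_correction_on_zero_cell(self):
        t = EnrichmentTable(0, 10, 5, 100)
        assert t.odds_ratio() == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))

    def test_proportional_table_is_null(self, small_ds):
        # planted positives spread like the sampled negatives -> OR near 1
        rng = np.random.default_rng(0)
        mask = small_ds.noncoding
        lens = np.array([iv.length for iv in mask], float)
        pos = []
        for _ in range(60):
            iv = mask[int(rng.choice(len(mask), p=lens / lens.sum()))]
            p = int(rng.integers(iv.start, iv.end))
            pos.append(GenomicInterval(iv.chrom, p, p + 1))
        dhmrs = small_ds.truth.dhmr_windows(small_ds.peaks)
        non = small_ds.truth.non_dhmr_windows(small_ds.peaks)
        table, odds, ci, p = snp_enrichment(pos, dhmrs, non, mask, seed=1)
        assert table.a + table.b == 60
        assert table.c + table.d == 600
        assert p > 0.001  # no systematic enrichment

    def test_planted_enrichment_detected(self, small_ds):
        dhmrs = small_ds.truth.dhmr_windows(small_ds.peaks)
        non = small_ds.truth.non_dhmr_windows(small_ds.peaks)
        table, odds, ci, p = snp_enrichment(
            small_ds.pos_snps, dhmrs, non, small_ds.noncoding, seed=2)
        assert odds > 1.5
        assert p < 0.01
        assert ci[0] < odds < ci[1]

    def test_deterministic_under_seed(self, small_ds):
        dhmrs = small_ds.truth.dhmr_windows(small_ds.peaks)
        non = small_ds.truth.non_dhmr_windows(small_ds.peaks)
        args = (small_ds.pos_snps, dhmrs, non, small_ds.noncoding)
        r1 = snp_enrichment(*args, seed=7)
        r2 = snp_enrichment(*args, seed=7)
        assert r1[0] == r2[0] and r1[1] == r2[1] and r1[3] == r2[3]

    def test_empty_positive_set_rejected(self, small_ds):
        far = [GenomicInterval("chrZ", 5, 6)]
        with pytest.raises(ValueError):
            snp_enrichment(far, [], [], small_ds.noncoding, seed=0)


class TestFeatureDistribution:
    annotations = [
        (GenomicInterval("chr1", 1000, 3000), "Exon"),
        (GenomicInterval("chr1", 5000, 5600), "Promoter"),
        (GenomicInterval("chr1", 5400, 9000), "Intron"),
    ]

    def call(self, start):
        return DhmrCall(GenomicInterval("chr1", start, start + 1000), 0.9)

    def test_full_containment(self):
        out = summarize_feature_distribution([self.call(1500)], self.annotations)
        assert out["Exon"]["count"] == 1

    def test_no_overlap_is_intergenic(self):
        out = summarize_feature_distribution([self.call(20_000)], self.annotations)
        assert out["Intergenic"]["count"] == 1

    def test_majority_overlap_wins(self):
        # window [5000,6000): 600 bp promoter, 600 bp intron -> tie broken
        # by priority (Promoter); [5100,6100): 500 promoter vs 700 intron
        out = summarize_feature_distribution([self.call(5000)], self.annotations)
        assert out["Promoter"]["count"] == 1
        out = summarize_feature_distribution([self.call(5100)], self.annotations)
        assert out["Intron"]["count"] == 1

    def test_fractions_sum_to_one(self):
        calls = [self.call(s) for s in (1500, 5000, 20_000)]
        out = summarize_feature_distribution(calls, self.annotations)
        assert sum(v["fraction"] for v in out.values()) == pytest.approx(1.0)
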