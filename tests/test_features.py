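"""One-hot encoding, peak standardization, profile windows and k-mer features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmcnet.features import (
    PeakBoundaryWarning,
    build_feature_pair,
    extract_epimark_feature,
    gc_fraction,
    kmer_features,
    n_windows,
    one_hot_encode,
    standardize_peak,
)
from hmcnet.intervals import GenomicInterval, ReadSet

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


class TestStandardizePeak:
    def test_recenter(self):
        p = GenomicInterval("chr1", 10000, 10600)  # center 10300
        assert standardize_peak(p) == GenomicInterval("chr1", 9800, 10800)

    def test_fixed_point(self):
        p = GenomicInterval("chr1", 5000, 6000)
        assert standardize_peak(p) == p

    def test_contig_edge_skipped(self):
        with pytest.warns(PeakBoundaryWarning):
            assert standardize_peak(GenomicInterval("chr1", 400, 401)) is None
        with pytest.warns(PeakBoundaryWarning):
            assert standardize_peak(GenomicInterval("chr1", 5000, 6000),
                                    chrom_size=5800) is None

    def test_odd_peak_len_rejected(self):
        with pytest.raises(ValueError):
            standardize_peak(GenomicInterval("chr1", 5000, 6000), peak_len=999)


class TestOneHot:
    def test_mapping_rule(self):
        m = one_hot_encode("ACGT")
        assert m.tolist() == [[1, 0, 0, 0], [0, 1, 0, 0],
                              [0, 0, 1, 0], [0, 0, 0, 1]]

    def test_ambiguous_rows_zero(self):
        assert one_hot_encode("NNNN").sum() == 0

    def test_long_homopolymer_column_sums(self):
        m = one_hot_encode("A" * 1000, expected_len=1000)
        assert m.sum(axis=0).tolist() == [1000, 0, 0, 0]

    def test_length_contract(self):
        with pytest.raises(ValueError):
            one_hot_encode("ACGT", expected_len=5)

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_row_sums_and_gc(self, seq):
        m = one_hot_encode(seq)
        sums = m.sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 1.0}
        assert sums.sum() == sum(c in "ACGT" for c in seq)
        # GC fraction recoverable from the C and G columns
        assert np.isclose(m[:, 1].sum() + m[:, 2].sum(),
                          gc_fraction(seq) * len(seq))


def _uniform_reads(chrom="chr1", span=(0, 40_000), step=100):
    starts = np.arange(span[0] + step // 2 - 50, span[1], step)
    return ReadSet.from_arrays({chrom: starts}, read_len=100)


class TestEpimarkFeature:
    def test_default_grid_is_41_windows(self):
        assert n_windows() == 41
        region = GenomicInterval("chr1", 15_000, 16_000)
        v = extract_epimark_feature(region, ReadSet([]))
        assert v.shape == (41,)
        assert (v == 0).all()

    def test_uniform_density_counts(self):
        # one midpoint per 100 bp -> every 1 kb window holds exactly 10 reads
        region = GenomicInterval("chr1", 15_000, 16_000)
        v = extract_epimark_feature(region, _uniform_reads(), norm_scale=None)
        assert (v == 10).all()

    def test_depth_normalization_scale(self):
        region = GenomicInterval("chr1", 15_000, 16_000)
        reads = _uniform_reads()
        v = extract_epimark_feature(region, reads, norm_scale=1e7)
        assert np.allclose(v, 10 * 1e7 / reads.total_reads)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 30_000, 500)
        delta = 4321
        r1 = ReadSet.from_arrays({"chr1": starts})
        r2 = ReadSet.from_arrays({"chr1": starts + delta})
        reg = GenomicInterval("chr1", 14_000, 15_000)
        v1 = extract_epimark_feature(reg, r1, norm_scale=None)
        v2 = extract_epimark_feature(reg.shift(delta), r2, norm_scale=None)
        assert (v1 == v2).all()

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 40_000, 500)
        reg = GenomicInterval("chr1", 19_500, 20_500)  # center 20000
        center = 20_000
        # reflect read midpoints about the region center
        mids = starts + 50
        reflected = (2 * center - 1 - mids) - 50
        v1 = extract_epimark_feature(reg, ReadSet.from_arrays({"chr1": starts}),
                                     norm_scale=None)
        v2 = extract_epimark_feature(
            reg, ReadSet.from_arrays({"chr1": reflected}), norm_scale=None)
        assert (v1 == v2[::-1]).all()

    def test_coverage_track_signal(self):
        from hmcnet.intervals import CoverageTrack
        # constant coverage 2.0 over the whole span: every 1 kb window
        # integrates to 2000
        track = CoverageTrack.from_intervals({"chr1": [(0, 40_000, 2.0)]})
        region = GenomicInterval("chr1", 15_000, 16_000)
        v = extract_epimark_feature(region, track, norm_scale=None)
        assert np.allclose(v, 2000.0)

    def test_out_of_bounds_windows_zeroed(self):
        region = GenomicInterval("chr1", 2_000, 3_000)  # flank reaches < 0
        v = extract_epimark_feature(region, _uniform_reads(), norm_scale=None)
        n_oob = (2_000 - 10_000 + 500 * np.arange(41) < 0).sum()
        assert (v[:n_oob] == 0).all()
        assert (v[n_oob:] > 0).all()


class TestFeaturePair:
    def test_shapes_single_mark(self, micro):
        region = micro.peaks[0]
        fp = build_feature_pair(region, micro.genome, micro.mark_reads)
        assert fp.seq.shape == (1000, 4)
        assert len(fp.marks) == 1
        assert fp.marks[0].shape == (1, 41)

    def test_replicates_stack_as_rows(self, micro):
        region = micro.peaks[0]
        reads = micro.mark_reads["enhancer_mark"][0]
        fp = build_feature_pair(region, micro.genome,
                                {"m": [reads, reads, reads]})
        assert fp.marks[0].shape == (3, 41)
        fp2 = build_feature_pair(region, micro.genome,
                                 {"m": [reads, reads, reads]},
                                 replicate_collapse=True)
        assert fp2.marks[0].shape == (1, 41)
        assert np.allclose(fp2.marks[0][0], fp.marks[0].mean(axis=0))

    def test_two_marks_ordered(self, micro):
        region = micro.peaks[0]
        reads = micro.mark_reads["enhancer_mark"]
        fp = build_feature_pair(region, micro.genome,
                                {"b_mark": reads, "a_mark": reads},
                                mark_order=["b_mark", "a_mark"])
        assert len(fp.marks) == 2

    def test_missing_chrom_errors(self, micro):
        with pytest.raises(KeyError):
            build_feature_pair(GenomicInterval("chrZ", 15_000, 16_000),
                               micro.genome, micro.mark_reads)


class TestKmerFeatures:
    def test_dimension(self):
        assert kmer_features("ACGTACGT", k=3).shape == (64,)

    def test_homopolymer(self):
        v = kmer_features("AAAA", k=3)
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_enumerated_windows(self):
        # ACGTACGT: windows ACG,CGT,GTA,TAC,ACG,CGT -> ACG/CGT twice, GTA/TAC once
        v = kmer_features("ACGTACGT", k=3)
        idx = lambda s: sum({"A": 0, "C": 1, "G": 2, "T": 3}[c] * 4 ** (2 - i)
                            for i, c in enumerate(s))
        assert v[idx("ACG")] == pytest.approx(2 / 6)
        assert v[idx("CGT")] == pytest.approx(2 / 6)
        assert v[idx("GTA")] == pytest.approx(1 / 6)
        assert v[idx("TAC")] == pytest.approx(1 / 6)
        assert v.sum() == pytest.approx(1.0)

    def test_ambiguous_windows_excluded(self):
        v = kmer_features("AANAA", k=3)  # only AAN/ANA/NAA windows contain N
        assert v.sum() == 0.0

    @given(dna.filter(lambda s: len(s) >= 3))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_when_valid_window_exists(self, seq):
        v = kmer_features(seq, k=3)
        n_valid = sum(all(c in "ACGT" for c in seq[i:i + 3])
                      for i in range(len(seq) - 2))
        if n_valid:
            assert v.sum() == pytest.approx(1.0)
        else:
            assert v.sum() == 0.0
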