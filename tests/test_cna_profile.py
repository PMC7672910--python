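"""Copy-number post-processing: bins, segment QC, burden, arms, genes, LOH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmlseq.cna_profile import (
    biweight_midvariance,
    call_arms,
    call_gene_copy_number,
    call_loh,
    clean_bins,
    cna_burden,
    qc_segments,
)
from pmlseq.model import (
    CopyNumberBin,
    CopyNumberSegment,
    GenomicInterval,
    GenomicIntervalSet,
    PmlseqError,
)


def _seg(start, end, log2, chrom="chr1", probes=50, ci=None, bivar=0.1, baf=None):
    ci_low, ci_high = ci if ci else (None, None)
    return CopyNumberSegment(
        chrom, start, end, log2, n_probes=probes, ci_low=ci_low, ci_high=ci_high,
        bivar=bivar, baf=baf,
    )


class TestCleanBins:
    def test_artifact_boundary(self):
        removed = CopyNumberBin("chr1", 0, 250, -16.0)
        kept_boundary = CopyNumberBin("chr1", 250, 500, -15.0)
        kept = CopyNumberBin("chr1", 500, 750, -14.9)
        assert clean_bins([removed, kept_boundary, kept]) == [kept_boundary, kept]

    def test_empty_input(self):
        assert clean_bins([]) == []


class TestSegmentQC:
    def test_few_probes_fail(self):
        passing, failing = qc_segments([_seg(0, 100, 0.5, probes=9, ci=(0.4, 0.6))])
        assert not passing and failing[0].reasons == ("few_probes",)
        passing, _ = qc_segments([_seg(0, 100, 0.5, probes=10, ci=(0.4, 0.6))])
        assert len(passing) == 1

    def test_bivar_strictly_more_than_two_fails(self):
        _, failing = qc_segments([_seg(0, 100, 0.5, bivar=2.5, ci=(0.4, 0.6))])
        assert failing[0].reasons == ("high_bivar",)
        passing, _ = qc_segments([_seg(0, 100, 0.5, bivar=2.0, ci=(0.4, 0.6))])
        assert len(passing) == 1

    def test_ci_containing_zero_fails_only_when_required(self):
        seg = _seg(0, 100, 0.2, ci=(-0.1, 0.4))
        _, failing = qc_segments([seg])
        assert failing[0].reasons == ("ci_contains_zero",)
        passing, _ = qc_segments([seg], require_ci=False)
        assert passing == [seg]

    def test_all_criteria_met_passes(self):
        passing, failing = qc_segments([_seg(0, 100, 0.25, probes=50, ci=(0.1, 0.4), bivar=0.5)])
        assert passing and not failing

    def test_missing_ci_is_flagged_but_evaluated_on_other_criteria(self):
        passing, failing = qc_segments([_seg(0, 100, 0.5, probes=9)])
        assert failing[0].flagged_missing_ci and "few_probes" in failing[0].reasons
        passing, failing = qc_segments([_seg(0, 100, 0.5)])
        assert len(passing) == 1


MB = 1_000_000


class TestBurden:
    def test_flat_profile_has_zero_burden(self):
        segs = [_seg(0, 10 * MB, 0.0), _seg(10 * MB, 30 * MB, 0.1)]
        assert cna_burden(segs).total_fraction == 0.0

    def test_single_gain_fraction(self):
        segs = [_seg(0, 30 * MB, 0.5), _seg(30 * MB, 100 * MB, 0.0)]
        result = cna_burden(segs)
        assert result.gain_fraction == pytest.approx(0.30)
        assert result.loss_fraction == 0.0

    def test_gain_and_loss_fractions_sum(self):
        segs = [
            _seg(0, 20 * MB, 0.6),
            _seg(20 * MB, 30 * MB, -0.8),
            _seg(30 * MB, 100 * MB, 0.0),
        ]
        result = cna_burden(segs)
        assert result.gain_fraction == pytest.approx(0.20)
        assert result.loss_fraction == pytest.approx(0.10)
        assert result.total_fraction == pytest.approx(0.30)

    def test_zero_total_length_is_an_error(self):
        with pytest.raises(PmlseqError):
            cna_burden([])

    def test_threshold_boundaries_are_strict(self):
        segs = [_seg(0, MB, 0.3), _seg(MB, 2 * MB, -0.3)]
        assert cna_burden(segs).total_fraction == 0.0

    @given(st.lists(st.tuples(st.integers(1, 50), st.floats(-2, 2)), min_size=1, max_size=30))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_length_summation(self, spec):
        segs, cursor = [], 0
        for length, log2 in spec:
            segs.append(_seg(cursor, cursor + length * 1000, log2))
            cursor += length * 1000
        result = cna_burden(segs)
        total = sum(s.length for s in segs)
        gain = sum(s.length for s in segs if s.log2 > 0.3)
        loss = sum(s.length for s in segs if s.log2 < -0.3)
        assert result.gain_fraction == pytest.approx(gain / total)
        assert result.loss_fraction == pytest.approx(loss / total)

    def test_splitting_a_segment_leaves_burden_unchanged(self):
        whole = [_seg(0, 40 * MB, 0.5), _seg(40 * MB, 100 * MB, 0.0)]
        split = [
            _seg(0, 15 * MB, 0.5),
            _seg(15 * MB, 40 * MB, 0.5),
            _seg(40 * MB, 100 * MB, 0.0),
        ]
        a, b = cna_burden(whole), cna_burden(split)
        assert a.gain_fraction == pytest.approx(b.gain_fraction)
        assert a.total_fraction == pytest.approx(b.total_fraction)


ARMS = GenomicIntervalSet(
    [
        GenomicInterval("chr1", 0, 50 * MB, "1p"),
        GenomicInterval("chr1", 50 * MB, 100 * MB, "1q"),
    ]
)


class TestArmCalls:
    def test_majority_loss_calls_the_arm_lost(self):
        segs = [
            _seg(0, 30 * MB, -0.6, ci=(-0.7, -0.5)),
            _seg(30 * MB, 50 * MB, 0.0),
        ]
        calls = {c.arm: c for c in call_arms(segs, ARMS)}
        assert calls["1p"].status == "lost"
        assert calls["1p"].involved_fraction == pytest.approx(0.6)

    def test_exactly_half_is_neutral(self):
        segs = [
            _seg(0, 25 * MB, -0.6, ci=(-0.7, -0.5)),
            _seg(25 * MB, 50 * MB, 0.0),
        ]
        calls = {c.arm: c for c in call_arms(segs, ARMS)}
        assert calls["1p"].status == "neutral"

    def test_arm_without_segments_is_neutral_with_zero_fraction(self):
        calls = {c.arm: c for c in call_arms([_seg(0, MB, 0.0)], ARMS)}
        assert calls["1q"].status == "neutral" and calls["1q"].involved_fraction == 0.0

    def test_order_invariance(self):
        segs = [
            _seg(0, 30 * MB, -0.6, ci=(-0.7, -0.5)),
            _seg(30 * MB, 50 * MB, 0.0),
            _seg(50 * MB, 90 * MB, 0.8, ci=(0.7, 0.9)),
        ]
        fwd = [(c.arm, c.status) for c in call_arms(segs, ARMS)]
        rev = [(c.arm, c.status) for c in call_arms(list(reversed(segs)), ARMS)]
        assert fwd == rev

    def test_unconfident_segment_does_not_drive_a_call(self):
        segs = [_seg(0, 40 * MB, -0.6, ci=(-1.4, 0.1)), _seg(40 * MB, 50 * MB, 0.0)]
        calls = {c.arm: c for c in call_arms(segs, ARMS)}
        assert calls["1p"].status == "neutral"


GENES = GenomicIntervalSet(
    [
        GenomicInterval("chr1", 10_000, 20_000, "ERBB2"),
        GenomicInterval("chr1", 40_000, 50_000, "TP53"),
    ]
)


def _bins_over(start, end, log2, width=250):
    return [
        CopyNumberBin("chr1", s, s + width, log2)
        for s in range(start, end, width)
    ]


class TestGeneCopyNumber:
    def test_too_few_bins_excluded(self):
        bins = _bins_over(10_000, 10_500, 0.8)  # only 2 bins
        segs = [_seg(0, 100_000, 0.8, probes=200, ci=(0.7, 0.9))]
        calls = call_gene_copy_number({"A": (bins, segs)}, GENES)["A"]
        erbb2 = next(c for c in calls if c.gene == "ERBB2")
        assert erbb2.status == "excluded" and erbb2.reason == "ineligible"

    def test_low_probe_segment_excluded(self):
        bins = _bins_over(10_000, 20_000, 0.8)
        segs = [_seg(0, 100_000, 0.8, probes=109, ci=(0.7, 0.9))]
        calls = call_gene_copy_number({"A": (bins, segs)}, GENES)["A"]
        assert next(c for c in calls if c.gene == "ERBB2").status == "excluded"

    def test_eligible_gene_in_amplified_segment_is_a_gain(self):
        bins = _bins_over(10_000, 20_000, 0.8)
        segs = [_seg(0, 100_000, 0.8, probes=200, ci=(0.7, 0.9))]
        calls = call_gene_copy_number({"A": (bins, segs)}, GENES)["A"]
        erbb2 = next(c for c in calls if c.gene == "ERBB2")
        assert erbb2.status == "gain" and erbb2.log2 == pytest.approx(0.8)

    def test_reporting_thresholds_are_asymmetric(self):
        bins = _bins_over(10_000, 20_000, 0.35) + _bins_over(40_000, 50_000, -0.5)
        segs = [
            _seg(0, 30_000, 0.35, probes=150, ci=(0.3, 0.4)),
            _seg(30_000, 100_000, -0.5, probes=150, ci=(-0.6, -0.4)),
        ]
        calls = {c.gene: c for c in call_gene_copy_number({"A": (bins, segs)}, GENES)["A"]}
        assert calls["ERBB2"].status == "neutral"  # 0.35 < 0.4 gain threshold
        assert calls["TP53"].status == "neutral"  # -0.5 > -0.6 loss threshold

    def test_breakpoint_in_one_region_excludes_gene_in_all_regions(self):
        bins = _bins_over(10_000, 20_000, 0.8)
        whole = [_seg(0, 100_000, 0.8, probes=200, ci=(0.7, 0.9))]
        split = [
            _seg(0, 15_000, 0.8, probes=120, ci=(0.7, 0.9)),
            _seg(15_000, 100_000, 0.0, probes=120),
        ]
        calls = call_gene_copy_number({"A": (bins, split), "B": (bins, whole)}, GENES)
        for region in ("A", "B"):
            erbb2 = next(c for c in calls[region] if c.gene == "ERBB2")
            assert erbb2.status == "excluded" and erbb2.reason == "breakpoint"

    def test_higher_confidence_segment_wins_for_multi_segment_gene(self):
        # both segments fully overlap the gene region; narrower CI wins
        bins = _bins_over(10_000, 20_000, 0.8)
        segs = [
            _seg(5_000, 25_000, 0.8, probes=150, ci=(0.2, 1.4)),
            _seg(5_000, 25_000, 0.1, probes=150, ci=(0.05, 0.15)),
        ]
        calls = call_gene_copy_number({"A": (bins, segs)}, GENES)["A"]
        erbb2 = next(c for c in calls if c.gene == "ERBB2")
        assert erbb2.log2 == pytest.approx(0.1)


class TestLoh:
    @pytest.mark.parametrize(
        "baf,expected",
        [(0.25, True), (0.3, False), (0.5, False), (0.7, False), (0.75, True)],
    )
    def test_baf_thresholds_are_strict(self, baf, expected):
        (call,) = call_loh([_seg(0, MB, 0.0, baf=baf)])
        assert call.is_loh is expected

    def test_missing_baf_is_not_loh_and_flagged(self):
        (call,) = call_loh([_seg(0, MB, 0.0)])
        assert not call.is_loh and call.flagged_missing_baf


def test_biweight_midvariance_tracks_dispersion():
    rng = np.random.default_rng(0)
    tight = biweight_midvariance(rng.normal(0, 0.1, 500))
    wide = biweight_midvariance(rng.normal(0, 1.0, 500))
    assert 0 < tight < wide
    assert biweight_midvariance([0.5]) == 0.0
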