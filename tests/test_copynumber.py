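import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonevo import copynumber
from clonevo.copynumber import Region
from clonevo.types import ClonevoError, GenomicEvent, PloidyCall, Segment


def seg(chrom, start, end, major, minor):
    return Segment(chrom, start, end, major, minor)


class TestComputePloidy:
    def test_diploid_genome(self):
        call = copynumber.compute_ploidy(
            [seg("chr1", 1, 1000, 1, 1), seg("chr2", 1, 5000, 1, 1)]
        )
        assert call.ploidy == 2.0
        assert not call.wgd

    def test_tetraploid_genome(self):
        call = copynumber.compute_ploidy([seg("chr1", 1, 1000, 2, 2)])
        assert call.ploidy == 4.0
        assert call.wgd

    def test_length_weighted_mean(self):
        # 100 Mb at total 3 plus 50 Mb at total 4 -> (300+200)/150
        call = copynumber.compute_ploidy(
            [
                seg("chr1", 1, 100_000_000, 2, 1),
                seg("chr2", 1, 50_000_000, 2, 2),
            ]
        )
        assert call.ploidy == pytest.approx(10 / 3, rel=1e-9)
        assert call.wgd

    def test_wgd_threshold_is_strict(self):
        # exactly 3 is not WGD; the tiniest excess is
        exactly3 = copynumber.compute_ploidy([seg("chr1", 1, 100, 2, 1)])
        assert not exactly3.wgd
        above = copynumber.compute_ploidy(
            [seg("chr1", 1, 99, 2, 1), seg("chr2", 1, 1, 2, 2)]
        )
        assert above.ploidy > 3
        assert above.wgd

    def test_empty_input_is_error(self):
        with pytest.raises(ClonevoError):
            copynumber.compute_ploidy([])

    @given(
        total=st.integers(0, 8),
        minor=st.integers(0, 4),
        split=st.integers(2, 9000),
    )
    def test_invariant_to_segment_splitting(self, total, minor, split):
        """Splitting a segment into equal-state pieces never moves ploidy."""
        minor = min(minor, total // 2)
        major = total - minor
        whole = [seg("chr1", 1, 10_000, major, minor),
                 seg("chr2", 1, 5_000, 1, 1)]
        parts = [
            seg("chr1", 1, split, major, minor),
            seg("chr1", split + 1, 10_000, major, minor),
            seg("chr2", 1, 5_000, 1, 1),
        ]
        assert copynumber.compute_ploidy(whole).ploidy == pytest.approx(
            copynumber.compute_ploidy(parts).ploidy, rel=1e-12
        )


GENE = Region("chr13", 1000, 2000, "RB1")


class TestGeneEvents:
    def test_loh_plus_loss_in_diploid(self):
        events = copynumber.call_gene_events(
            [seg("chr13", 1, 10_000, 1, 0)], [GENE], PloidyCall(2.0, False)
        )
        assert {e.kind for e in events} == {"LOH", "loss"}

    def test_focal_amplification_chrx_male(self):
        # total 8 on a 1 Mb segment against ploidy 3.8 (hemizygous chrX)
        gene = Region("chrX", 67_544_021, 67_730_619, "AR")
        segs = [
            seg("chrX", 1, 67_000_000, 2, 0),
            seg("chrX", 67_000_001, 68_000_000, 8, 0),
            seg("chrX", 68_000_001, 156_000_000, 2, 0),
        ]
        events = copynumber.call_gene_events(
            segs, [gene], PloidyCall(3.8, True), sex="male"
        )
        assert any(e.kind == "focal_amplification" for e in events)
        # hemizygous X: no LOH call, and 2 copies is not a loss
        assert not any(e.kind in ("LOH", "loss") for e in events)

    def test_balanced_diploid_gene_is_silent(self):
        events = copynumber.call_gene_events(
            [seg("chr13", 1, 10_000, 1, 1)], [GENE], PloidyCall(2.0, False)
        )
        assert events == []

    def test_uncovered_gene_is_nocall(self):
        events = copynumber.call_gene_events(
            [seg("chr13", 1, 1500, 1, 0)], [GENE], PloidyCall(2.0, False)
        )
        assert events == []

    def test_straddling_gene_uses_extreme_states(self):
        segs = [seg("chr13", 1, 1500, 1, 0), seg("chr13", 1501, 3000, 2, 1)]
        events = copynumber.call_gene_events(
            segs, [GENE], PloidyCall(2.0, False)
        )
        assert {e.kind for e in events} == {"LOH", "loss"}

    def test_post_wgd_single_copy_is_loss(self):
        events = copynumber.call_gene_events(
            [seg("chr13", 1, 10_000, 1, 0)], [GENE], PloidyCall(4.0, True)
        )
        assert any(e.kind == "loss" for e in events)


ARM = Region("chr4", 1, 50_000_000, "4p")


class TestArmEvents:
    def test_copy_neutral_loh(self):
        events = copynumber.call_arm_events(
            [seg("chr4", 1, 50_000_000, 2, 0)], [ARM], PloidyCall(2.0, False)
        )
        assert {e.kind for e in events} == {"LOH"}

    def test_gain_one_copy_above_ploidy(self):
        events = copynumber.call_arm_events(
            [seg("chr4", 1, 50_000_000, 2, 1)], [ARM], PloidyCall(2.0, False)
        )
        assert {e.kind for e in events} == {"gain"}

    def test_balanced_arm_is_silent(self):
        events = copynumber.call_arm_events(
            [seg("chr4", 1, 50_000_000, 1, 1)], [ARM], PloidyCall(2.0, False)
        )
        assert events == []

    def test_low_coverage_is_nocall(self):
        events = copynumber.call_arm_events(
            [seg("chr4", 1, 10_000_000, 2, 0)], [ARM], PloidyCall(2.0, False)
        )
        assert events == []


class TestCompareAcrossSamples:
    def test_shared_and_private_split(self):
        rb1 = lambda: GenomicEvent("LOH", "gene", "RB1")
        tp53 = GenomicEvent("LOH", "gene", "TP53")
        part = copynumber.compare_events_across_samples(
            {"ADENO": [rb1()], "TNEPC": [rb1(), tp53]}
        )
        assert [e.target for e in part["shared_all"]] == ["RB1"]
        assert [e.target for e in part["private"]] == ["TP53"]
        assert part["private"][0].present_in() == {"TNEPC"}

    def test_identical_sets_all_shared(self):
        ev = lambda: GenomicEvent("gain", "arm", "3p")
        part = copynumber.compare_events_across_samples(
            {"A": [ev()], "B": [ev()]}
        )
        assert len(part["shared_all"]) == 1
        assert not part["private"] and not part["shared_subset"]

    def test_subset_sharing_three_samples(self):
        ev = lambda: GenomicEvent("loss", "gene", "PTEN")
        part = copynumber.compare_events_across_samples(
            {"S1": [], "S2": [ev()], "S3": [ev()]}
        )
        assert part["shared_subset"][0].present_in() == {"S2", "S3"}

    def test_single_sample_is_error(self):
        with pytest.raises(ClonevoError):
            copynumber.compare_events_across_samples({"S1": []})
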