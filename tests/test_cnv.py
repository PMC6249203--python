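import numpy as np
import pytest

from ipsc_integrity import cnv as cn
from ipsc_integrity.types import CnvSegment, DomainError, SampleMeta


def _seg(chrom, start, end, state="loss", fraction=1.0, sample="c1", n_genes=0):
    return CnvSegment(chrom, start, end, state, fraction, n_genes, sample)


class TestReciprocalOverlap:
    def test_hand_oracle(self):
        a = _seg("chr1", 0, 100)
        b = _seg("chr1", 50, 150)
        # overlap 50; fractions 50/100 and 50/100
        assert cn.reciprocal_overlap(a, b) == pytest.approx(0.5)
        assert cn.reciprocal_overlap(a, _seg("chr2", 0, 100)) == 0.0
        assert cn.reciprocal_overlap(a, _seg("chr1", 100, 200)) == 0.0


class TestSomaticCalling:
    def test_size_and_absence_criteria(self):
        clone = [_seg("chr10", 0, 150_000), _seg("chr11", 0, 90_000)]
        somatic = cn.call_somatic_cnvs(clone, [], donor_id="D1")
        assert [s.segment.chrom for s in somatic] == ["chr10"]  # 90 kb excluded

    def test_fibroblast_overlap_same_direction_blocks(self):
        clone = [_seg("chr10", 0, 150_000, "loss")]
        fib_same = [_seg("chr10", 10_000, 140_000, "loss", sample="f1")]
        # reciprocal overlap 130/150 vs 130/130 -> min ~0.867 >= 0.5
        assert cn.call_somatic_cnvs(clone, fib_same) == []
        fib_opposite = [_seg("chr10", 10_000, 140_000, "gain", sample="f1")]
        assert len(cn.call_somatic_cnvs(clone, fib_opposite)) == 1
        fib_small = [_seg("chr10", 0, 30_000, "loss", sample="f1")]
        assert len(cn.call_somatic_cnvs(clone, fib_small)) == 1

    def test_cohort_pairing(self):
        metas = [
            SampleMeta("fD1", "D1", "fibroblast"),
            SampleMeta("iD1", "D1", "RiPSC", 10, "retroviral", parent_sample="fD1"),
        ]
        segs = [
            _seg("chr5", 0, 400_000, "gain", sample="iD1"),
            _seg("chr5", 0, 400_000, "gain", sample="fD1"),
            _seg("chr7", 0, 200_000, "loss", sample="iD1"),
        ]
        somatic = cn.call_cohort_somatic_cnvs(segs, metas)
        assert [s.segment.chrom for s in somatic] == ["chr7"]

    def test_min_size_never_violated(self, cohort):
        truth, metas = cohort["truth"], cohort["metas"]
        segs = []
        for donor in truth.donors.values():
            segs.extend(donor.fibroblast_cnvs)
            for clone in donor.clones.values():
                segs.extend(clone.cnvs)
        for s in cn.call_cohort_somatic_cnvs(segs, metas):
            assert s.segment.length >= cn.MIN_SOMATIC_SIZE


class TestAneuploidy:
    LENGTHS = {"chr12": 10_000_000}

    def test_full_chromosome_gain_is_trisomy(self):
        calls = cn.detect_aneuploidy([_seg("chr12", 0, 10_000_000, "gain")], self.LENGTHS)
        assert calls.loc[0, "call"] == "trisomy" and not calls.loc[0, "mosaic"]

    def test_subclonal_fraction_reported_mosaic(self):
        calls = cn.detect_aneuploidy(
            [_seg("chr12", 0, 10_000_000, "gain", fraction=0.4)], self.LENGTHS
        )
        assert calls.loc[0, "mosaic"] and calls.loc[0, "clonal_fraction"] == 0.4

    def test_half_chromosome_is_segmental(self):
        calls = cn.detect_aneuploidy([_seg("chr12", 0, 5_000_000, "gain")], self.LENGTHS)
        assert calls.empty


class TestLineage:
    def test_fixed_to_half_flags_oligoclonality(self):
        parent = [_seg("chr11", 0, 500_000, "loss", 1.0)]
        npc = [_seg("chr11", 0, 500_000, "loss", 0.5, sample="npc")]
        report = cn.compare_lineage(parent, npc)
        assert report["counts"]["fraction_shifted"] == 1
        assert report["oligoclonality_flag"]

    def test_identical_sets_all_retained(self):
        parent = [_seg("chr11", 0, 500_000, "loss"), _seg("chr2", 0, 300_000, "gain")]
        deriv = [_seg("chr11", 0, 500_000, "loss"), _seg("chr2", 0, 300_000, "gain")]
        report = cn.compare_lineage(parent, deriv)
        assert report["counts"] == {"retained": 2, "fraction_shifted": 0, "lost": 0, "gained": 0}
        assert not report["oligoclonality_flag"]

    def test_passage_comparison_no_differences(self):
        # same CNVs at passage 14 and 30: nothing gained or lost
        p14 = [_seg("chr4", 0, 2_000_000, "gain")]
        p30 = [_seg("chr4", 0, 2_000_000, "gain")]
        report = cn.compare_lineage(p14, p30)
        assert report["counts"]["gained"] == 0 and report["counts"]["lost"] == 0

    def test_zero_culture_cnv_rate_conserves_lineage(self, cohort):
        truth = cohort["truth"]
        for m in cohort["metas"]:
            if m.material != "NPC":
                continue
            parent = truth.donors[m.donor_id].clones[m.parent_sample].cnvs
            npc = truth.donors[m.donor_id].clones[m.sample_id].cnvs
            report = cn.compare_lineage(parent, npc, overlap_rule=0.99)
            assert report["counts"]["gained"] == 0 and report["counts"]["lost"] == 0


class TestRecurrence:
    def test_two_donor_overlap_found(self):
        cnvs = [
            cn.SomaticCnv(_seg("chr10", 0, 200_000, "loss", sample="i88H-R1-001"), "88H"),
            cn.SomaticCnv(_seg("chr10", 150_000, 400_000, "loss", sample="iO3H-R1-001"), "O3H"),
        ]
        regions = cn.find_recurrent_regions(cnvs)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (150_000, 200_000)  # intersection footprint
        assert r.donors == {"88H", "O3H"} and len(r.supporting_clones) == 2

    def test_single_cnv_no_region(self):
        cnvs = [cn.SomaticCnv(_seg("chr10", 0, 200_000), "D1")]
        assert cn.find_recurrent_regions(cnvs) == []

    def test_same_clone_does_not_recur(self):
        cnvs = [
            cn.SomaticCnv(_seg("chr10", 0, 200_000, sample="c1"), "D1"),
            cn.SomaticCnv(_seg("chr10", 100_000, 300_000, sample="c1"), "D1"),
        ]
        assert cn.find_recurrent_regions(cnvs) == []

    def test_mixed_states_count_together(self):
        # two deletions and a duplication within one locus: one region with
        # three supporting clones (independent reprogramming events)
        cnvs = [
            cn.SomaticCnv(_seg("chr11", 0, 300_000, "loss", sample="i82A-R1-001"), "82A"),
            cn.SomaticCnv(_seg("chr11", 100_000, 400_000, "loss", sample="i82A-R1-002"), "82A"),
            cn.SomaticCnv(_seg("chr11", 150_000, 500_000, "gain", sample="iK22-S1-001"), "K22"),
        ]
        regions = cn.find_recurrent_regions(cnvs)
        assert len(regions) == 1
        assert len(regions[0].supporting_clones) == 3
        assert regions[0].copy_states == {"loss", "gain"}


class TestRegressions:
    @staticmethod
    def _metas(n_donors=6, clones_per_donor=2):
        metas = []
        for d in range(n_donors):
            donor = f"D{d}"
            metas.append(SampleMeta(f"f{donor}", donor, "fibroblast"))
            for c in range(clones_per_donor):
                material = "RiPSC" if c % 2 == 0 else "SiPSC"
                method = "retroviral" if c % 2 == 0 else "sendai"
                metas.append(
                    SampleMeta(f"i{donor}-{c}", donor, material, 5 + d, method,
                               donor_age=30.0 + 5 * d, parent_sample=f"f{donor}")
                )
        return metas

    @staticmethod
    def _cnvs_for_counts(metas, counts):
        cnvs = []
        for m in metas:
            if m.material not in ("RiPSC", "SiPSC"):
                continue
            for i in range(counts[m.sample_id]):
                cnvs.append(
                    cn.SomaticCnv(
                        _seg("chr3", i * 1_000_000, i * 1_000_000 + 200_000,
                             sample=m.sample_id),
                        m.donor_id,
                    )
                )
        return cnvs

    def test_exact_linear_truth_r2_one(self):
        metas = self._metas()
        clones = [m for m in metas if m.material in ("RiPSC", "SiPSC")]
        counts = {m.sample_id: m.passage - 3 for m in clones}  # exact line in passage
        result = cn.cnv_regressions(self._cnvs_for_counts(metas, counts), metas)
        assert result["passage_fit"]["r_squared"] == pytest.approx(1.0)
        assert result["passage_fit"]["slope"] == pytest.approx(1.0)

    def test_age_null_slope_ci_coverage(self):
        # CNV rate independent of donor age: slope CI covers 0 in >=90 of 100
        rng = np.random.default_rng(17)
        metas = self._metas(n_donors=10)
        clones = [m for m in metas if m.material in ("RiPSC", "SiPSC")]
        covered = 0
        for _ in range(100):
            counts = {m.sample_id: int(rng.poisson(1.3)) for m in clones}
            result = cn.cnv_regressions(self._cnvs_for_counts(metas, counts), metas)
            lo, hi = result["age_fit"]["slope_ci"]
            covered += lo <= 0.0 <= hi
        assert covered >= 90

    def test_size_outlier_excluded(self):
        metas = self._metas(n_donors=3)
        cnvs = [
            cn.SomaticCnv(_seg("chr1", 0, 5_900_000, sample="iD0-0"), "D0"),  # > 5 Mb
            cn.SomaticCnv(_seg("chr2", 0, 200_000, sample="iD0-0"), "D0"),
            cn.SomaticCnv(_seg("chr2", 0, 300_000, sample="iD0-1"), "D0"),
        ]
        result = cn.cnv_regressions(cnvs, metas)
        # count comparison keeps the outlier, size comparison drops it
        assert result["group_comparisons"]["count"]["test"] == "mannwhitneyu"
        assert result["group_comparisons"]["size"]["test"] == "mannwhitneyu"
        per_clone = result["per_clone"].set_index("sample_id")
        assert per_clone.loc["iD0-0", "n_cnvs"] == 2

    def test_too_few_units_refused(self):
        metas = self._metas(n_donors=1, clones_per_donor=1)
        with pytest.raises(DomainError):
            cn.cnv_regressions([], metas)
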