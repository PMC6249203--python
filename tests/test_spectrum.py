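import numpy as np
import pytest

from ipsc_integrity import simulate as sm
from ipsc_integrity import somatic as so
from ipsc_integrity import spectrum as sp
from ipsc_integrity.types import GeneAnnotationSet, Locus, VariantObservation

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _call(ref, alt, sample="c1", pos=None, impact="MODERATE", gene="", scores=None,
          somatic_class="fixed"):
    _call.counter = getattr(_call, "counter", 0) + 1
    obs = VariantObservation(
        Locus("chr1", pos if pos is not None else _call.counter, ref, alt),
        sample, 40, 80, impact, gene, scores or {},
    )
    call = so.SomaticCall(obs, "D1", 0, 80)
    call.somatic_class = somatic_class
    return call


class TestStrandCollapse:
    @pytest.mark.parametrize("ref", "ACGT")
    def test_collapse_idempotent_and_revcomp_invariant(self, ref):
        for alt in "ACGT":
            if alt == ref:
                continue
            cls = sp.collapse_snv(ref, alt)
            assert cls[0] in "CT"
            # collapsing the reverse complement yields the same class
            assert sp.collapse_snv(_COMP[ref], _COMP[alt]) == cls
            # collapsing an already-collapsed class is the identity
            assert sp.collapse_snv(*cls.split(">")) == cls

    def test_transition_counts(self):
        calls = [_call("C", "T"), _call("G", "A"), _call("A", "G"), _call("C", "A")]
        s = sp.partition_spectrum(calls)["c1"]
        assert s.transitions == 3 and s.transversions == 1
        assert s.snv_spectrum["C>T"] == 2  # G>A collapsed into C>T

    def test_empty_call_set(self):
        assert sp.partition_spectrum([]) == {}


class TestPartition:
    def test_count_conservation(self, cohort):
        summaries = sp.partition_spectrum(cohort["fixed"])
        for s in summaries.values():
            assert sum(s.impact_counts.values()) == s.n_calls
            assert sum(s.type_counts.values()) == s.n_calls
            total = sum(s.snv_spectrum.values())
            assert total == s.type_counts.get("SNV", 0)
            if total:
                assert sum(s.spectrum_fractions.values()) == pytest.approx(1.0)

    def test_frame_shape(self, cohort):
        frame = sp.spectrum_frame(sp.partition_spectrum(cohort["fixed"]))
        assert (frame["transitions"] + frame["transversions"] == frame["type_SNV"]).all()


class TestUvSignature:
    def test_cc_tt_and_strand_equivalent_counted(self):
        calls = [_call("CC", "TT"), _call("GG", "AA"), _call("AT", "GC")]
        table = sp.uv_scores(calls)
        assert table.loc[0, "n_cc_tt"] == 2 and table.loc[0, "n_mnp"] == 3

    def test_context_check_rejects_non_dipyrimidine(self):
        c = _call("CC", "TT", pos=500)
        contexts = {("chr1", 500): "GCC"}  # purine 5' flank: still dipyrimidine CC
        assert sp.uv_scores([c], contexts=contexts).loc[0, "n_cc_tt"] == 1
        # a recorded context lacking the pyrimidine pair is rejected
        contexts = {("chr1", 500): "ATA"}
        assert sp.uv_scores([c], contexts=contexts).loc[0, "n_cc_tt"] == 0

    def test_uv_clone_scores_above_non_uv(self):
        # 200 simulated clone pairs drawn from the generator's UV and non-UV
        # channels: the UV clone outranks the non-UV clone in >=95%
        rng = np.random.default_rng(21)
        wins = 0
        for trial in range(200):
            uv_calls, null_calls = [], []
            for i in range(rng.poisson(35)):
                if rng.random() < 0.25:
                    ref, alt = ("CC", "TT") if rng.random() < 0.5 else ("GG", "AA")
                else:
                    ref, alt = sm._draw_snv_alleles(rng, ct_boost=3.0)
                uv_calls.append(_call(ref, alt, sample="uv", pos=10 * i))
            for i in range(rng.poisson(35)):
                ref, alt = sm._draw_snv_alleles(rng)
                null_calls.append(_call(ref, alt, sample="nv", pos=10 * i))
            table = sp.uv_scores(uv_calls + null_calls).set_index("sample_id")
            wins += table.loc["uv", "uv_score"] > table.loc["nv", "uv_score"]
        assert wins >= 190

    def test_null_calibrated_threshold_bounds_firing_rate(self):
        rng = np.random.default_rng(5)
        null_scores = rng.beta(2, 8, size=300)
        threshold = sp.uv_threshold_from_null(null_scores, q=0.99)
        fired = np.sum(null_scores > threshold)
        assert fired <= 3  # <= 1% of 300 by construction


class TestScorePartition:
    def test_cutoffs_and_boundary_rule(self):
        calls = [
            _call("A", "G", scores={"CADD": 25.0, "REVEL": 0.5}),
            _call("A", "G", scores={"CADD": 10.0, "REVEL": 0.4}),
        ]
        table = sp.score_partition(calls).set_index("score")
        assert table.loc["CADD", "n_above"] == 1  # 25 >= 20
        assert table.loc["REVEL", "n_above"] == 1  # inclusive at 0.5
        strict = sp.score_partition(calls, inclusive=False).set_index("score")
        assert strict.loc["REVEL", "n_above"] == 0
        assert table.loc["M-CAP", "n_total"] == 0  # missing scores excluded

    def test_uniform_scores_split_at_half(self):
        rng = np.random.default_rng(3)
        calls = [
            _call("A", "G", pos=i, scores={"REVEL": float(v)})
            for i, v in enumerate(rng.uniform(0, 1, size=2000))
        ]
        frac = sp.score_partition(calls, cutoffs={"REVEL": 0.5}).loc[0, "fraction_above"]
        # closed-form uniform tail: P(X >= 0.5) = 0.5, +-4 binomial SEs
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 2000)


class TestGeneFlags:
    ANNOTATION = GeneAnnotationSet(
        cgc={"BRAF"},
        omim={"BRAF": "Cardiofaciocutaneous syndrome", "MTM1": "Myotubular myopathy"},
        brain_elevated={"GPR162"},
        pli={"BRAF": 1.0},
    )

    def test_high_impact_listed_gene_flagged(self):
        calls = [_call("C", "T", impact="HIGH", gene="BRAF")]
        flagged = sp.flag_listed_genes(calls, self.ANNOTATION)
        assert len(flagged) == 1
        assert flagged[0].lists_hit == {"CGC", "OMIM"}
        assert flagged[0].pli == 1.0

    def test_moderate_impact_not_flagged(self):
        assert sp.flag_listed_genes(
            [_call("C", "T", impact="MODERATE", gene="BRAF")], self.ANNOTATION
        ) == []

    def test_unlisted_gene_not_flagged(self):
        assert sp.flag_listed_genes(
            [_call("C", "T", impact="HIGH", gene="NOVEL1")], self.ANNOTATION
        ) == []

    def test_low_frequency_not_flagged(self):
        assert sp.flag_listed_genes(
            [_call("C", "T", impact="HIGH", gene="BRAF", somatic_class="low_frequency")],
            self.ANNOTATION,
        ) == []
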