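import filecmp

import numpy as np
import pytest
from scipy import stats

from ipsc_integrity import io as fio
from ipsc_integrity import simulate as sm
from ipsc_integrity.mosaicism import detection_probability
from ipsc_integrity.types import IntegrityError


def test_zero_subclones_is_config_error():
    with pytest.raises(IntegrityError):
        sm.simulate_cohort(sm.SimConfig(n_subclones_per_fibroblast=0))


def test_uv_channel_switched_off():
    config = sm.SimConfig(n_donors=2, uv_subclone_prob=0.0, seed=3)
    truth, _ = sm.simulate_cohort(config)
    for donor in truth.donors.values():
        assert not any(donor.subclone_is_uv)
        assert not any(v.is_uv_mnp for v in donor.subclone_variants)


def test_single_subclone_forces_bulk_af_half():
    config = sm.SimConfig(n_donors=2, n_subclones_per_fibroblast=1, seed=4)
    truth, _ = sm.simulate_cohort(config)
    for donor in truth.donors.values():
        assert all(v.fib_af == 0.5 for v in donor.subclone_variants)


def test_npc_inherits_parent_variants_without_passaging():
    config = sm.SimConfig(n_donors=2, lambda_passage=0.0, seed=5)
    truth, metas = sm.simulate_cohort(config)
    for m in metas:
        if m.material != "NPC":
            continue
        npc_afs = truth.sample_afs(m.sample_id)
        parent_afs = truth.sample_afs(m.parent_sample)
        assert npc_afs == parent_afs


def test_fibroblast_bulk_af_law():
    # bulk AF of a mosaic variant is half the carrying subclone's proportion
    config = sm.SimConfig(n_donors=2, seed=6)
    truth, _ = sm.simulate_cohort(config)
    for donor in truth.donors.values():
        for v in donor.subclone_variants:
            assert v.fib_af == pytest.approx(0.5 * donor.subclone_proportions[v.subclone])
            assert 0.0 < v.fib_af <= 0.5


def test_binomial_sampling_moments():
    # one subclone, many variants fixed at AF 0.5, near-Poisson depth 80
    config = sm.SimConfig(
        n_donors=1, n_subclones_per_fibroblast=1, lambda_mosaic=400.0,
        n_germline=0, lambda_passage=0.0, oligoclonal_prob=0.0,
        mean_depth=80.0, depth_dispersion=1e6, seq_error=0.0,
        n_ripsc=1, n_sipsc=0, n_npc=0, vector_snv_lambda=0.0, seed=7,
    )
    truth, metas = sm.simulate_cohort(config)
    clone = next(m.sample_id for m in metas if m.material == "RiPSC")
    obs = [o for o in sm.sample_reads(truth) if o.sample_id == clone]
    depths = np.array([o.total_depth for o in obs], dtype=float)
    alts = np.array([o.alt_depth for o in obs], dtype=float)
    assert abs(depths.mean() - 80.0) < 3 * depths.std() / np.sqrt(len(depths))
    # E[alt] = 0.5 * depth per site; compare against the binomial SE
    se = np.sqrt(np.sum(depths * 0.25)) / len(depths)
    assert abs(alts.mean() - 0.5 * depths.mean()) < 3 * se


def test_true_af_zero_without_error_never_sampled():
    config = sm.SimConfig(n_donors=1, seq_error=0.0, seed=8)
    truth, metas = sm.simulate_cohort(config)
    blood = next(m.sample_id for m in metas if m.material == "blood")
    afs = truth.sample_afs(blood)
    for o in sm.sample_reads(truth):
        if o.sample_id == blood and afs[_uid_at(truth, blood, o)] == 0.0:
            assert o.alt_depth == 0


def _uid_at(truth, sample_id, obs):
    donor = truth.donor_of(sample_id)
    for v in donor.all_variants():
        if v.locus == obs.locus:
            return v.uid
    raise AssertionError("observation without truth variant")


def test_detection_rate_matches_binomial_tail():
    # empirical fibroblast detection of mosaic variants tracks 1-(1-f)^c
    config = sm.SimConfig(n_donors=3, seq_error=0.0, seed=9)
    truth, metas = sm.simulate_cohort(config)
    observations = sm.sample_reads(truth)
    detected, expected = [], []
    for m in metas:
        if m.material != "fibroblast":
            continue
        afs = truth.sample_afs(m.sample_id)
        by_locus = {o.locus: o for o in observations if o.sample_id == m.sample_id}
        for v in truth.donors[m.donor_id].subclone_variants:
            o = by_locus[v.locus]
            if o.total_depth == 0:
                continue
            detected.append(o.alt_depth >= 1)
            expected.append(detection_probability(v.fib_af, o.total_depth))
    p_hat, p_model = np.mean(detected), np.mean(expected)
    se = np.sqrt(np.sum(np.array(expected) * (1 - np.array(expected)))) / len(expected)
    assert abs(p_hat - p_model) < 4 * max(se, 1e-9)


def test_clone_picking_is_drift_not_selection():
    # over many reprogramming events, pick frequencies match subclone
    # proportions (chi-square goodness of fit)
    config = sm.SimConfig(
        n_donors=1, n_subclones_per_fibroblast=4, lambda_mosaic=0.5,
        n_germline=0, lambda_passage=0.0, oligoclonal_prob=0.0,
        cnv_lambda=0.0, fibroblast_cnv_lambda=0.0, aneuploidy_prob=0.0,
        vector_snv_lambda=0.0, n_ripsc=1000, n_sipsc=0, n_npc=0, seed=10,
    )
    truth, _ = sm.simulate_cohort(config)
    donor = next(iter(truth.donors.values()))
    counts = np.zeros(4)
    for clone in donor.clones.values():
        counts[clone.picks[0][0]] += 1
    expected = 1000 * donor.subclone_proportions
    result = stats.chisquare(counts, expected)
    assert result.pvalue > 0.01


def test_passage_accrual_poisson_mean():
    config = sm.SimConfig(
        n_donors=1, n_subclones_per_fibroblast=1, lambda_mosaic=0.0,
        n_germline=0, lambda_passage=0.5, oligoclonal_prob=0.0,
        cnv_lambda=0.0, fibroblast_cnv_lambda=0.0, aneuploidy_prob=0.0,
        vector_snv_lambda=0.0, n_ripsc=500, n_sipsc=0, n_npc=0,
        ripsc_passage_range=(10, 11), seed=12,
    )
    truth, _ = sm.simulate_cohort(config)
    donor = next(iter(truth.donors.values()))
    total = sum(len(c.culture_variants) for c in donor.clones.values())
    mean = 500 * 0.5 * 10  # Poisson with mean lambda_passage * passage per clone
    assert abs(total - mean) < 4 * np.sqrt(mean)


def test_emitted_cohort_round_trips_and_is_deterministic(tmp_path):
    config = sm.SimConfig(n_donors=2, seed=13)
    truth, metas = sm.simulate_cohort(config)
    observations = sm.sample_reads(truth)
    d1 = sm.emit_cohort(truth, observations, tmp_path / "run1")

    # conservation: every truth-fixed variant of a clone is in its VCF column
    back = fio.read_multisample_vcf(d1["vcf"], fio.read_sample_metadata(d1["meta"]))
    seen = {(o.sample_id, o.locus) for o in back if o.alt_depth > 0}
    for m in metas:
        if m.material in ("RiPSC", "SiPSC", "NPC"):
            for v in truth.fixed_truth(m.sample_id):
                assert (m.sample_id, v.locus) in seen

    # determinism: a fresh run with the same seed emits identical bytes
    truth2, _ = sm.simulate_cohort(sm.SimConfig(n_donors=2, seed=13))
    obs2 = sm.sample_reads(truth2)
    d2 = sm.emit_cohort(truth2, obs2, tmp_path / "run2")
    for key in d1:
        assert filecmp.cmp(d1[key], d2[key], shallow=False), key

    # a different seed changes the read draws
    truth3, _ = sm.simulate_cohort(sm.SimConfig(n_donors=2, seed=14))
    obs3 = sm.sample_reads(truth3)
    assert [o.alt_depth for o in obs2[:200]] != [o.alt_depth for o in obs3[:200]]


def test_coverage_profiles_encode_material_contrasts(coverage_profiles, cohort):
    truth = cohort["truth"]
    by_sample = {p.sample_id: p for p in coverage_profiles}
    factor = set(sm.FACTOR_GENES)

    def exon_mean(profile, genes):
        ivs = [iv for iv in profile.by_role("exon") if iv.gene in genes]
        return np.mean([iv.mean_depth for iv in ivs])

    ratios = {m: [] for m in ("blood", "fibroblast", "RiPSC", "SiPSC", "NPC")}
    for sample_id, meta in truth.meta.items():
        p = by_sample[sample_id]
        chrm = np.mean([iv.mean_depth for iv in p.by_role("chrM_bin")])
        chr1 = np.mean([iv.mean_depth for iv in p.by_role("chr1_target")])
        ratios[meta.material].append(chrm / chr1)
        panel = exon_mean(p, set(truth.genome.panel_genes))
        fac = exon_mean(p, factor)
        if meta.material == "SiPSC":
            # no integration: factor loci look like the panel
            assert fac / panel < 1.3
        elif meta.material == "RiPSC":
            assert fac / panel > 1.5  # exon-only elevation from inserts
            introns = [iv.mean_depth for iv in p.by_role("intron") if iv.gene in factor]
            assert np.mean(introns) < 0.6 * panel  # introns stay at shoulder
    # material dosage ordering (fibroblast ~ iPSC > NPC > blood) is preserved
    med = {m: np.median(r) for m, r in ratios.items() if r}
    assert med["fibroblast"] > med["NPC"] > med["blood"]
    assert med["RiPSC"] > med["NPC"] and med["SiPSC"] > med["NPC"]
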