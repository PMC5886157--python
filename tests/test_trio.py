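"""Genotype caller and DNM filter cascade behaviour."""
import numpy as np
import pandas as pd
import pytest

from dnmburden import trio
from dnmburden.models import DNMCandidate, MemberObservation, Site, TrioObservation


def obs(child, father, mother, siblings=(), site=None, family="FAM001"):
    return TrioObservation(
        site=site or Site("1", 100, "A", "G"),
        child=MemberObservation(*child),
        father=MemberObservation(*father),
        mother=MemberObservation(*mother),
        siblings=[MemberObservation(*s) for s in siblings],
        family_id=family,
    )


class TestGenotypeCaller:
    def test_balanced_child_clean_parents_call_de_novo_pattern(self):
        o = obs((15, 15), (30, 0), (28, 0))
        calls = trio.call_trio_genotypes(o, eps=0.01)
        assert calls["child"][0] == 1
        assert calls["child"][1] > 0.99
        assert calls["father"][0] == 0 and calls["mother"][0] == 0

    def test_all_reference_child_is_hom_ref(self):
        o = obs((30, 0), (30, 0), (30, 0))
        calls = trio.call_trio_genotypes(o, eps=0.01)
        assert calls["child"][0] == 0

    def test_zero_depth_member_is_no_call_and_blocks_pattern(self):
        o = obs((15, 15), (0, 0), (30, 0))
        calls = trio.call_trio_genotypes(o, eps=0.01)
        assert calls["father"][0] is None
        ok, reason = trio.denovo_pattern_filter(calls["child"][0], calls["father"][0],
                                                calls["mother"][0])
        assert not ok and reason == "uncallable"

    def test_posterior_matches_direct_binomial_computation(self):
        # independent oracle: explicit Bayes over binomial likelihoods
        from scipy.stats import binom

        eps, ref_c, alt_c = 0.01, 12, 9
        priors = trio.default_priors()
        lik = np.array([binom.pmf(alt_c, ref_c + alt_c, t) for t in (eps, 0.5, 1 - eps)])
        expected = lik * priors / (lik * priors).sum()
        post = trio.genotype_posterior(ref_c, alt_c, eps)
        np.testing.assert_allclose(post, expected, rtol=1e-10)

    def test_hom_alt_child_called(self):
        post = trio.genotype_posterior(0, 30, eps=0.01, priors=trio.hwe_priors(0.3))
        assert int(np.argmax(post)) == 2


@pytest.mark.parametrize("gts,expected", [
    ((1, 0, 0), True),
    ((1, 1, 0), False),   # inherited
    ((2, 0, 0), False),   # pattern requires a het child
    ((0, 0, 0), False),
    ((1, 0, 2), False),
])
def test_denovo_pattern_filter(gts, expected):
    ok, _ = trio.denovo_pattern_filter(*gts)
    assert ok is expected


class TestParentalTrace:
    def test_clean_parents_pass(self):
        assert trio.parental_trace_filter(obs((15, 15), (30, 0), (28, 0)))[0]

    def test_single_alt_read_is_a_trace(self):
        ok, reason = trio.parental_trace_filter(obs((15, 15), (29, 1), (28, 0)))
        assert not ok and reason == "parental alt trace"

    def test_zero_depth_parents_are_not_zero_trace_evidence(self):
        ok, reason = trio.parental_trace_filter(obs((15, 15), (0, 0), (0, 0)))
        assert not ok and reason == "no depth data"


@pytest.mark.parametrize("gene,nepg,expected", [
    ("GENE001", {"GENE001"}, False),
    (None, {"GENE001"}, True),      # intergenic passes
    ("GENE002", set(), True),       # empty list is the identity filter
])
def test_nepg_filter(gene, nepg, expected):
    assert trio.nepg_filter(gene, nepg)[0] is expected


@pytest.mark.parametrize("csq,expected", [
    ("missense", True), ("stop_gain", True), ("splice", True),
    ("frameshift", True), ("synonymous", False), ("utr", False),
    ("intronic", False), (None, False), (float("nan"), False),
])
def test_nonsilent_filter(csq, expected):
    assert trio.nonsilent_filter(csq)[0] is expected


def _four_site_fixture():
    """One NEPG-gene variant, one parental-trace variant, one synonymous,
    one clean missense DNM."""
    sites = [Site("1", p, "A", "G") for p in (100, 200, 300, 400)]
    observations = [
        obs((15, 15), (30, 0), (30, 0), site=sites[0]),            # NEPG gene
        obs((15, 15), (29, 1), (30, 0), site=sites[1]),            # parent trace
        obs((15, 15), (30, 0), (30, 0), site=sites[2]),            # synonymous
        obs((15, 15), (30, 0), (30, 0), site=sites[3]),            # clean DNM
    ]
    annotation = pd.DataFrame([
        {"chrom": "1", "pos": 100, "ref": "A", "alt": "G", "gene": "NEPG1",
         "consequence": "missense", "maf": np.nan},
        {"chrom": "1", "pos": 200, "ref": "A", "alt": "G", "gene": "CLEAN1",
         "consequence": "missense", "maf": np.nan},
        {"chrom": "1", "pos": 300, "ref": "A", "alt": "G", "gene": "CLEAN2",
         "consequence": "synonymous", "maf": np.nan},
        {"chrom": "1", "pos": 400, "ref": "A", "alt": "G", "gene": "CLEAN3",
         "consequence": "missense", "maf": np.nan},
    ])
    return observations, annotation


class TestCascade:
    def test_four_site_fixture_one_rejection_per_stage(self):
        observations, annotation = _four_site_fixture()
        cands, report = trio.run_filter_cascade(observations, annotation,
                                                nepg_genes=["NEPG1"], eps=0.01)
        survivors = [c for c in cands if c.final_status == "candidate"]
        assert len(survivors) == 1
        assert survivors[0].site.pos == 400
        assert [s["n_in"] - s["n_out"] for s in report.stages] == [1, 1, 1]

    def test_empty_input(self):
        cands, report = trio.run_filter_cascade([], pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene", "consequence", "maf"]),
            nepg_genes=[], eps=0.01)
        assert cands == [] and report.n_input == 0
        assert all(s["n_in"] == 0 for s in report.stages)

    def test_counts_monotone_non_increasing(self, small_observations, small_trio_sim):
        _, report = trio.run_filter_cascade(
            small_observations, small_trio_sim.annotation,
            small_trio_sim.nepg_genes, eps=small_trio_sim.config.seq_error)
        ns = [report.n_input] + [s["n_out"] for s in report.stages]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_rejected_sites_never_resurrect(self, small_observations, small_trio_sim):
        cands, report = trio.run_filter_cascade(
            small_observations, small_trio_sim.annotation,
            small_trio_sim.nepg_genes, eps=small_trio_sim.config.seq_error)
        survivors = {(str(c.site), c.family_id) for c in cands
                     if c.final_status == "candidate"}
        rejected = {(str(c.site), c.family_id) for c in cands
                    if c.final_status == "rejected"}
        assert not survivors & rejected

    def test_noiseless_recovery_sensitivity_one_and_no_inherited(
            self, noiseless_observations, noiseless_trio_sim):
        sim = noiseless_trio_sim
        cands, _ = trio.run_filter_cascade(noiseless_observations, sim.annotation,
                                           sim.nepg_genes, eps=0.0)
        truth = {t.site_id: t.truth_class for t in sim.truth}
        survivors = [c for c in cands if c.final_status == "candidate"]
        got = {str(c.site) for c in survivors}
        true_dnms = {t.site_id for t in sim.truth if t.truth_class == "true_dnm"}
        assert true_dnms <= got                       # sensitivity 1
        assert all(truth[str(c.site)] != "inherited" for c in survivors)

    def test_noise_does_not_increase_surviving_true_dnms(self):
        """More sequencing error can only lose true DNMs (parental traces)."""
        from dnmburden.synthetic import TrioSimConfig, simulate_trios

        surv_counts = []
        for eps in (0.0, 0.02):
            sim = simulate_trios(TrioSimConfig(n_trios=20, seq_error=eps,
                                               n_background_sites=60, seed=77))
            observations = _observations_in_memory(sim)
            cands, _ = trio.run_filter_cascade(observations, sim.annotation,
                                               sim.nepg_genes, eps=eps)
            truth = {t.site_id: t.truth_class for t in sim.truth}
            surv_counts.append(sum(truth[str(c.site)] == "true_dnm"
                                   for c in cands if c.final_status == "candidate"))
        assert surv_counts[1] <= surv_counts[0]


def _observations_in_memory(sim):
    """Build observations straight from simulated records (no file round trip)."""
    from dnmburden.io import _family_structure

    fams = _family_structure(sim.ped)
    out = []
    for rec in sim.site_records:
        site = Site(str(rec["chrom"]), rec["pos"], rec["ref"], rec["alt"])
        for fam_id, fam in fams.items():
            def m(s):
                _gt, r, a = rec["calls"][s]
                return MemberObservation(r, a)
            out.append(TrioObservation(site=site, child=m(fam["child"]),
                                       father=m(fam["father"]), mother=m(fam["mother"]),
                                       siblings=[m(s) for s in fam["siblings"]],
                                       family_id=fam_id))
    return out


class TestFalsePositiveFlags:
    def _candidate(self, gene="GENE1", pos=100):
        c = DNMCandidate(site=Site("1", pos, "A", "G"), family_id="FAM001", gene=gene,
                         nepg_pass=True, denovo_pattern_pass=True,
                         parental_trace_pass=True, nonsilent_pass=True)
        return c

    def test_sibling_carrying_allele_flags_mosaic(self):
        o = obs((15, 15), (30, 0), (30, 0), siblings=[(14, 16)])
        trio.call_trio_genotypes(o, eps=0.01)
        c = trio.flag_false_positive_modes(self._candidate(), o)
        assert c.mosaic

    def test_no_sibling_means_unflagged(self):
        o = obs((15, 15), (30, 0), (30, 0))
        trio.call_trio_genotypes(o, eps=0.01)
        assert not trio.flag_false_positive_modes(self._candidate(), o).mosaic

    def test_paralog_map_drives_psv_flag(self):
        o = obs((15, 15), (30, 0), (30, 0))
        trio.call_trio_genotypes(o, eps=0.01)
        pmap = {"GENE1": {"paralog": "GENE1B", "positions": [100]}}
        assert trio.flag_false_positive_modes(self._candidate(), o, pmap).psv_suspect
        assert not trio.flag_false_positive_modes(
            self._candidate(gene="OTHER"), o, pmap).psv_suspect

    def test_mosaics_flagged_on_noiseless_simulation(
            self, noiseless_observations, noiseless_trio_sim):
        sim = noiseless_trio_sim
        cands, _ = trio.run_filter_cascade(noiseless_observations, sim.annotation,
                                           sim.nepg_genes, eps=0.0)
        by_key = {(o.site.key, o.family_id): o for o in noiseless_observations}
        survivors = [c for c in cands if c.final_status == "candidate"]
        for c in survivors:
            trio.flag_false_positive_modes(c, by_key[(c.site.key, c.family_id)])
        mosaic_ids = {t.site_id for t in sim.truth if t.truth_class == "mosaic"}
        assert mosaic_ids, "fixture should contain mosaic events"
        flagged = {str(c.site) for c in survivors if c.mosaic}
        assert mosaic_ids <= flagged


class TestCaseOnlyScan:
    def test_zero_threshold_finds_nothing(self, small_observations, small_trio_sim):
        out = trio.case_only_scan(small_observations, small_trio_sim.annotation,
                                  maf_threshold=0.0)
        assert out == {"n_variants": 0, "n_genes": 0}

    def test_all_synonymous_finds_nothing(self):
        observations, annotation = _four_site_fixture()
        annotation["consequence"] = "synonymous"
        out = trio.case_only_scan(observations, annotation, maf_threshold=0.01, eps=0.01)
        assert out["n_variants"] == 0

    def test_scan_dwarfs_trio_cascade(self, small_observations, small_trio_sim):
        sim = small_trio_sim
        scan = trio.case_only_scan(small_observations, sim.annotation,
                                   maf_threshold=0.01, eps=sim.config.seq_error)
        cands, report = trio.run_filter_cascade(small_observations, sim.annotation,
                                                sim.nepg_genes,
                                                eps=sim.config.seq_error)
        assert scan["n_variants"] > report.n_survivors
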