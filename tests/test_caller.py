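import numpy as np
import pytest

from rips import (
    SimParams,
    StopPileup,
    call_sites,
    enrichment_ratio,
    map_reads,
    pileup,
    profile,
    simulate_library,
    standin_oligo,
    termination_rate,
)
from rips.caller import CallerError


def make_pileup(stop5, ref_id="ref"):
    stop5 = np.asarray(stop5, dtype=np.int64)
    return StopPileup(ref_id, len(stop5), stop5, np.cumsum(stop5),
                      n_mapped=int(stop5.sum()))


def arm_profile(template, params, arm, min_cov=50, rng=None):
    reads, _ = simulate_library([template], params, arm, rng)
    pu = pileup(map_reads(reads, [template]), template)
    return profile(pu, min_cov=min_cov, arm=arm)


class TestTerminationRate:
    def test_ratio_of_stops_to_informative_reads(self):
        stop5 = [0, 0, 45, 55, 0, 0]  # 45 read-throughs past site 3, 55 stops at 4
        assert termination_rate(make_pileup(stop5), 3, min_cov=10) == pytest.approx(0.55)

    def test_zero_stops_gives_zero_rate(self):
        assert termination_rate(make_pileup([100, 0, 0, 0]), 1, min_cov=10) == 0.0

    def test_thin_coverage_returns_missing(self):
        assert termination_rate(make_pileup([10, 5, 0, 0]), 1, min_cov=50) is None

    def test_last_position_has_no_threeprime_neighbor(self):
        with pytest.raises(CallerError):
            termination_rate(make_pileup([1, 1, 1]), 3)

    def test_rate_invariant_to_threeprime_truncation(self):
        # reads stopping 5' of the site don't enter the denominator
        base = make_pileup([40, 0, 10, 90, 0, 0])
        truncated = make_pileup([40, 0, 10, 90, 500, 0])  # extra stops 3' of site
        s = 3
        assert termination_rate(base, s, 10) == termination_rate(truncated, s, 10)

    def test_cmc_only_rate_composes_labeling_and_stop_probability(self, oligo60):
        # T(Ψ) ~ p_label_ss * p_rt_stop when background stops are off
        p = SimParams(p_label_ss=0.7, p_rt_stop=0.85, p_bg_stop=0.0,
                      seq_error=0.0, n_molecules=20000, seed=23)
        prof = arm_profile(oligo60, p, "cmc_only")
        expect = 0.7 * 0.85
        se = np.sqrt(expect * (1 - expect) / prof.denominator(30))
        assert abs(prof.rate_at(30) - expect) < 3 * se


class TestProfile:
    def test_rates_defined_only_where_covered(self):
        prof = profile(make_pileup([100, 0, 3, 1, 0]), min_cov=50)
        assert np.isfinite(prof.rate[0])
        assert prof.rate_at(1) == 0.0
        assert len(prof.rate) == 4  # last position has no rate

    def test_rates_bounded(self, oligo60):
        prof = arm_profile(oligo60, SimParams(n_molecules=3000, seed=29), "cmc_xrn1")
        finite = prof.rate[np.isfinite(prof.rate)]
        assert ((finite >= 0) & (finite <= 1)).all()


class TestCallSites:
    def test_flat_treated_profile_yields_no_calls(self):
        quiet = profile(make_pileup([1000] + [0] * 59), min_cov=50)
        assert call_sites(quiet, quiet) == []

    def test_single_call_at_the_psi_position(self, oligo60):
        p = SimParams(n_molecules=20000, seed=31)
        rng = np.random.default_rng
        treated = arm_profile(oligo60, p, "cmc_xrn1", rng=rng(1))
        control = arm_profile(oligo60, p, "cmc_only", rng=rng(2))
        inp = arm_profile(oligo60, p, "input", rng=rng(3))
        calls = call_sites(treated, control, inp)
        assert [c.site for c in calls] == [30]
        c = calls[0]
        assert c.T_treated > 0.55 and c.T_control < 0.30
        assert c.delta > 0.1 and c.snr > 1 and c.pvalue < 1e-6

    def test_doublet_without_collapse_shows_fragment_start_artifact(self, oligo60):
        p = SimParams(n_molecules=20000, seed=31)
        rng = np.random.default_rng
        treated = arm_profile(oligo60, p, "cmc_xrn1", rng=rng(1))
        control = arm_profile(oligo60, p, "cmc_only", rng=rng(2))
        raw = call_sites(treated, control, collapse_adjacent=False)
        assert [c.site for c in raw] == [29, 30]
        merged = call_sites(treated, control)
        assert len(merged) == 1 and merged[0].merged_sites == (29, 30)

    def test_duplex_blocked_psi_is_not_called(self):
        ds = standin_oligo("ds", 60, 30, seed=33).with_mask([True] * 60)
        p = SimParams(n_molecules=20000, seed=35)
        rng = np.random.default_rng
        treated = arm_profile(ds, p, "cmc_xrn1", rng=rng(4))
        control = arm_profile(ds, p, "cmc_only", rng=rng(5))
        assert call_sites(treated, control) == []

    def test_intrinsic_input_stop_vetoes_the_call(self):
        treated = profile(make_pileup([0, 0, 30, 70, 0]), min_cov=50)
        control = profile(make_pileup([0, 0, 95, 5, 0]), min_cov=50)
        noisy_input = profile(make_pileup([0, 0, 40, 60, 0]), min_cov=50)
        assert [c.site for c in call_sites(treated, control)] == [3]
        assert call_sites(treated, control, noisy_input) == []

    def test_mismatched_references_rejected(self):
        a = profile(make_pileup([10, 0, 0], ref_id="a"))
        b = profile(make_pileup([10, 0, 0], ref_id="b"))
        with pytest.raises(CallerError):
            call_sites(a, b)

    def test_psi_free_template_produces_no_false_positives(self):
        # specificity spot-check over a handful of seeds (low background)
        from rips import RnaTemplate

        t = RnaTemplate("flat", ("ACG" * 20))
        for seed in range(5):
            p = SimParams(p_bg_stop=0.01, n_molecules=5000, seed=seed)
            rng = np.random.default_rng
            treated = arm_profile(t, p, "cmc_xrn1", rng=rng(seed))
            control = arm_profile(t, p, "cmc_only", rng=rng(seed + 100))
            assert call_sites(treated, control) == []


class TestEnrichment:
    def test_degraded_reference_cedes_its_share(self):
        pre = [make_pileup([50, 0], "psi"), make_pileup([50, 0], "plain")]
        post = [make_pileup([50, 0], "psi"), make_pileup([0, 0], "plain")]
        df = enrichment_ratio(pre, post).set_index("ref")
        assert df.loc["psi", "post_share"] == pytest.approx(1.0)
        assert df.loc["psi", "fold_change"] == pytest.approx(2.0)

    def test_no_digestion_leaves_shares_unchanged(self, oligo32, oligo60):
        p = SimParams(p_engage=0.0, n_molecules=2000, seed=37)
        rng = np.random.default_rng
        pres, posts = [], []
        for arm, bucket, r in (("cmc_only", pres, rng(6)), ("cmc_xrn1", posts, rng(6))):
            reads, _ = simulate_library([oligo32, oligo60], p, arm, r)
            alns = map_reads(reads, [oligo32, oligo60])
            bucket.extend(pileup(alns, t) for t in (oligo32, oligo60))
        df = enrichment_ratio(pres, posts)
        assert np.allclose(df["fold_change"], 1.0, atol=0.05)

    def test_mixture_enriches_the_single_stranded_template(self, oligo32):
        ds60 = standin_oligo("ds60", 60, 30, seed=39).with_mask([True] * 60)
        p = SimParams(n_molecules=4000, seed=41)
        rng = np.random.default_rng
        pres, posts = [], []
        for arm, bucket, r in (("cmc_only", pres, rng(7)), ("cmc_xrn1", posts, rng(8))):
            reads, _ = simulate_library([oligo32, ds60], p, arm, r)
            alns = map_reads(reads, [oligo32, ds60])
            bucket.extend(pileup(alns, t) for t in (oligo32, ds60))
        df = enrichment_ratio(pres, posts).set_index("ref")
        assert df.loc["o32", "post_share"] > df.loc["o32", "pre_share"]
        assert df.loc["o32", "post_share"] > 0.9
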