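import math

import numpy as np
import pytest

from hybridpanel import (
    binomial_randomness_test,
    default_panel,
    fis_weir_cockerham_locus,
    hwe_exact_locus,
    loci_examined_for_site,
    site_allele_percentages,
    site_hwe,
    summarize_site,
    swarm_classification,
)
from hybridpanel.model import MISSING, TAXON_INDEX
from hybridpanel.swarm import CONSISTENT_Y, NOT_APPLICABLE, REJECTED_N, hwp_site_criterion
from hybridpanel import sim

from conftest import f1_calls, make_record, parental_calls


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent enumeration of the conditional heterozygote-count
    distribution using exact integer arithmetic."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    if nA == 0 or na == 0:
        return 1.0, 1.0
    weights = {}
    for h in range(nA % 2, min(nA, na) + 1, 2):
        aa = (nA - h) // 2
        bb = (na - h) // 2
        weights[h] = (
            2**h * math.factorial(n) // (math.factorial(aa) * math.factorial(h) * math.factorial(bb))
        )
    total = sum(weights.values())
    p_def = sum(w for h, w in weights.items() if h <= n_Aa) / total
    p_exc = sum(w for h, w in weights.items() if h >= n_Aa) / total
    return p_def, p_exc


class TestSitePercentages:
    def test_two_parentals_plus_f1(self, panel):
        """2 parental WCT + 1 F1: WCT share = (2*136 + 68) / (3*136)."""
        records = [
            make_record(parental_calls(panel, "WCT"), panel, "p1"),
            make_record(parental_calls(panel, "WCT"), panel, "p2"),
            make_record(f1_calls(panel, "WCT", "RT"), panel, "h1"),
        ]
        pcts = site_allele_percentages(records, panel)
        assert pcts["WCT"] == pytest.approx(100 * (2 * 136 + 68) / (3 * 136))
        assert pcts["YCT"] == 0.0

    def test_all_parental_site(self, panel):
        records = [make_record(parental_calls(panel, "WCT"), panel, f"p{i}") for i in range(5)]
        pcts = site_allele_percentages(records, panel)
        assert pcts == {"WCT": 100.0, "RT": 0.0, "YCT": 0.0}

    def test_three_taxon_site_matches_weighted_mean(self, panel):
        from hybridpanel import estimate_admixture

        rng = np.random.default_rng(21)
        records = []
        for i in range(8):
            q = rng.dirichlet([3, 2, 1])
            calls = rng.binomial(2, q[panel.taxon_of]).astype(np.int8)
            calls[rng.random(panel.n_nuclear) < 0.1] = MISSING
            records.append(make_record(calls, panel, f"f{i}"))
        taxa_union = set()
        from hybridpanel import taxa_present

        for r in records:
            taxa_union |= set(taxa_present(r, panel))
        if len(taxa_union) < 3:
            pytest.skip("rng draw did not produce a three-taxon site")
        pcts = site_allele_percentages(records, panel)
        ests = [estimate_admixture(r, panel) for r in records]
        w = np.array([e.alleles_counted for e in ests], dtype=float)
        expected = (np.vstack([e.q for e in ests]) * w[:, None]).sum(axis=0) / w.sum() * 100
        for i, t in enumerate(("WCT", "RT", "YCT")):
            assert pcts[t] == pytest.approx(expected[i])


class TestLociExamined:
    def test_pair_panel_sizes(self, panel):
        wr = [
            make_record(f1_calls(panel, "WCT", "RT"), panel, "a"),
            make_record(parental_calls(panel, "WCT"), panel, "b"),
        ]
        assert loci_examined_for_site(wr, panel) == 68
        wy = [make_record(f1_calls(panel, "WCT", "YCT"), panel, "a")]
        assert loci_examined_for_site(wy, panel) == 53
        calls = f1_calls(panel, "WCT", "RT")
        calls[np.flatnonzero(panel.taxon_of == TAXON_INDEX["YCT"])[0]] = 1
        three = [make_record(calls, panel, "a")]
        assert loci_examined_for_site(three, panel) == 86

    def test_no_admixed_fish_returns_none(self, panel):
        recs = [make_record(parental_calls(panel, "WCT"), panel, "a")]
        assert loci_examined_for_site(recs, panel) is None


class TestBinomialTest:
    def test_zero_statistic(self, panel):
        """Ten identical F1-like fish sit exactly at the sample
        proportion, so the dispersion statistic is 0 and p = 1."""
        records = [make_record(f1_calls(panel, "WCT", "RT"), panel, f"f{i}") for i in range(10)]
        res = binomial_randomness_test(records, panel, B=500, seed=4)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == 1.0
        assert res.decision == CONSISTENT_Y

    def test_parental_mixture_rejected(self, panel):
        """Parental WCT and RT plus two admixed fish: the bimodal allele
        distribution is maximally overdispersed and must be rejected."""
        records = [make_record(parental_calls(panel, "WCT"), panel, f"w{i}") for i in range(5)]
        records += [make_record(parental_calls(panel, "RT"), panel, f"r{i}") for i in range(5)]
        records += [make_record(f1_calls(panel, "WCT", "RT"), panel, f"h{i}") for i in range(2)]
        res = binomial_randomness_test(records, panel, B=2000, seed=5)
        assert res.decision == REJECTED_N
        assert res.p_value < 0.001
        res2 = binomial_randomness_test(records, panel, B=2000, seed=5)
        assert res2.p_value == res.p_value  # seed-stable

    def test_small_samples_and_pure_sites_not_analyzed(self, panel):
        few = [make_record(f1_calls(panel, "WCT", "RT"), panel, f"f{i}") for i in range(9)]
        assert binomial_randomness_test(few, panel).decision == NOT_APPLICABLE
        pure = [make_record(parental_calls(panel, "WCT"), panel, f"p{i}") for i in range(12)]
        assert binomial_randomness_test(pure, panel).decision == NOT_APPLICABLE

    def test_null_rejection_rate_nominal(self, panel):
        """Size check at reduced scale (full 500-site version in the
        acceptance suite)."""
        rej = 0
        n_sites = 120
        for seed in range(n_sites):
            recs, _ = sim.scenario("swarm", panel, seed=seed, generations=5, p0=0.3,
                                   population_size=400, n=30)
            r = binomial_randomness_test(recs, panel, B=400, seed=seed + 10**6)
            if r.decision == REJECTED_N:
                rej += 1
        rate = rej / n_sites
        band = 3 * np.sqrt(0.05 * 0.95 / n_sites)
        assert abs(rate - 0.05) <= band + 0.02


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts",
        [(5, 0, 5), (0, 10, 0), (3, 4, 3), (1, 1, 1), (12, 5, 0), (2, 9, 8)],
    )
    def test_matches_integer_enumeration_oracle(self, counts):
        got = hwe_exact_locus(*counts)
        expected = hwe_oracle(*counts)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_monomorphic_never_significant(self):
        assert hwe_exact_locus(10, 0, 0) == (1.0, 1.0)
        assert hwe_exact_locus(0, 0, 7) == (1.0, 1.0)

    def test_tails_overlap_correctly(self):
        # one-sided tails both include the observed state
        p_def, p_exc = hwe_exact_locus(5, 0, 5)
        assert p_def < 0.01  # no hets among 10 fish at p=0.5 is extreme
        assert p_exc == pytest.approx(1.0)

    def test_distribution_sums_to_one(self):
        # complementary tails: P(h <= obs) + P(h >= obs) - P(obs) = 1
        for counts in [(4, 3, 6), (7, 7, 1), (0, 2, 11)]:
            p_def, p_exc = hwe_exact_locus(*counts)
            n = sum(counts)
            # P(obs) via the oracle weights
            import math as m

            nA = 2 * counts[0] + counts[1]
            na = 2 * n - nA
            weights = {}
            for h in range(nA % 2, min(nA, na) + 1, 2):
                aa, bb = (nA - h) // 2, (na - h) // 2
                weights[h] = 2**h * m.factorial(n) // (
                    m.factorial(aa) * m.factorial(h) * m.factorial(bb)
                )
            p_obs = weights[counts[1]] / sum(weights.values())
            assert p_def + p_exc - p_obs == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_permutation_oracle(self):
        """Shuffle the 2n alleles into diploids and compare the exact
        deficit tail with its Monte-Carlo frequency."""
        n_AA, n_Aa, n_aa = 5, 2, 5
        p_def, _ = hwe_exact_locus(n_AA, n_Aa, n_aa)
        n = n_AA + n_Aa + n_aa
        alleles = np.array([1] * (2 * n_AA + n_Aa) + [0] * (2 * n_aa + n_Aa))
        rng = np.random.default_rng(3)
        hits = 0
        B = 4000
        for _ in range(B):
            rng.shuffle(alleles)
            hets = int((alleles[::2] != alleles[1::2]).sum())
            if hets <= n_Aa:
                hits += 1
        mc = hits / B
        assert p_def == pytest.approx(mc, abs=4 * np.sqrt(mc * (1 - mc) / B))


class TestFis:
    def test_all_heterozygotes_is_minus_one(self):
        f, _, _ = fis_weir_cockerham_locus(0, 10, 0)
        assert f == pytest.approx(-1.0)

    def test_hw_proportions_large_sample_near_zero(self):
        # 10000 fish at p=0.5 in exact HW proportions
        f, _, _ = fis_weir_cockerham_locus(2500, 5000, 2500)
        assert abs(f) < 0.001

    def test_monomorphic_undefined(self):
        f, b, c = fis_weir_cockerham_locus(9, 0, 0)
        assert f is None and b == 0.0 and c == 0.0

    def test_matches_textbook_formula(self):
        """Direct Weir-Cockerham components recomputed symbol by symbol."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            counts = rng.multinomial(n, [0.3, 0.4, 0.3])
            n_AA, n_Aa, n_aa = map(int, counts)
            p = (2 * n_AA + n_Aa) / (2 * n)
            if p in (0.0, 1.0):
                continue
            h = n_Aa / n
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            f, bg, cg = fis_weir_cockerham_locus(n_AA, n_Aa, n_aa)
            assert f == pytest.approx(1 - c / (b + c))
            assert bg == pytest.approx(b) and cg == pytest.approx(c)


class TestHwpCriterion:
    @pytest.mark.parametrize(
        "n_def,n_exc,loci,expected",
        [
            (3, 0, 68, False),  # 3 <= 3.4
            (4, 0, 68, True),  # 4 > 3.4
            (0, 4, 68, True),  # excess side counts too
            (5, 0, 86, True),  # 5 > 4.3
            (4, 0, 86, False),
            (2, 0, 53, False),
            (3, 1, 53, True),
        ],
    )
    def test_threshold_arithmetic(self, n_def, n_exc, loci, expected):
        res = hwp_site_criterion(n_def, n_exc, loci)
        assert res.out_of_hwp is expected


class TestSwarmClassification:
    def test_parental_fish_vetoes_swarm(self, panel):
        records = [make_record(parental_calls(panel, "WCT"), panel, "p0")]
        records += [make_record(f1_calls(panel, "WCT", "RT"), panel, f"h{i}") for i in range(11)]
        s = summarize_site("x", records, panel, B=300, seed=1)
        assert s.parental_counts["WCT"] == 1
        assert not s.is_swarm

    def test_parental_mixture_is_not_swarm(self, panel):
        records = [make_record(parental_calls(panel, "WCT"), panel, f"w{i}") for i in range(6)]
        records += [make_record(parental_calls(panel, "RT"), panel, f"r{i}") for i in range(4)]
        records += [make_record(f1_calls(panel, "WCT", "RT"), panel, f"h{i}") for i in range(2)]
        s = summarize_site("x", records, panel, B=1000, seed=2)
        assert not s.is_swarm
        assert s.swarm_test.decision == REJECTED_N

    def test_na_binomial_blocks_swarm_call(self, panel):
        records = [make_record(f1_calls(panel, "WCT", "RT"), panel, f"h{i}") for i in range(5)]
        s = summarize_site("x", records, panel, B=300, seed=3)
        assert s.swarm_test.decision == NOT_APPLICABLE
        assert not s.is_swarm

    def test_simulated_swarms_usually_classified_as_swarms(self, panel):
        """Random-mating swarm sites should pass the full battery at
        roughly (1 - alpha) x HWP pass rate; check > 0.75 at this scale
        (the larger replication lives in the acceptance suite)."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            recs, _ = sim.scenario("swarm", panel, seed=seed + 500, generations=10, p0=0.3,
                                   population_size=500, n=30)
            s = summarize_site("swarm", recs, panel, B=500, seed=seed)
            if s.is_swarm:
                hits += 1
        assert hits / n_rep > 0.75
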