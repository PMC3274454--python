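import numpy as np
import pytest

from regassoc.burden import (
    BurdenGroup,
    assign_groups,
    bonferroni_threshold,
    wss_permutation_p,
    wss_statistic,
)
from regassoc.simulate import CohortSimConfig, RareVariantSpec, simulate_cohort

from .oracles import wss_exact_p, wss_rank_sum


class TestGroups:
    def test_fixture_group_sizes(self, recon, recon_rarity):
        _, _, records = recon
        groups = assign_groups(records, recon_rarity)
        sizes = {name: len(v) for name, v in groups.items()}
        assert sizes == {
            "5' Regulatory": 8,
            "All Coding": 21,
            "Non-synonymous": 15,
            "Predicted deleterious": 10,
            "3' UTR": 4,
            "All Rare": 38,
        }

    def test_deleterious_subset_of_nonsyn(self, recon, recon_rarity):
        _, _, records = recon
        groups = assign_groups(records, recon_rarity)
        assert set(groups["Predicted deleterious"]) <= set(groups["Non-synonymous"])
        assert set(groups["Non-synonymous"]) <= set(groups["All Coding"])

    def test_empty_predicate(self, recon, recon_rarity):
        _, _, records = recon
        g = BurdenGroup("none", frozenset({"downstream"}), frozenset({"benign"}))
        with pytest.raises(ValueError):
            BurdenGroup("bad", frozenset({"exonic"}))
        # downstream variants have no deleteriousness class -> empty group
        out = assign_groups(records, recon_rarity, [g])
        assert out["none"] == []

    def test_missing_rarity_errors(self, recon):
        _, _, records = recon
        with pytest.raises(ValueError):
            assign_groups(records, {})


class TestStatistic:
    def test_hand_worked_example(self):
        """N=6, one variant, 2 case het carriers, no control carriers."""
        D = np.array([[1.0], [1.0], [0.0], [0.0], [0.0], [0.0]])
        is_case = np.arange(6) < 3
        x, scores = wss_statistic(D, is_case)
        q = 1 / 8
        w = np.sqrt(6 * q * (1 - q))
        assert scores[0] == pytest.approx(1 / w)  # ~1.2345
        assert x == pytest.approx(5.5 + 5.5 + 2.5)

    def test_no_carriers_pure_midrank(self):
        D = np.zeros((10, 3))
        x, _ = wss_statistic(D, np.arange(10) < 4)
        assert x == pytest.approx(4 * 11 / 2)

    def test_identical_hets_all_tied(self):
        D = np.ones((8, 2))
        x, _ = wss_statistic(D, np.arange(8) < 3)
        assert x == pytest.approx(3 * 9 / 2)

    def test_matches_independent_rederivation(self):
        rng = np.random.default_rng(3)
        D = rng.choice([0.0, 1.0], size=(30, 5), p=[0.9, 0.1])
        D[rng.random(D.shape) < 0.1] = np.nan
        is_case = rng.permutation(np.arange(30) < 12)
        x, _ = wss_statistic(D, is_case)
        assert x == pytest.approx(wss_rank_sum(D, is_case), rel=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wss_statistic(np.zeros((4, 0)), np.array([1, 1, 0, 0], bool))
        with pytest.raises(ValueError):
            wss_statistic(np.zeros((4, 1)), np.array([1, 1, 1, 1], bool))


class TestPermutationP:
    def test_exact_enumeration_small_n(self):
        """Permutation estimate agrees with the all-assignments oracle."""
        D = np.array([[1.0], [1.0], [0.0], [0.0], [0.0], [0.0]])
        is_case = np.array([True, True, True, False, False, False])
        exact = wss_exact_p(D, is_case)
        assert exact == pytest.approx(4 / 20)
        res = wss_permutation_p(D, is_case, k=4000, seed=1)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.empirical_p - exact) < 3 * se + 1 / 4000

    def test_exact_enumeration_two_variants(self):
        rng = np.random.default_rng(7)
        D = np.zeros((8, 2))
        D[[0, 3], 0] = 1.0
        D[[1, 4, 6], 1] = 1.0
        is_case = np.arange(8) < 4
        exact = wss_exact_p(D, is_case)
        res = wss_permutation_p(D, is_case, k=6000, seed=2)
        se = np.sqrt(exact * (1 - exact) / 6000)
        assert abs(res.empirical_p - exact) < 3 * se + 1 / 6000

    def test_p_never_below_plus_one_floor(self):
        D = np.zeros((12, 1))
        D[:3] = 1.0
        is_case = np.arange(12) < 3  # maximally case-enriched
        res = wss_permutation_p(D, is_case, k=200, seed=0)
        assert res.empirical_p >= 1 / 201

    def test_allele_totals_reported(self, recon, recon_rarity):
        gm, phen, records = recon
        groups = assign_groups(records, recon_rarity)
        idx = [gm.variant_ids.index(v) for v in groups["5' Regulatory"]]
        res = wss_permutation_p(
            gm.dosages[:, idx], phen.is_case, k=10, seed=0,
            group_name="5' Regulatory",
        )
        assert (res.case_alleles, res.control_alleles) == (10, 1)

    def test_type_one_error_calibration(self):
        """Null cohorts reject at ~5%: fraction in [0.03, 0.07] over 500."""
        spec = [
            RareVariantSpec(f"v{i}", "promoter", case_prob=0.05, control_prob=0.05)
            for i in range(8)
        ]
        hits = 0
        for rep in range(500):
            cfg = CohortSimConfig(
                n_case=40, n_control=40,
                haplotype_pool=[("0", 0.6), ("1", 0.4)],
                rare_spec=spec, missing_rate=0.02, seed=20_000 + rep,
            )
            gm, phen, _ = simulate_cohort(cfg)
            p = wss_permutation_p(
                gm.dosages[:, 1:], phen.is_case, k=499, seed=rep
            ).empirical_p
            hits += p < 0.05
        assert 0.03 <= hits / 500 <= 0.07


class TestBonferroni:
    def test_published_setting(self):
        assert bonferroni_threshold(0.05, 6) == pytest.approx(0.05 / 6)
        assert round(bonferroni_threshold(0.05, 6), 3) == 0.008

    def test_trivial_cases(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.10, 4) == 0.025
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
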