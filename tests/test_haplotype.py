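import itertools

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from regassoc.haplotype import (
    HaplotypeBlock,
    em_haplotype_freqs,
    empirical_p_familywise,
    gabriel_blocks,
    haplotype_association,
    pairwise_ld,
)
from regassoc.simulate import CohortSimConfig, simulate_cohort, table3_pool

from .oracles import em_grid_oracle


def _freqs_of(fs):
    return fs.frequencies


class TestEM:
    def test_unambiguous_equals_counting(self):
        # every individual homozygous: haplotypes are directly countable
        D = np.array([[0, 0], [2, 2], [2, 2], [0, 2]], dtype=float)
        fs = em_haplotype_freqs(D)
        f = _freqs_of(fs)
        assert f["00"] == pytest.approx(0.25, abs=1e-9)
        assert f["11"] == pytest.approx(0.5, abs=1e-9)
        assert f["01"] == pytest.approx(0.25, abs=1e-9)

    def test_single_marker_equals_allele_freq(self):
        D = np.array([[1], [1], [2], [0]], dtype=float)
        f = _freqs_of(em_haplotype_freqs(D))
        assert f["1"] == pytest.approx(0.5)

    def test_matches_grid_search_oracle(self):
        """EM MLE equals a nested-grid likelihood maximization (2 markers)."""
        rng = np.random.default_rng(5)
        true = np.array([0.4, 0.3, 0.2, 0.1])  # order 00, 10, 01, 11
        haps = rng.choice(4, size=(100, 2), p=true)
        bit1, bit2 = haps % 2, haps // 2
        D = np.column_stack([bit1.sum(axis=1), bit2.sum(axis=1)]).astype(float)
        fs = em_haplotype_freqs(D, tol=1e-10)
        est = {h: f for h, f in fs.frequencies.items()}
        counts = {}
        for g1, g2 in D.astype(int):
            counts[(g1, g2)] = counts.get((g1, g2), 0) + 1
        oracle = em_grid_oracle(counts)
        for h, k in zip(["00", "10", "01", "11"], range(4)):
            assert est.get(h, 0.0) == pytest.approx(oracle[k], abs=1e-4)

    def test_loglik_monotone_and_invariants(self):
        gm, _, _ = simulate_cohort(
            CohortSimConfig(n_case=150, n_control=100, rare_spec=[], seed=2)
        )
        fs = em_haplotype_freqs(gm.dosages)
        ll = np.array(fs.loglik_trace)
        assert (np.diff(ll) >= -1e-8).all()
        assert fs.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fs.hap_dosage.sum(axis=1), 2.0, atol=1e-9)
        for post in fs.diplotype_posteriors[:20]:
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_marker_bound_enforced(self):
        with pytest.raises(ValueError, match="subset"):
            em_haplotype_freqs(np.zeros((4, 13)))

    def test_recovers_published_pool_frequencies(self):
        """2,000 simulated individuals: every pool frequency within 0.01."""
        gm, _, records = simulate_cohort(
            CohortSimConfig(n_case=1200, n_control=800, rare_spec=[],
                            missing_rate=0.027, seed=42)
        )
        fs = em_haplotype_freqs(gm.dosages)
        alleles = [(r.ref_allele, r.alt_allele) for r in records]
        est = fs.render(alleles)
        for hap, target in table3_pool():
            assert est.get(hap, 0.0) == pytest.approx(target, abs=0.01)


class TestPairwiseLD:
    def test_perfect_coupling(self):
        D = np.array([[0, 0], [2, 2], [1, 1], [2, 2], [0, 0]], dtype=float)
        ld = pairwise_ld(D[:, 0], D[:, 1])
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_exact_independence(self):
        # all four haplotypes at 0.25: 8 homozygous individuals, no ambiguity
        D = np.array(
            [[0, 0], [0, 0], [0, 2], [0, 2], [2, 0], [2, 0], [2, 2], [2, 2]],
            dtype=float,
        )
        ld = pairwise_ld(D[:, 0], D[:, 1])
        assert ld.d_prime == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_counts(self):
        """Phased counts AB:40 Ab:10 aB:10 ab:40 -> D=0.15, D'=0.6, r2=0.36."""
        blocks = [(2, 2)] * 20 + [(2, 0)] * 5 + [(0, 2)] * 5 + [(0, 0)] * 20
        D = np.array(blocks, dtype=float)
        ld = pairwise_ld(D[:, 0], D[:, 1])
        assert ld.d == pytest.approx(0.15, abs=1e-9)
        assert ld.d_prime == pytest.approx(0.6, abs=1e-9)
        assert ld.r2 == pytest.approx(0.36, abs=1e-9)
        lo, hi = ld.d_prime_ci
        assert 0 <= lo <= 0.6 <= hi <= 1

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError):
            pairwise_ld(np.zeros(10), np.ones(10))


class TestBlocks:
    @staticmethod
    def _ci(m, fill):
        ci = np.full((m, m, 2), np.nan)
        for i, j in itertools.combinations(range(m), 2):
            ci[i, j] = ci[j, i] = fill(i, j)
        return ci

    def test_all_strong_ld_single_block(self):
        ci = self._ci(3, lambda i, j: (0.9, 1.0))
        assert [b.markers for b in gabriel_blocks(ci)] == [(0, 1, 2)]

    def test_all_recombination_no_blocks(self):
        ci = self._ci(4, lambda i, j: (0.05, 0.5))
        assert gabriel_blocks(ci) == []

    def test_recombinant_marker_excluded(self):
        # strong LD within markers 0-3; marker 4 recombines with everything
        ci = self._ci(
            5, lambda i, j: (0.05, 0.5) if j == 4 else (0.9, 1.0)
        )
        assert [b.markers for b in gabriel_blocks(ci)] == [(0, 1, 2, 3)]

    def test_block_type_contiguity(self):
        with pytest.raises(ValueError):
            HaplotypeBlock((0, 2))
        with pytest.raises(ValueError):
            HaplotypeBlock((3,))


class TestAssociation:
    def test_identical_profiles_null(self):
        # same genotype distribution in both arms, unambiguous phase
        D = np.array([[0], [2], [0], [2]], dtype=float)
        fs = em_haplotype_freqs(D)
        res = haplotype_association(fs, np.array([True, True, False, False]))
        for r in res:
            assert r.chi2 == pytest.approx(0.0, abs=1e-12)
            assert r.p == pytest.approx(1.0)

    def test_known_phase_equals_integer_chisquare(self):
        """With unambiguous phase the fractional table is the integer table.

        37 carrier chromosomes of 1432 in cases vs 5 of 794 in controls.
        """
        n_case, n_ctrl = 716, 397
        D = np.zeros((n_case + n_ctrl, 1))
        D[:37] = 1.0  # 37 case het carriers
        D[n_case : n_case + 5] = 1.0
        is_case = np.arange(n_case + n_ctrl) < n_case
        fs = em_haplotype_freqs(D)
        res = {r.haplotype: r for r in haplotype_association(fs, is_case)}
        a, b, c, d = 37, 1432 - 37, 5, 794 - 5
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res["1"].chi2 == pytest.approx(chi2, rel=1e-9)
        assert res["1"].p == pytest.approx(chi2_dist.sf(chi2, 1), rel=1e-9)
        assert res["1"].p == pytest.approx(0.0012, abs=2e-4)

    def test_absent_in_controls_has_finite_or(self):
        D = np.zeros((40, 1))
        D[:4] = 1.0
        is_case = np.arange(40) < 20
        fs = em_haplotype_freqs(D)
        res = {r.haplotype: r for r in haplotype_association(fs, is_case, 0.0)}
        assert np.isfinite(res["1"].odds_ratio) and res["1"].odds_ratio > 1


class TestEmpiricalP:
    def test_label_invariant_statistic(self):
        p = empirical_p_familywise(
            lambda lab: np.array([3.0]), np.arange(6) < 3, k=50, seed=0
        )
        assert p[0] == 1.0

    def test_boundary_plus_one(self):
        calls = {"first": True}

        def stat(lab):
            if calls["first"]:
                calls["first"] = False
                return np.array([100.0])
            return np.array([1.0])

        p = empirical_p_familywise(stat, np.arange(6) < 3, k=19, seed=0)
        assert p[0] == pytest.approx(1 / 20)

    def test_matches_exhaustive_label_enumeration(self):
        """Two-test max-statistic null at N=6 vs full enumeration."""
        D = np.array([[1, 0], [1, 1], [0, 0], [0, 1], [0, 0], [0, 0]], float)
        labels = np.arange(6) < 3

        def stats(lab):
            out = []
            for j in range(2):
                a = D[lab, j].sum()
                c = D[~lab, j].sum()
                b, d = 2 * lab.sum() - a, 2 * (~lab).sum() - c
                n = a + b + c + d
                denom = (a + b) * (c + d) * (a + c) * (b + d)
                out.append(0.0 if denom == 0 else n * (a * d - b * c) ** 2 / denom)
            return np.array(out)

        obs = stats(labels)
        exact = np.zeros(2)
        total = 0
        for cases in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=bool)
            lab[list(cases)] = True
            s = stats(lab).max()
            exact += s >= obs - 1e-12
            total += 1
        exact_p = exact / total
        est = empirical_p_familywise(stats, labels, k=4000, seed=9)
        # plus-one estimator converges to the enumeration value
        assert np.allclose(est, exact_p, atol=0.03)
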