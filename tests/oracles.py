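"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (integer combinatorics and
exhaustive enumeration) and deliberately shares no code with the package.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional HWE p by full enumeration (exact rational arithmetic)."""
    n = n_hom_major + n_het + n_hom_minor
    nm = 2 * n_hom_minor + n_het
    nm = min(nm, 2 * n - nm)
    if nm == 0:
        return 1.0
    weights = {}
    for h in range(nm % 2, nm + 1, 2):
        rare_hom = (nm - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        # multinomial ways x 2^h for the two orderings of each het
        weights[h] = Fraction(
            2**h * comb(n, h) * comb(n - h, rare_hom), 1
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Probability-mass two-sided Fisher p by hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= cutoff))


def bh_stepup_rejections(pvals, alpha: float) -> set:
    """Classical BH step-up rejection set (indices into the input)."""
    order = np.argsort(pvals)
    n = len(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= alpha * rank / n:
            k_max = rank
    return set(order[:k_max].tolist())


def wss_rank_sum(dosages: np.ndarray, is_case: np.ndarray) -> float:
    """Weighted-sum rank statistic, straightforward re-derivation.

    Controls-anchored weights, midranks computed by explicit tie groups,
    missing scored as zero minor alleles.
    """
    D = np.asarray(dosages, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    nonmiss = ~np.isnan(D)
    Dz = np.where(nonmiss, D, 0.0)
    scores = np.zeros(D.shape[0])
    for j in range(D.shape[1]):
        m_u = Dz[~y, j].sum()
        n_u = nonmiss[~y, j].sum()
        q = (m_u + 1) / (2 * n_u + 2)
        w = np.sqrt(nonmiss[:, j].sum() * q * (1 - q))
        scores += Dz[:, j] / w
    # midranks via explicit sorting
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores))
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and np.isclose(
            scores[order[j + 1]], scores[order[i]]
        ):
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return float(ranks[y].sum())


def wss_exact_p(dosages: np.ndarray, is_case: np.ndarray) -> float:
    """Exact one-sided p over all case-label assignments (N small)."""
    y = np.asarray(is_case, dtype=bool)
    n, n_case = len(y), int(y.sum())
    x_obs = wss_rank_sum(dosages, y)
    hits = total = 0
    for cases in combinations(range(n), n_case):
        lab = np.zeros(n, dtype=bool)
        lab[list(cases)] = True
        total += 1
        if wss_rank_sum(dosages, lab) >= x_obs - 1e-9:
            hits += 1
    return hits / total


def em_grid_oracle(genotype_counts: dict, refine: int = 5) -> np.ndarray:
    """Two-marker haplotype MLE by nested grid search over the 3-simplex.

    ``genotype_counts`` maps (g1, g2) genotype pairs to counts.  Returns
    frequencies ordered [00, 10, 01, 11] (bit 0 = marker 1 minor).
    """
    compat = {}
    for gt in genotype_counts:
        pairs = []
        site_choice = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}
        for a1, a2 in site_choice[gt[0]]:
            for b1, b2 in site_choice[gt[1]]:
                pairs.append((a1 + 2 * b1, a2 + 2 * b2))
        compat[gt] = pairs

    def loglik(f):
        ll = 0.0
        for gt, cnt in genotype_counts.items():
            s = sum(f[h1] * f[h2] for h1, h2 in compat[gt])
            if s <= 0:
                return -np.inf
            ll += cnt * np.log(s)
        return ll

    center = np.full(4, 0.25)
    width = 1.0
    best = center
    for _ in range(refine):
        step = width / 20
        grid = []
        rng = [np.clip(np.arange(c - width / 2, c + width / 2 + step, step), 0, 1)
               for c in center]
        for f0 in rng[0]:
            for f1 in rng[1]:
                for f2 in rng[2]:
                    f3 = 1 - f0 - f1 - f2
                    if -1e-12 <= f3 <= 1:
                        grid.append((f0, f1, f2, max(f3, 0.0)))
        lls = [loglik(np.array(g)) for g in grid]
        best = np.array(grid[int(np.argmax(lls))])
        center = best
        width = 3 * step
    return best
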