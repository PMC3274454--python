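"""Haplotype estimation and association.

Multi-marker haplotype frequencies are estimated from unphased genotypes by
expectation-maximization over all diplotypes compatible with each
individual's genotype (missing sites are summed over).  Blocks of markers
are called with the D' confidence-interval method: a run of markers is a
block when nearly all informative pairs are in strong LD.  Per-haplotype
association uses a 1-df chi-square on expected (posterior-weighted)
haplotype counts, with family-wise empirical p-values from phenotype-label
permutations of a max-statistic null.

Haplotypes are represented internally as bitmasks over the marker set
(bit j set = minor allele at marker j) and rendered as '0'/'1' strings, or
as allele-letter strings given per-marker (major, minor) labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

MAX_EM_MARKERS = 12

# ---------------------------------------------------------------------------
# EM haplotype frequency estimation


@dataclass
class HaplotypeFreqSet:
    """EM-estimated haplotype frequencies with per-individual posteriors.

    ``hap_dosage[i, h]`` is individual i's posterior-expected count (0..2)
    of haplotype h; rows sum to 2.  ``diplotype_posteriors[i]`` maps
    unordered haplotype-index pairs to posterior weights summing to 1.
    """

    haplotypes: list[str]  # '0'/'1' strings, minor allele = '1'
    freqs: np.ndarray
    hap_dosage: np.ndarray
    diplotype_posteriors: list[dict[tuple[int, int], float]]
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def frequencies(self) -> dict[str, float]:
        return dict(zip(self.haplotypes, self.freqs))

    def render(self, alleles: list[tuple[str, str]]) -> dict[str, float]:
        """Frequencies keyed by allele-letter strings.

        ``alleles[j]`` is the (major, minor) pair for marker j.
        """
        out = {}
        for hap, f in zip(self.haplotypes, self.freqs):
            out["".join(alleles[j][int(c)] for j, c in enumerate(hap))] = f
        return out


def _compatible_pairs(gt: tuple[int, ...]) -> list[tuple[int, int]]:
    """All ordered (h1, h2) bitmask pairs compatible with one genotype.

    Genotype codes per site: 0, 1, 2 minor alleles, 3 = missing.
    """
    choices = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)],
               3: [(0, 0), (0, 1), (1, 0), (1, 1)]}
    pairs = [(0, 0)]
    for j, g in enumerate(gt):
        bit = 1 << j
        pairs = [
            (h1 | (a1 * bit), h2 | (a2 * bit))
            for h1, h2 in pairs
            for a1, a2 in choices[g]
        ]
    return pairs


def em_haplotype_freqs(
    dosages: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    prune_freq: float = 1e-5,
) -> HaplotypeFreqSet:
    """Maximum-likelihood haplotype frequencies by EM.

    ``dosages``: (samples x markers) minor-allele dosages with nan missing.
    Initialization is uniform over all haplotypes compatible with the data;
    convergence when the largest absolute frequency change drops below
    ``tol``.  The log-likelihood is checked to be non-decreasing at every
    iteration.  Haplotypes with final frequency below ``prune_freq`` are
    dropped from the report (posteriors recomputed on the pruned set).
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    n, m = D.shape
    if m > MAX_EM_MARKERS:
        raise ValueError(
            f"{m} markers exceeds the full-enumeration bound of "
            f"{MAX_EM_MARKERS}; subset the markers (e.g. per block)"
        )
    if n == 0:
        raise ValueError("no individuals")
    codes = np.where(np.isnan(D), 3, D).astype(int)

    # group identical genotype rows
    uniq, inverse, counts = np.unique(
        codes, axis=0, return_inverse=True, return_counts=True
    )
    class_pairs = [_compatible_pairs(tuple(gt)) for gt in uniq]
    universe = sorted({h for pairs in class_pairs for hh in pairs for h in hh})
    index = {h: i for i, h in enumerate(universe)}
    H = len(universe)
    pair_i1 = [np.array([index[a] for a, _ in pairs]) for pairs in class_pairs]
    pair_i2 = [np.array([index[b] for _, b in pairs]) for pairs in class_pairs]

    f = np.full(H, 1.0 / H)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        new = np.zeros(H)
        ll = 0.0
        for g, cnt in enumerate(counts):
            w = f[pair_i1[g]] * f[pair_i2[g]]
            s = w.sum()
            ll += cnt * np.log(s)
            post = cnt * w / s
            np.add.at(new, pair_i1[g], post)
            np.add.at(new, pair_i2[g], post)
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(ll)):
            raise AssertionError("EM log-likelihood decreased")
        trace.append(float(ll))
        new /= 2 * n
        delta = np.abs(new - f).max()
        f = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM hit the iteration cap before converging", RuntimeWarning)

    keep = f >= prune_freq
    if not keep.all():
        f = f[keep]
        f /= f.sum()
        remap = -np.ones(H, dtype=int)
        remap[np.flatnonzero(keep)] = np.arange(keep.sum())
        universe = [h for h, k in zip(universe, keep) if k]
        new_i1, new_i2 = [], []
        for g in range(len(counts)):
            ok = keep[pair_i1[g]] & keep[pair_i2[g]]
            if not ok.any():
                raise AssertionError("pruning removed all diplotypes of a genotype")
            new_i1.append(remap[pair_i1[g][ok]])
            new_i2.append(remap[pair_i2[g][ok]])
        pair_i1, pair_i2 = new_i1, new_i2
        H = len(universe)

    # final posteriors per genotype class, expanded to individuals
    class_post = []
    class_dosage = np.zeros((len(counts), H))
    for g in range(len(counts)):
        w = f[pair_i1[g]] * f[pair_i2[g]]
        w = w / w.sum()
        class_post.append(w)
        np.add.at(class_dosage[g], pair_i1[g], w)
        np.add.at(class_dosage[g], pair_i2[g], w)
    hap_dosage = class_dosage[inverse]
    posteriors = []
    for i in range(n):
        g = inverse[i]
        d: dict[tuple[int, int], float] = {}
        for a, b, w in zip(pair_i1[g], pair_i2[g], class_post[g]):
            key = (min(a, b), max(a, b))
            d[key] = d.get(key, 0.0) + float(w)
        posteriors.append(d)

    hap_strings = [format(h, f"0{m}b")[::-1] for h in universe]
    return HaplotypeFreqSet(
        haplotypes=hap_strings,
        freqs=f,
        hap_dosage=hap_dosage,
        diplotype_posteriors=posteriors,
        loglik_trace=trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# pairwise LD and confidence-interval blocks


@dataclass(frozen=True)
class LDStats:
    d: float
    d_prime: float
    r2: float
    d_prime_ci: tuple[float, float]  # 90% coverage on |D'|


def _two_locus_loglik(codes: np.ndarray, counts: np.ndarray, hapf: np.ndarray) -> float:
    """Log-likelihood of 2-marker genotype classes given 4 haplotype freqs.

    ``hapf`` is indexed by bitmask (bit 0 = minor at marker 1, bit 1 = minor
    at marker 2).
    """
    ll = 0.0
    for gt, cnt in zip(codes, counts):
        pairs = _compatible_pairs(tuple(gt))
        s = sum(hapf[a] * hapf[b] for a, b in pairs)
        ll += cnt * np.log(max(s, 1e-300))
    return ll


def pairwise_ld(g1: np.ndarray, g2: np.ndarray, ci_grid: int = 101) -> LDStats:
    """D', r2 and a 90% likelihood-based CI on |D'| for two markers.

    Haplotype frequencies come from the 2-marker EM; the CI is read off the
    normalized likelihood curve over D' in [0, 1] (allele frequencies held
    at their estimates, sign of D fixed to the estimate), taking the 5th and
    95th percentiles of the discretized curve.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    for g in (g1, g2):
        v = g[~np.isnan(g)]
        if v.size == 0 or v.sum() == 0 or v.sum() == 2 * v.size:
            raise ValueError("monomorphic marker")
    fs = em_haplotype_freqs(np.column_stack([g1, g2]), prune_freq=0.0)
    freq = {int(h[::-1], 2): f for h, f in zip(fs.haplotypes, fs.freqs)}
    p00, p01, p10, p11 = (freq.get(k, 0.0) for k in (0, 2, 1, 3))
    # bit 0 = marker 1; reorder to [00,01,10,11] over (m1, m2)
    pA = p10 + p11  # minor at marker 1
    pB = p01 + p11
    D = p11 - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    d_prime = min(d_prime, 1.0)

    codes = np.where(
        np.isnan(np.column_stack([g1, g2])), 3, np.column_stack([g1, g2])
    ).astype(int)
    uniq, counts = np.unique(codes, axis=0, return_counts=True)
    sign = 1.0 if D >= 0 else -1.0
    grid = np.linspace(0.0, 1.0, ci_grid)
    ll = np.empty(ci_grid)
    for i, dp in enumerate(grid):
        Dg = sign * dp * dmax
        hapf = np.array(  # bitmask order: 00, minor@m1, minor@m2, 11
            [
                (1 - pA) * (1 - pB) + Dg,
                pA * (1 - pB) - Dg,
                (1 - pA) * pB - Dg,
                pA * pB + Dg,
            ]
        )
        hapf = np.clip(hapf, 1e-10, None)
        ll[i] = _two_locus_loglik(uniq, counts, hapf)
    w = np.exp(ll - ll.max())
    w /= w.sum()
    c = np.cumsum(w)
    low = float(grid[int(np.searchsorted(c, 0.05))])
    high = float(grid[min(int(np.searchsorted(c, 0.95)), ci_grid - 1)])
    return LDStats(d=float(D), d_prime=float(d_prime), r2=float(r2),
                   d_prime_ci=(low, high))


@dataclass(frozen=True)
class HaplotypeBlock:
    """Contiguous run of >= 2 markers (indices into the ordered marker list)."""

    markers: tuple[int, ...]

    def __post_init__(self) -> None:
        m = self.markers
        if len(m) < 2 or any(b - a != 1 for a, b in zip(m, m[1:])):
            raise ValueError("block must be >= 2 contiguous marker indices")

    @property
    def start(self) -> int:
        return self.markers[0]

    @property
    def stop(self) -> int:
        return self.markers[-1]


def ld_ci_matrix(dosages: np.ndarray) -> np.ndarray:
    """(m, m, 2) array of 90% |D'| CI bounds for all marker pairs i < j."""
    D = np.asarray(dosages, dtype=float)
    m = D.shape[1]
    out = np.full((m, m, 2), np.nan)
    for i, j in itertools.combinations(range(m), 2):
        ld = pairwise_ld(D[:, i], D[:, j])
        out[i, j] = out[j, i] = ld.d_prime_ci
    return out


def gabriel_blocks(
    ci: np.ndarray,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_informative_frac: float = 0.95,
) -> list[HaplotypeBlock]:
    """Call haplotype blocks from pairwise |D'| confidence intervals.

    A pair is in strong LD when its CI is (low >= strong_low, high >=
    strong_high), and shows strong recombination when high < recomb_high;
    only such pairs are informative.  A candidate span qualifies when the
    strong-LD fraction of its informative pairs reaches
    ``min_informative_frac``; overlaps are resolved longest-span-first
    (ties to the leftmost).
    """
    m = ci.shape[0]
    strong = (ci[..., 0] >= strong_low) & (ci[..., 1] >= strong_high)
    recomb = ci[..., 1] < recomb_high
    candidates = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            n_strong = sum(strong[a, b] for a, b in pairs)
            n_inf = n_strong + sum(recomb[a, b] for a, b in pairs)
            if n_inf == 0:
                continue
            if n_strong / n_inf >= min_informative_frac:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(HaplotypeBlock(tuple(range(i, j + 1))))
    blocks.sort(key=lambda b: b.start)
    return blocks


# ---------------------------------------------------------------------------
# association


@dataclass
class HaplotypeAssocResult:
    haplotype: str
    freq_all: float
    freq_case: float
    freq_control: float
    chi2: float
    p: float
    odds_ratio: float
    empirical_p: float = float("nan")


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def _hap_tables(
    hap_dosage: np.ndarray, is_case: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    case_counts = hap_dosage[is_case].sum(axis=0)
    ctrl_counts = hap_dosage[~is_case].sum(axis=0)
    return case_counts, ctrl_counts, 2.0 * is_case.sum(), 2.0 * (~is_case).sum()


def haplotype_association(
    freqset: HaplotypeFreqSet,
    is_case: np.ndarray,
    min_report_freq: float = 0.01,
) -> list[HaplotypeAssocResult]:
    """Haplotype-vs-rest 1-df chi-square per reported haplotype.

    Expected haplotype counts are sums of posterior dosages; haplotypes
    below ``min_report_freq`` are pooled into the "rest" side and not
    reported individually.  The OR comes from the same fractional table
    (Haldane 0.5 on zero cells).
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("both arms must contain individuals")
    case_counts, ctrl_counts, case_tot, ctrl_tot = _hap_tables(
        freqset.hap_dosage, is_case
    )
    results = []
    for h, hap in enumerate(freqset.haplotypes):
        if freqset.freqs[h] < min_report_freq:
            continue
        a, c = case_counts[h], ctrl_counts[h]
        b, d = case_tot - a, ctrl_tot - c
        chi2 = _chi2_2x2(a, b, c, d)
        cells = np.array([a, b, c, d])
        if (cells == 0).any():
            cells = cells + 0.5
        or_ = (cells[0] * cells[3]) / (cells[1] * cells[2])
        results.append(
            HaplotypeAssocResult(
                haplotype=hap,
                freq_all=(a + c) / (case_tot + ctrl_tot),
                freq_case=a / case_tot,
                freq_control=c / ctrl_tot,
                chi2=float(chi2),
                p=float(chi2_dist.sf(chi2, 1)),
                odds_ratio=float(or_),
            )
        )
    return results


def empirical_p_familywise(
    statistic_fn,
    labels: np.ndarray,
    k: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Family-wise empirical p-values under a max-statistic permutation null.

    ``statistic_fn(labels)`` must return one non-negative statistic per test
    and be deterministic given the labels.  For each test t,
    p_emp(t) = (1 + #{perm : max_t' S_perm(t') >= S_obs(t)}) / (k + 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels)
    rng = rng if rng is not None else np.random.default_rng(seed)
    obs = np.asarray(statistic_fn(labels), dtype=float)
    exceed = np.zeros_like(obs)
    for _ in range(k):
        s = np.asarray(statistic_fn(rng.permutation(labels)), dtype=float)
        exceed += s.max() >= obs - 1e-12
    return (1.0 + exceed) / (k + 1.0)


def haplotype_empirical_p(
    freqset: HaplotypeFreqSet,
    is_case: np.ndarray,
    min_report_freq: float = 0.01,
    k: int = 100_000,
    seed: int | None = None,
    chunk: int = 2_000,
) -> list[HaplotypeAssocResult]:
    """Association results with family-wise empirical p-values.

    Vectorized permutation of case/control labels; diplotype posteriors stay
    fixed at the pooled-EM fit (labels are exchangeable under the null, and
    the pooled fit does not depend on them).
    """
    is_case = np.asarray(is_case, dtype=bool)
    results = haplotype_association(freqset, is_case, min_report_freq)
    keep = [freqset.haplotypes.index(r.haplotype) for r in results]
    dos = freqset.hap_dosage[:, keep]
    n = dos.shape[0]
    n_case = int(is_case.sum())
    case_tot, ctrl_tot = 2.0 * n_case, 2.0 * (n - n_case)
    tot = dos.sum(axis=0)
    obs = np.array([r.chi2 for r in results])
    exceed = np.zeros(len(keep))
    rng = np.random.default_rng(seed)
    done = 0
    while done < k:
        b = min(chunk, k - done)
        P = rng.permuted(np.tile(is_case, (b, 1)), axis=1)
        A = P.astype(float) @ dos  # (b, H) case haplotype counts
        C = tot - A
        B = case_tot - A
        Dd = ctrl_tot - C
        nn = case_tot + ctrl_tot
        denom = (A + B) * (C + Dd) * (A + C) * (B + Dd)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(denom > 0, nn * (A * Dd - B * C) ** 2 / denom, 0.0)
        exceed += (chi2.max(axis=1)[:, None] >= obs[None, :] - 1e-12).sum(axis=0)
        done += b
    for r, e in zip(results, exceed):
        r.empirical_p = float((1.0 + e) / (k + 1.0))
    return results
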