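"""Single-variant allelic association.

Each variant is tested on a 2x2 table of minor/major allele counts in cases
vs controls (two alleles per genotyped diploid individual; missing genotypes
contribute none).  Significance is the two-sided Fisher exact test under the
probability-mass convention (sum of all hypergeometric outcomes no more
probable than the observed one).  Effect size is the allelic odds ratio with
a Woolf log-OR 95% CI; zero cells are handled with the Haldane 0.5
correction when enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

from .io import GenotypeMatrix, PhenotypeVector


@dataclass(frozen=True)
class AlleleCountTable:
    minor_case: int
    major_case: int
    minor_control: int
    major_control: int

    def __post_init__(self) -> None:
        if min(self.minor_case, self.major_case, self.minor_control, self.major_control) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def case_alleles(self) -> int:
        return self.minor_case + self.major_case

    @property
    def control_alleles(self) -> int:
        return self.minor_control + self.major_control

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.minor_case, self.major_case], [self.minor_control, self.major_control]]
        )


@dataclass
class SingleVariantResult:
    variant_id: str
    table: AlleleCountTable
    p_fisher: float
    odds_ratio: float  # nan when undefined
    ci95: tuple[float, float]
    maf_case: float
    maf_control: float


def allele_table(genotypes: np.ndarray, phen: PhenotypeVector) -> AlleleCountTable:
    """Minor/major allele counts per arm from minor-oriented dosages."""
    g = np.asarray(genotypes, dtype=float)
    out = []
    for mask in (phen.is_case, ~phen.is_case):
        col = g[mask]
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise ValueError("no genotyped samples in one arm")
        minor = int(col.sum())
        out.append((minor, 2 * col.size - minor))
    (mc, Mc), (mu, Mu) = out
    return AlleleCountTable(mc, Mc, mu, Mu)


def fisher_two_sided(table: AlleleCountTable) -> float:
    """Two-sided Fisher exact p (probability-mass convention)."""
    return float(fisher_exact(table.as_array(), alternative="two-sided")[1])


def odds_ratio_ci(
    table: AlleleCountTable, zero_cell_correction: bool = True
) -> tuple[float, tuple[float, float]]:
    """Allelic OR with Woolf 95% CI; Haldane +0.5 on zero cells.

    With a zero cell and the correction disabled the OR and CI are undefined
    and returned as nan (flagged, not raised).
    """
    a, b, c, d = (
        table.minor_case,
        table.major_case,
        table.minor_control,
        table.major_control,
    )
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        if not zero_cell_correction:
            return float("nan"), (float("nan"), float("nan"))
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), (float(lo), float(hi))


def test_variant(
    variant_id: str, genotypes: np.ndarray, phen: PhenotypeVector
) -> SingleVariantResult:
    t = allele_table(genotypes, phen)
    or_, ci = odds_ratio_ci(t)
    return SingleVariantResult(
        variant_id=variant_id,
        table=t,
        p_fisher=fisher_two_sided(t),
        odds_ratio=or_,
        ci95=ci,
        maf_case=t.minor_case / t.case_alleles,
        maf_control=t.minor_control / t.control_alleles,
    )


def single_variant_scan(
    gm: GenotypeMatrix, phen: PhenotypeVector
) -> list[SingleVariantResult]:
    phen = phen.aligned_to(gm)
    return [
        test_variant(vid, gm.dosages[:, j], phen)
        for j, vid in enumerate(gm.variant_ids)
    ]


def scan_frame(results: list[SingleVariantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "variant_id": r.variant_id,
                "minor_case": r.table.minor_case,
                "case_alleles": r.table.case_alleles,
                "minor_control": r.table.minor_control,
                "control_alleles": r.table.control_alleles,
                "maf_case": r.maf_case,
                "maf_control": r.maf_control,
                "p_fisher": r.p_fisher,
                "odds_ratio": r.odds_ratio,
                "or_ci_low": r.ci95[0],
                "or_ci_high": r.ci95[1],
            }
        )
    return pd.DataFrame(rows)
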