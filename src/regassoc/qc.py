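"""Per-variant quality control.

Three filters, mirroring common resequencing practice: an exact
Hardy-Weinberg equilibrium test (genotyping-artifact screen, variants with
p below ``hwe_alpha`` are excluded from all downstream association steps),
per-variant call rate, and the common/rare split at a control-MAF threshold
(inclusive at the boundary, default 2%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import GenotypeMatrix, PhenotypeVector


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed minor-allele count and sums the probabilities
    of all heterozygote configurations no more probable than the observed
    one (the standard exact HWE test).  Computed in log space.  Returns 1.0
    for a monomorphic variant (single possible configuration).
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotyped samples")
    nm = 2 * n_hom_minor + n_het
    nm = min(nm, 2 * n - nm)  # fold to the rarer allele; test is symmetric
    if nm == 0:
        return 1.0
    # heterozygote count must share parity with the minor-allele count
    hets = np.arange(nm % 2, nm + 1, 2)
    # log P(het = h | n, nm) up to a shared constant
    logw = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((nm - hets) / 2 + 1)
        - gammaln(n - (nm + hets) / 2 + 1)
    )
    logw -= logsumexp(logw)
    obs = min(n_het, nm)  # after folding, het count is unchanged
    log_obs = logw[hets == obs][0]
    keep = logw <= log_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logw[keep]))))


def call_rate(genotypes: np.ndarray) -> float:
    """Fraction of samples with a non-missing genotype at one variant."""
    g = np.asarray(genotypes, dtype=float)
    if g.size == 0:
        raise ValueError("call rate needs at least one sample")
    return float(np.mean(~np.isnan(g)))


def control_maf(control_genotypes: np.ndarray) -> float:
    g = np.asarray(control_genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("no genotyped controls")
    maf = g.sum() / (2 * g.size)
    return float(min(maf, 1 - maf))


def classify_rarity(control_genotypes: np.ndarray, threshold: float = 0.02) -> str:
    """'common' iff control MAF >= threshold (inclusive), else 'rare'."""
    return "common" if control_maf(control_genotypes) >= threshold else "rare"


@dataclass
class QCReport:
    variant_id: str
    call_rate: float
    hwe_p: float
    maf_controls: float
    rarity: str
    excluded: bool
    reason: str = ""


def _genotype_counts(g: np.ndarray) -> tuple[int, int, int]:
    g = g[~np.isnan(g)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def run_qc(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    hwe_alpha: float = 0.05,
    rare_maf: float = 0.02,
    hwe_scope: str = "combined",
) -> list[QCReport]:
    """QC every variant; HWE in the combined sample by default.

    ``hwe_scope`` may be 'combined' or 'controls' (which sample the exact
    test is evaluated in; the combined sample matches cohort-wide exclusion
    of genotyping artifacts).
    """
    if hwe_scope not in ("combined", "controls"):
        raise ValueError("hwe_scope must be 'combined' or 'controls'")
    phen = phen.aligned_to(gm)
    ctrl = ~phen.is_case
    reports = []
    for j, vid in enumerate(gm.variant_ids):
        col = gm.dosages[:, j]
        hwe_col = col[ctrl] if hwe_scope == "controls" else col
        p = hwe_exact_p(*_genotype_counts(hwe_col))
        maf = control_maf(col[ctrl])
        excluded = p < hwe_alpha
        reports.append(
            QCReport(
                variant_id=vid,
                call_rate=call_rate(col),
                hwe_p=p,
                maf_controls=maf,
                rarity="common" if maf >= rare_maf else "rare",
                excluded=excluded,
                reason=f"HWE p {p:.3g} < {hwe_alpha}" if excluded else "",
            )
        )
    return reports


def qc_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
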