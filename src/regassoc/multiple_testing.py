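"""Benjamini-Hochberg q-values and the shared empirical-p estimator.

q-values are computed over exactly the family of tests passed in; family
membership is always an explicit argument, never inferred from context.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, returned in input order.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * n / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d vector of p-values")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def empirical_p(n_exceed: int, k: int) -> float:
    """Plus-one permutation estimator (n_exceed + 1) / (k + 1)."""
    if k < 1 or n_exceed < 0 or n_exceed > k:
        raise ValueError("need 0 <= n_exceed <= k, k >= 1")
    return (n_exceed + 1.0) / (k + 1.0)
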