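"""Meta-analysis scoring of candidate regions and multiple-testing correction.

Each candidate DER is scored with Cochran's Q, the classical heterogeneity
statistic of inverse-variance-weighted meta-analysis, treating every member
probe as a "study" contributing its regression slope ``m`` and squared
standard error ``se2``:

    Q = sum_j ( m_j - m_bar )^2 / se2_j,
    m_bar = sum_i (m_i / se2_i) / sum_i (1 / se2_i)

Noisy probes get small weight, so spurious runs driven by a few
high-difference probes score low.  Significance never comes from the chi-square
reference: neighbouring tiles are correlated, so the null is built by
permuting phenotype labels (see :mod:`tilemeta.pipeline`).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["cochran_q", "permutation_pvalue", "bh_fdr"]


def cochran_q(m, se2) -> float:
    """Cochran's Q for slopes ``m`` with squared standard errors ``se2``.

    All ``se2`` must be strictly positive (the regression stage floors them).
    A single probe gives Q = 0.
    """
    m = np.asarray(m, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if m.size == 0:
        raise ValueError("cochran_q requires at least one probe")
    if np.any(se2 <= 0) or not np.all(np.isfinite(se2)):
        raise ValueError("all se2 must be finite and > 0")
    w = 1.0 / se2
    m_bar = float(np.sum(w * m) / np.sum(w))
    return float(np.sum(w * (m - m_bar) ** 2))


def permutation_pvalue(q_obs: float, null_q) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= obs}) / (1 + B)``.

    Never exactly zero; the smallest attainable value is ``1/(B+1)``.
    """
    null_q = np.asarray(null_q, dtype=float)
    if null_q.size < 1:
        raise ValueError("null distribution must contain at least one value")
    return float((1 + np.sum(null_q >= q_obs)) / (1 + null_q.size))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, q >= p."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
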