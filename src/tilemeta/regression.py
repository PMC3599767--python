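"""Probe-wise ordinary least squares of signal on phenotype (plus covariates).

Every probe is fit independently with an intercept; the quantities carried
forward are the phenotype coefficient ``m`` (slope) and its squared standard
error ``se2``, the inputs of the downstream inverse-variance meta-analysis.
With a 0/1 phenotype and no covariates the slope equals the group-1 minus
group-0 mean difference and ``se2`` its pooled-variance squared SE.

Missing values are handled per probe by complete-case analysis.  A probe with
too few complete observations, or a design that becomes singular after
dropping incomplete rows, is flagged unusable and excluded from run detection.
Zero-residual (perfect) fits would give infinite meta-analysis weight, so
``se2`` is floored at a tiny positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ProbeMatrix, SampleTable, ValidationError, align_samples

__all__ = ["SE2_FLOOR", "ProbeStats", "ols_slope_se", "fit_all_probes"]

#: floor for the squared standard error of the slope (matrix units squared);
#: keeps 1/se2 weights finite at zero-residual probes while preserving order
SE2_FLOOR = 1e-24


@dataclass
class ProbeStats:
    """Per-probe regression results, aligned with the probe order of the matrix."""

    slope: np.ndarray  # float, NaN where unusable
    se2: np.ndarray  # float >= SE2_FLOOR where usable
    n_used: np.ndarray  # int, complete observations per probe
    usable: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.slope)


def ols_slope_se(
    y: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    se2_floor: float = SE2_FLOOR,
) -> tuple[float, float, int]:
    """OLS fit of one probe; returns ``(m, se2, n_used)``.

    ``covariates`` is an optional ``(n, k)`` array of additive terms.  Rows
    with a missing value in ``y`` or the design are dropped.  Returns
    ``(nan, nan, n_used)`` when degrees of freedom are insufficient
    (``n_used < p + 2`` where p counts design columns including the
    intercept, i.e. no residual df would remain) or the design is singular.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(phenotype, dtype=float)
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
    X = np.column_stack(cols)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n_used = int(keep.sum())
    p = X.shape[1]
    if n_used < p + 1:
        return float("nan"), float("nan"), n_used
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        return float("nan"), float("nan"), n_used
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n_used - p)
    se2 = max(s2 * xtx_inv[1, 1], se2_floor)
    return float(beta[1]), float(se2), n_used


def _design_from_annotation(
    annot: SampleTable,
    sample_order,
    phenotype_name: str,
    covariate_names=(),
) -> tuple[np.ndarray, np.ndarray | None]:
    """Extract phenotype vector and covariate block aligned to sample order."""
    x = annot.column(phenotype_name, sample_order)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValidationError(f"phenotype {phenotype_name!r} is constant")
    cov_cols = []
    for name in covariate_names:
        c = annot.column(name, sample_order)
        finite = c[np.isfinite(c)]
        if np.unique(finite).size < 2:
            warnings.warn(
                f"covariate {name!r} is constant; dropped from the design",
                stacklevel=3,
            )
            continue
        cov_cols.append(c)
    covs = np.column_stack(cov_cols) if cov_cols else None
    return x, covs


def batch_ols(Y: np.ndarray, X: np.ndarray, se2_floor: float = SE2_FLOOR):
    """Vectorized complete-data OLS of many probes against one design.

    ``Y`` is ``(n_probes, n_samples)`` without NaN; ``X`` is the full design
    with intercept in column 0 and phenotype in column 1.  Returns
    ``(m, se2)`` arrays of length ``n_probes``.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # (p, n)
    B = Y @ proj.T  # (probes, p)
    resid = Y - B @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / (n - p)
    se2 = np.maximum(s2 * xtx_inv[1, 1], se2_floor)
    return B[:, 1], se2


def fit_all_probes(
    matrix: ProbeMatrix,
    annot: SampleTable,
    phenotype_name: str,
    covariate_names=(),
    se2_floor: float = SE2_FLOOR,
) -> ProbeStats:
    """Fit the probe-wise linear model across the whole matrix.

    Returns one entry per probe in matrix order.  A fully observed matrix is
    fit in a single vectorized pass; probes with missing values fall back to
    per-probe complete-case fits.
    """
    align_samples(matrix, annot)
    x, covs = _design_from_annotation(
        annot, matrix.sample_ids, phenotype_name, covariate_names
    )
    Y = matrix.values
    n_probes, n_samples = Y.shape
    cols = [np.ones(n_samples), x]
    if covs is not None:
        cols.extend(covs[:, j] for j in range(covs.shape[1]))
    X = np.column_stack(cols)
    p = X.shape[1]

    slope = np.full(n_probes, np.nan)
    se2 = np.full(n_probes, np.nan)
    n_used = np.full(n_probes, n_samples, dtype=int)
    usable = np.zeros(n_probes, dtype=bool)

    row_complete = np.all(np.isfinite(Y), axis=1)
    if np.linalg.matrix_rank(X.T @ X) < p:
        raise ValidationError("design matrix is singular (collinear covariates?)")
    if row_complete.any():
        m_c, se2_c = batch_ols(Y[row_complete], X, se2_floor)
        slope[row_complete] = m_c
        se2[row_complete] = se2_c
        usable[row_complete] = n_samples >= p + 1
    for i in np.flatnonzero(~row_complete):
        m_i, se2_i, nu = ols_slope_se(Y[i], x, covs, se2_floor)
        slope[i], se2[i], n_used[i] = m_i, se2_i, nu
        usable[i] = np.isfinite(m_i)
    return ProbeStats(slope, se2, n_used, usable)
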