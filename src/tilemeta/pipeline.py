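"""End-to-end DER calling: fit, run detection, permutation-calibrated Q, FDR.

The permutation scheme shuffles the phenotype column only (covariates stay
attached to their samples), refits the per-probe slopes under each shuffled
design, and recomputes Q for every candidate region.  One seeded sequence of
B permutations is shared by all candidates in a run, which keeps the cost of
large candidate sets manageable and makes ranks directly comparable across
regions.  The p-value is the add-one upper-tail quantile of the observed Q in
its permutation null, and Benjamini-Hochberg correction is applied across all
candidates of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ProbeMatrix, SampleTable, ValidationError, DER_COLUMNS
from .meta import bh_fdr, cochran_q, permutation_pvalue
from .regions import CandidateDER, find_candidate_ders, summarize_der
from .regression import SE2_FLOOR, batch_ols, fit_all_probes, ols_slope_se, _design_from_annotation

logger = logging.getLogger("tilemeta")

__all__ = ["ScoredDER", "permutation_null", "call_ders", "scored_to_frame"]


@dataclass
class ScoredDER:
    """A scored differentially enriched region.

    ``start``/``end`` are the 1-based positions of the first and last member
    probe (inclusive).  ``direction`` is the shared slope sign.  ``Q`` is the
    observed meta-statistic, ``p`` its add-one permutation p-value and
    ``q_fdr`` the Benjamini-Hochberg adjusted value across the run.
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    direction: int
    mean_diff: float
    max_diff: float
    Q: float
    p: float
    q_fdr: float
    first_probe: int = -1  # matrix row index; bookkeeping, not written to tables
    last_probe: int = -1


def _check_permutable(x: np.ndarray) -> None:
    uniq = np.unique(x)
    if uniq.size == 2:
        counts = [(x == u).sum() for u in uniq]
        if min(counts) < 2:
            raise ValidationError(
                "binary phenotype needs at least 2 samples per group "
                "for a usable permutation null"
            )


def _permutation_matrix(x: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B independent shuffles of the phenotype, as columns of an (n, B) array."""
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    perms = np.tile(x, (B, 1))
    perms = rng.permuted(perms, axis=1)
    return perms.T


def _batch_null_q(
    values: np.ndarray,
    segments: list[np.ndarray],
    x_perms: np.ndarray,
    covariates: np.ndarray | None,
    se2_floor: float = SE2_FLOOR,
) -> np.ndarray:
    """Null Q for every segment under every permutation; shape (n_segments, B).

    ``values`` is the full sample-complete value matrix; each segment is an
    array of row indices.  A closed-form simple-regression path covers the
    common case (no covariates, no missing data); otherwise each permuted
    design is refit explicitly.
    """
    member = np.concatenate(segments)
    bounds = np.cumsum([0] + [len(s) for s in segments])[:-1]
    Ym = values[member]
    n = values.shape[1]
    B = x_perms.shape[1]
    complete = np.all(np.isfinite(Ym), axis=1)

    if covariates is None and complete.all():
        x0 = x_perms[:, 0]
        sxx = float(np.sum((x0 - x0.mean()) ** 2))
        V = (x_perms - x_perms.mean(axis=0, keepdims=True)) / sxx
        M = Ym @ V  # (members, B)
        syy = np.sum((Ym - Ym.mean(axis=1, keepdims=True)) ** 2, axis=1)
        s2 = np.clip(syy[:, None] - M * M * sxx, 0.0, None) / (n - 2)
        se2 = np.maximum(s2 / sxx, se2_floor)
        W = 1.0 / se2
        WM = W * M
        sw = np.add.reduceat(W, bounds, axis=0)
        swm = np.add.reduceat(WM, bounds, axis=0)
        swm2 = np.add.reduceat(WM * M, bounds, axis=0)
        return swm2 - swm * swm / sw

    null_q = np.empty((len(segments), B))
    for b in range(B):
        xb = x_perms[:, b]
        cols = [np.ones(n), xb]
        if covariates is not None:
            cols.extend(covariates[:, j] for j in range(covariates.shape[1]))
        X = np.column_stack(cols)
        m = np.full(len(member), np.nan)
        se2 = np.full(len(member), np.nan)
        if complete.any():
            m_c, se2_c = batch_ols(Ym[complete], X, se2_floor)
            m[complete], se2[complete] = m_c, se2_c
        for i in np.flatnonzero(~complete):
            m[i], se2[i], _ = ols_slope_se(Ym[i], xb, covariates, se2_floor)
        for k in range(len(segments)):
            lo = bounds[k]
            hi = bounds[k + 1] if k + 1 < len(bounds) else len(member)
            mk, sk = m[lo:hi], se2[lo:hi]
            good = np.isfinite(mk)
            null_q[k, b] = cochran_q(mk[good], sk[good]) if good.any() else 0.0
    return null_q


def permutation_null(
    values: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    B: int = 1000,
    seed: int | np.random.Generator = 1,
    se2_floor: float = SE2_FLOOR,
) -> np.ndarray:
    """Permutation null distribution of Q for one region.

    ``values`` is the region's probe-by-sample slice.  The phenotype column is
    shuffled B times (covariates stay attached to their samples) and Q is
    recomputed from the refit slopes for each shuffle.  Returns the B null Q
    values; reproducible for a fixed seed.
    """
    x = np.asarray(phenotype, dtype=float)
    _check_permutable(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_perms = _permutation_matrix(x, B, rng)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return _batch_null_q(values, [np.arange(values.shape[0])], x_perms, covariates, se2_floor)[0]


def call_ders(
    matrix: ProbeMatrix,
    annot: SampleTable,
    phenotype_name: str,
    covariate_names=(),
    min_probes: int = 3,
    B: int = 1000,
    seed: int = 1,
    max_gap_bp: int | None = None,
    se2_floor: float = SE2_FLOOR,
) -> list[ScoredDER]:
    """Run the full DER-calling pipeline and return scored regions.

    Steps: probe-wise regression -> maximal same-sign slope runs of at least
    ``min_probes`` probes -> per-region Q with a shared, seeded permutation
    null of size ``B`` -> BH-FDR across all candidates.  The returned list is
    sorted by (p ascending, Q descending, \\|mean_diff\\| descending,
    coordinates) so output order is deterministic.
    """
    stats = fit_all_probes(matrix, annot, phenotype_name, covariate_names, se2_floor)
    candidates = find_candidate_ders(
        stats, matrix.chrom, matrix.position, min_probes, max_gap_bp
    )
    logger.info(
        "call_ders: %d probes, %d candidate regions, B=%d, seed=%d",
        matrix.n_probes,
        len(candidates),
        B,
        seed,
    )
    if not candidates:
        return []

    x, covs = _design_from_annotation(
        annot, matrix.sample_ids, phenotype_name, covariate_names
    )
    _check_permutable(x)
    rng = np.random.default_rng(seed)
    x_perms = _permutation_matrix(x, B, rng)
    segments = [c.probe_indices() for c in candidates]
    null_q = _batch_null_q(matrix.values, segments, x_perms, covs, se2_floor)

    q_obs = np.array(
        [cochran_q(stats.slope[seg], stats.se2[seg]) for seg in segments]
    )
    pvals = np.array(
        [permutation_pvalue(q_obs[k], null_q[k]) for k in range(len(candidates))]
    )
    qvals = bh_fdr(pvals)

    scored = []
    for k, cand in enumerate(candidates):
        mean_diff, max_diff = summarize_der(cand, matrix, x, stats)
        scored.append(
            ScoredDER(
                chrom=cand.chrom,
                start=int(matrix.position[cand.first]),
                end=int(matrix.position[cand.last]),
                n_probes=cand.n_probes,
                direction=cand.direction,
                mean_diff=mean_diff,
                max_diff=max_diff,
                Q=float(q_obs[k]),
                p=float(pvals[k]),
                q_fdr=float(qvals[k]),
                first_probe=cand.first,
                last_probe=cand.last,
            )
        )
    scored.sort(key=lambda d: (d.p, -d.Q, -abs(d.mean_diff), d.chrom, d.start))
    return scored


def scored_to_frame(ders) -> "pd.DataFrame":
    """Scored DERs as a DataFrame in the documented column order and sort order."""
    import pandas as pd

    rows = [
        {col: getattr(d, col) for col in DER_COLUMNS}
        for d in sorted(ders, key=lambda d: (d.p, -d.Q, -abs(d.mean_diff), d.chrom, d.start))
    ]
    return pd.DataFrame(rows, columns=DER_COLUMNS)
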