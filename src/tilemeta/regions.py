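"""Candidate DER detection: maximal same-sign slope runs along the genome.

A candidate differentially enriched region is a maximal stretch of adjacent
usable probes whose regression slopes share a strict sign, holding at least
``min_probes`` probes (default 3, the smallest region the method is meant to
resolve — about one enrichment fragment on common tiling platforms).  Runs
never span chromosomes, break at exactly-zero slopes and unusable probes, and
optionally break where the inter-probe distance exceeds ``max_gap_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ProbeMatrix
from .regression import ProbeStats

__all__ = ["CandidateDER", "find_candidate_ders", "summarize_der"]


@dataclass
class CandidateDER:
    """A maximal same-sign slope run, by probe index into the matrix."""

    chrom: str
    first: int  # index of first member probe (inclusive)
    last: int  # index of last member probe (inclusive)
    direction: int  # +1 or -1

    @property
    def n_probes(self) -> int:
        return self.last - self.first + 1

    def probe_indices(self) -> np.ndarray:
        return np.arange(self.first, self.last + 1)


def find_candidate_ders(
    stats: ProbeStats,
    chrom: np.ndarray,
    position: np.ndarray,
    min_probes: int = 3,
    max_gap_bp: int | None = None,
) -> list[CandidateDER]:
    """Enumerate maximal same-sign slope runs with at least ``min_probes`` probes.

    ``chrom``/``position`` are the matrix coordinate arrays aligned with
    ``stats``.  Returns candidates in genomic order.
    """
    if min_probes < 2:
        raise ValueError(f"min_probes must be >= 2, got {min_probes}")
    n = len(stats)
    signs = np.zeros(n, dtype=int)
    ok = stats.usable & np.isfinite(stats.slope)
    signs[ok] = np.sign(stats.slope[ok]).astype(int)

    out: list[CandidateDER] = []
    run_start = None
    run_sign = 0

    def flush(end_index: int) -> None:
        nonlocal run_start, run_sign
        if run_start is not None and end_index - run_start + 1 >= min_probes:
            out.append(
                CandidateDER(str(chrom[run_start]), run_start, end_index, run_sign)
            )
        run_start, run_sign = None, 0

    for i in range(n):
        s = signs[i]
        breaks = run_start is not None and (
            chrom[i] != chrom[run_start]
            or (
                max_gap_bp is not None
                and position[i] - position[i - 1] > max_gap_bp
            )
        )
        if breaks:
            flush(i - 1)
        if s == 0:
            flush(i - 1)
            continue
        if run_start is None:
            run_start, run_sign = i, s
        elif s != run_sign:
            flush(i - 1)
            run_start, run_sign = i, s
    flush(n - 1)
    return out


def summarize_der(
    candidate: CandidateDER,
    matrix: ProbeMatrix,
    phenotype: np.ndarray,
    stats: ProbeStats | None = None,
) -> tuple[float, float]:
    """Per-probe fold-difference summaries of a candidate: ``(mean_diff, max_diff)``.

    For a binary 0/1 phenotype the per-probe difference is the group-1 mean
    minus the group-0 mean; for a continuous phenotype it is the fitted slope
    (``stats`` required).  ``mean_diff`` is the average of the per-probe
    differences; ``max_diff`` is the signed difference of largest magnitude.
    """
    idx = candidate.probe_indices()
    x = np.asarray(phenotype, dtype=float)
    uniq = np.unique(x[np.isfinite(x)])
    if uniq.size == 2 and set(uniq) == {0.0, 1.0}:
        vals = matrix.values[idx]
        g1 = np.nanmean(vals[:, x == 1.0], axis=1)
        g0 = np.nanmean(vals[:, x == 0.0], axis=1)
        diffs = g1 - g0
    else:
        if stats is None:
            raise ValueError("continuous phenotype requires probe stats (slopes)")
        diffs = stats.slope[idx]
    mean_diff = float(np.mean(diffs))
    max_diff = float(diffs[int(np.argmax(np.abs(diffs)))])
    return mean_diff, max_diff
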