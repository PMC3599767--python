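"""Scoring of DER calls against a ground-truth set of hidden DMRs.

Confusion counts follow the asymmetric convention common in region-calling
benchmarks: calls are the unit for true/false positives (every significant
call overlapping a truth interval counts as a TP, even if several hit the
same interval), truth intervals are the unit for false negatives, and
non-significant non-overlapping calls are the true negatives at the region
level.  Probe-level counts classify every probe of the evaluated matrix by
(inside a significant call) x (inside a truth interval), which is the more
comparable metric across callers with different candidate counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "significant_mask",
    "ttest_average_dmr",
    "der_level_confusion",
    "probe_level_confusion",
    "roc_auc",
    "truth_found_flags",
    "power_table",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    level: str  # "der" or "probe"

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else float("nan")


def significant_mask(scored, alpha: float = 0.05, use_fdr: bool = True) -> np.ndarray:
    """Boolean significance flag per scored DER (BH q < alpha, or nominal p)."""
    if use_fdr:
        return np.array([d.q_fdr < alpha for d in scored], dtype=bool)
    return np.array([d.p < alpha for d in scored], dtype=bool)


def ttest_average_dmr(values: np.ndarray, group: np.ndarray) -> float:
    """Two-sample pooled-variance t-test of per-sample averages across probes.

    ``values`` is (probes, samples); ``group`` is 0/1 per sample.  The
    degenerate case (zero variance in both groups, equal means) returns 1.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    group = np.asarray(group)
    per_sample = values.mean(axis=0)
    a, b = per_sample[group == 1], per_sample[group == 0]
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 samples per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _overlaps(call, truth) -> bool:
    """True when two 1-based inclusive intervals on the same chrom share a probe."""
    return call.chrom == truth.chrom and call.start <= truth.end and call.end >= truth.start


def der_level_confusion(
    scored,
    truth,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> ConfusionCounts:
    """Region-level confusion counts of calls vs truth intervals."""
    sig = significant_mask(scored, alpha, use_fdr)
    tp = fp = tn = 0
    hit_truth = np.zeros(len(truth), dtype=bool)
    for call, is_sig in zip(scored, sig):
        overlapping = [j for j, t in enumerate(truth) if _overlaps(call, t)]
        if is_sig:
            if overlapping:
                tp += 1
                hit_truth[overlapping] = True
            else:
                fp += 1
        elif not overlapping:
            tn += 1
    fn = int((~hit_truth).sum())
    return ConfusionCounts(tp, tn, fp, fn, level="der")


def probe_level_confusion(
    scored,
    truth,
    matrix,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> ConfusionCounts:
    """Per-probe confusion: (inside a significant call) x (inside truth)."""
    in_call = np.zeros(matrix.n_probes, dtype=bool)
    sig = significant_mask(scored, alpha, use_fdr)
    for call, is_sig in zip(scored, sig):
        if not is_sig:
            continue
        mask = (
            (matrix.chrom == call.chrom)
            & (matrix.position >= call.start)
            & (matrix.position <= call.end)
        )
        in_call |= mask
    in_truth = np.zeros(matrix.n_probes, dtype=bool)
    for t in truth:
        mask = (
            (matrix.chrom == t.chrom)
            & (matrix.position >= t.start)
            & (matrix.position <= t.end)
        )
        in_truth |= mask
    tp = int(np.sum(in_call & in_truth))
    fp = int(np.sum(in_call & ~in_truth))
    fn = int(np.sum(~in_call & in_truth))
    tn = int(np.sum(~in_call & ~in_truth))
    return ConfusionCounts(tp, tn, fp, fn, level="probe")


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """AUC by the Mann-Whitney identity (ties count 1/2) with a bootstrap CI.

    The 95% CI comes from a stratified bootstrap (positives and negatives
    resampled separately), seeded for reproducibility.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute an AUC")
    auc = float(roc_auc_score(labels, scores))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos, neg = np.flatnonzero(labels), np.flatnonzero(~labels)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        )
        boots[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return auc, float(lo), float(hi)


def truth_found_flags(scored, truth, alpha: float = 0.05, use_fdr: bool = True) -> np.ndarray:
    """Per truth interval: overlapped by at least one significant call?"""
    sig = significant_mask(scored, alpha, use_fdr)
    found = np.zeros(len(truth), dtype=bool)
    for call, is_sig in zip(scored, sig):
        if not is_sig:
            continue
        for j, t in enumerate(truth):
            if not found[j] and _overlaps(call, t):
                found[j] = True
    return found


def power_table(records: pd.DataFrame, stratum: str = "stratum") -> pd.DataFrame:
    """Power (fraction of truth intervals found) per stratum with binomial CI.

    ``records`` needs a boolean ``found`` column and a ``stratum`` column.
    Empty strata are omitted.  The CI is Wilson at 95%.
    """
    rows = []
    for key, grp in records.groupby(stratum, sort=True):
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["found"].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {stratum: key, "n": n, "found": k, "power": k / n, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)
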