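"""Reproducible benchmark experiments: simulate -> call -> evaluate.

Two harnesses:

* :func:`fig1_experiment` / :func:`fig1_summary` — the head-to-head comparison
  of the permutation-calibrated meta-analysis against a Student's t-test of
  the per-sample region average, over a grid of single-DMR panels with a
  designed percentage of individually significant probes.  Panels are taken
  as drawn (no exact-count enforcement), so the realized percentage varies
  around the design value; replicates where every probe misses individual
  significance supply the false-positive comparison (regions with fewer than
  1% individually different probes).

* :func:`power_benchmark` — a template-matched matrix with hidden DMRs across
  an (effect size x length) grid, analysed at several sample sizes; reports
  probe-level ROC AUC and power stratified by effect size, region length and
  sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluate import probe_level_confusion, roc_auc, truth_found_flags
from .io import ProbeMatrix, SampleTable
from .pipeline import _batch_null_q, _permutation_matrix, call_ders
from .evaluate import ttest_average_dmr
from .simulate import (
    Fig1Scenario,
    draw_dmr_specs,
    insert_hidden_dmrs,
    make_template,
    simulate_fig1_panel,
    simulate_null_matrix,
)

__all__ = ["fig1_experiment", "fig1_summary", "power_benchmark"]

FIG1_LENGTHS = (5, 10, 15, 20, 25, 30)
FIG1_PCTS = (20, 40, 60, 80, 100)


def fig1_experiment(
    lengths=FIG1_LENGTHS,
    pcts=FIG1_PCTS,
    n_replicates: int = 100,
    B: int = 1000,
    seed: int = 1,
    alpha: float = 0.05,
    perm_chunk: int = 200,
    **scenario_kwargs,
) -> pd.DataFrame:
    """Run the panel grid; one row per simulated DMR.

    Columns: ``length``, ``pct`` (designed percent significant), ``frac_sig``
    (realized fraction of individually significant probes), ``meta_p``
    (permutation p of the region Q) and ``ttest_p`` (t-test of the per-sample
    region average).  Scenarios whose percent does not divide the length into
    an integer probe count are skipped (they are unrealizable by design).
    The permutation null is shared across panels and processed in chunks to
    bound memory.
    """
    rng = np.random.default_rng(seed)
    panels = []
    rows = []
    for length in lengths:
        for pct in pcts:
            if (pct * length) % 100 != 0:
                continue
            scenario = Fig1Scenario(length, pct, **scenario_kwargs)
            reps = simulate_fig1_panel(scenario, n_replicates, rng, alpha=alpha)
            for rep in reps:
                panels.append(rep)
                rows.append(
                    {
                        "length": length,
                        "pct": pct,
                        "frac_sig": rep.realized.mean(),
                        "ttest_p": ttest_average_dmr(rep.values, rep.group),
                    }
                )
    # score all panels against one shared, seeded permutation sequence
    group = panels[0].group.astype(float)
    values = np.vstack([rep.values for rep in panels])
    segments = []
    offset = 0
    for rep in panels:
        L = rep.values.shape[0]
        segments.append(np.arange(offset, offset + L))
        offset += L
    q_obs = _batch_null_q(values, segments, group[:, None], None)[:, 0]
    exceed = np.zeros(len(segments), dtype=np.int64)
    done = 0
    while done < B:
        nb = min(perm_chunk, B - done)
        x_perms = _permutation_matrix(group, nb, rng)
        null_q = _batch_null_q(values, segments, x_perms, None)
        exceed += np.sum(null_q >= q_obs[:, None], axis=1)
        done += nb
    meta_p = (1 + exceed) / (1 + B)

    df = pd.DataFrame(rows)
    df["Q"] = q_obs
    df["meta_p"] = meta_p
    return df


def fig1_summary(
    df: pd.DataFrame,
    alpha: float = 0.05,
    fp_threshold: float = 0.01,
) -> dict:
    """Headline numbers of the panel comparison.

    * ``mean_pct_meta`` / ``mean_pct_ttest`` — mean realized fraction of
      individually significant probes among regions each method calls
      significant at p < alpha.
    * ``fp_odds_ratio`` / ``fp_fisher_p`` — Fisher's exact comparison of how
      often false-positive regions (fewer than ``fp_threshold`` of probes
      individually different) pass p < alpha under each method (meta vs
      t-test; an odds ratio below 1 favours the meta-analysis).
    """
    meta_sig = df["meta_p"] < alpha
    t_sig = df["ttest_p"] < alpha
    is_fp = df["frac_sig"] < fp_threshold
    a = int((meta_sig & is_fp).sum())
    b = int((~meta_sig & is_fp).sum())
    c = int((t_sig & is_fp).sum())
    d = int((~t_sig & is_fp).sum())
    oddsratio, fisher_p = sps.fisher_exact([[a, b], [c, d]])
    return {
        "n_dmrs": len(df),
        "n_meta_significant": int(meta_sig.sum()),
        "n_ttest_significant": int(t_sig.sum()),
        "mean_pct_meta": float(df.loc[meta_sig, "frac_sig"].mean()),
        "mean_pct_ttest": float(df.loc[t_sig, "frac_sig"].mean()),
        "fp_table": [[a, b], [c, d]],
        "fp_odds_ratio": float(oddsratio),
        "fp_fisher_p": float(fisher_p),
    }


def _probe_scores(scored, matrix: ProbeMatrix) -> np.ndarray:
    """Per-probe score: highest 1 - p among calls covering the probe, else 0."""
    score = np.zeros(matrix.n_probes)
    for d in scored:
        sl = slice(d.first_probe, d.last_probe + 1)
        score[sl] = np.maximum(score[sl], 1.0 - d.p)
    return score


def power_benchmark(
    seed: int = 1,
    n_probes: int = 10_000,
    n_per_group_grid=(5, 10, 20),
    effects=(0.1, 0.5, 1.0, 2.0),
    lengths=(5, 15, 30),
    n_dmrs: int = 156,
    B: int = 500,
    min_probes: int = 3,
    alpha: float = 0.05,
    use_fdr: bool = True,
    auc_bootstrap: int = 500,
) -> dict:
    """Template-matched hidden-DMR benchmark across sample sizes.

    One matrix is simulated at the largest sample size; smaller designs are
    obtained by subsampling arrays, so strata stay comparable.  Returns power
    tables by effect size and region length (at the largest sample size), the
    power by sample size, the probe-level AUC with bootstrap CI, and the full
    per-truth-region records.
    """
    rng = np.random.default_rng(seed)
    max_n = max(n_per_group_grid)
    template = make_template(n_probes, seed=rng)
    matrix = simulate_null_matrix(template, 2 * max_n, seed=rng)
    controls = matrix.sample_ids[:max_n]
    cases = matrix.sample_ids[max_n:]
    specs = draw_dmr_specs(n_probes, lengths, effects, n_dmrs, seed=rng)
    matrix, truth = insert_hidden_dmrs(matrix, cases, specs)

    records = []
    by_n = {}
    probe_auc = None
    for n in sorted(n_per_group_grid):
        ids = controls[:n] + cases[:n]
        sub = matrix.subset_samples(ids)
        annot = SampleTable(
            pd.DataFrame({"group": [0] * n + [1] * n}, index=pd.Index(ids, name="sample_id"))
        )
        run_seed = int(rng.integers(2**31 - 1))
        scored = call_ders(sub, annot, "group", min_probes=min_probes, B=B, seed=run_seed)
        found = truth_found_flags(scored, truth, alpha=alpha, use_fdr=use_fdr)
        by_n[n] = found.mean() if len(truth) else float("nan")
        for t, f in zip(truth, found):
            records.append(
                {
                    "n_per_group": n,
                    "effect": t.effect,
                    "length": t.n_probes,
                    "found": bool(f),
                }
            )
        if n == max_n:
            labels = np.zeros(sub.n_probes, dtype=bool)
            for t in truth:
                labels[t.first : t.last + 1] = True
            scores = _probe_scores(scored, sub)
            probe_auc = roc_auc(scores, labels, n_boot=auc_bootstrap, seed=rng)
            confusion = probe_level_confusion(scored, truth, sub, alpha, use_fdr)

    rec = pd.DataFrame(records)
    at_max = rec[rec["n_per_group"] == max_n]
    power_by_effect = at_max.groupby("effect")["found"].mean()
    power_by_length = at_max.groupby("length")["found"].mean()
    power_by_n = rec.groupby("n_per_group")["found"].mean()
    return {
        "records": rec,
        "probe_auc": probe_auc[0],
        "probe_auc_ci": (probe_auc[1], probe_auc[2]),
        "probe_confusion": confusion,
        "power_by_effect": power_by_effect,
        "power_by_length": power_by_length,
        "power_by_n": power_by_n,
    }
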