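# Methods

## Model and assumptions

`tilemeta` treats each tiling-array probe as an independent "study" of the
same phenotype contrast.  For probe *j* with normalized signal vector *y_j*
(one value per sample) and design **X** = [1, phenotype, covariates…], it fits
OLS and keeps the phenotype coefficient *m_j* and its squared standard error
SE²(m_j).  The model is additive (no interactions); two-level phenotypes and
covariates are coded 0/1 (lexicographically smaller label → 0), so that with
a binary phenotype and no covariates *m_j* is exactly the group-1 minus
group-0 mean and SE²(m_j) the pooled-variance squared SE of that difference.
Continuous phenotypes (dose, age) are used as given.

Candidate regions are maximal runs of ≥ `min_probes` adjacent probes whose
slopes share a strict sign.  The default `min_probes = 3` corresponds to
roughly one enrichment-fragment length at common tiling densities (~35 bp
probe spacing) and is the smallest region the method is intended to resolve.
Runs break at chromosome boundaries, exactly-zero slopes, unusable probes
(insufficient complete observations or singular per-probe design) and,
optionally, at inter-probe gaps larger than `max_gap_bp` (unlimited by
default; useful for sparse promoter designs).

Each candidate is scored with Cochran's Q, the inverse-variance-weighted
heterogeneity statistic, over its member probes' (m, SE²) pairs.  Q grows
when precisely measured probes deviate from the region's weighted mean slope;
noisy probes contribute little.  Q is a *heterogeneity* measure: a region
whose slopes are perfectly uniform has Q ≈ 0 regardless of their common size.
In practice regional enrichment signals are peaked (strongest at the centre,
tapering at the edges), which is exactly the profile Q rewards; the
permutation step (below) additionally gives Q sensitivity to homogeneous
shifts, because label shuffling inflates the per-probe variance estimates of
truly shifted probes and thereby deflates the null Q.

Significance is by phenotype permutation: the phenotype column is shuffled B
times (covariates stay attached to their samples — covariate-aware schemes
such as residual permutation are out of scope), slopes are refit and Q is
recomputed on the same member probes.  One seeded permutation sequence is
shared by all candidates of a run: this is substantially cheaper than
independent draws per region and makes ranks directly comparable.  The
p-value uses the add-one convention, p = (1 + #{Q_null ≥ Q_obs})/(1 + B), so
p ∈ [1/(B+1), 1] and is never exactly zero.  Benjamini–Hochberg correction is
applied across all candidates of the run.  Output ordering is deterministic:
p ascending, then Q descending (higher Q = stronger at equal p), then
|mean_diff| descending, then coordinates.

### Known operating characteristics

* **Conservatism at null regions.**  Candidates are *selected* as same-sign
  slope runs, which constrains the observed slopes to one orthant and lowers
  the observed Q relative to the unconditioned permutation null.  On
  pure-noise matrices the fraction of candidates with p < 0.05 is ~0.004, not
  0.05; p-values at null regions are strongly super-uniform (never
  anti-conservative).  This is a property of the published procedure (the
  permutation refits the same probe set without re-running run detection),
  and it costs power at marginal regions while essentially never producing
  nominal false positives.
* **FDR resolution is limited by B.**  The smallest attainable q-value is
  roughly (1/(B+1)) · n_candidates / n_true_hits; with few true regions among
  many candidates, B must be large enough for q < α to be reachable.
* **Minimum design.**  ≥ 4 samples overall, ≥ 2 per group for a binary
  phenotype (otherwise no informative permutations exist); per probe,
  complete observations must exceed the design column count by one, else the
  probe is flagged unusable.  SE² is floored at 1e-24 so zero-residual probes
  keep finite meta-analysis weight without disturbing the ordering.

## Synthetic data generators

### Template-matched matrices with hidden DMRs

`make_template` draws per-probe means (uniform −0.5…0.5) and SDs (uniform
0.08…0.2); `simulate_null_matrix` then draws every probe i.i.d. normal across
samples.  This emulates generating a null matrix probe-by-probe with the mean
and variance of a real normalized experiment.  The SD range is calibrated to
the operating regime of the quantile-normalized enrichment-array data the
benchmark design is modelled on: a 0.1 log2-fold regional shift is detectable
but far from saturated at 20 samples per group.  `insert_hidden_dmrs` adds,
for case samples only, a symmetric triangular mean shift peaking at the
middle probe and rescaled so the mean shift across the region equals the
nominal effect exactly (the simplest shape satisfying "peak at the middle,
mean ≈ effect"); probe-specific variance is retained.  Placement is uniform
with a 2-probe buffer between regions.

What this generator deliberately does **not** model: spatial correlation of
noise along the genome, sample-level batch structure, platform-specific probe
response, and enrichment chemistry.  Passing benchmarks therefore demonstrate
correct behaviour of the statistics under the stated noise model, not
end-to-end performance on raw array data.

### Single-DMR panels (method comparison)

`simulate_fig1_panel` builds standalone panels of one region × 10 samples
(5 cases, 5 controls).  A designed fraction (20–100%) of probes carries a
case shift drawn Normal(0.10, 0.001) — a ~10% methylation difference — with
within-group SD σ_sig = 0.06.  The remaining probes carry a *regional
background offset*: one draw b ~ Normal(0, 0.12) shared by all background
probes of the panel, under larger noise σ_ns = 0.15.  The shared offset
models consistent-direction background stretches, the mechanism by which
false-positive regions enter the candidate list and fool a plain
region-average test while contributing little to the inverse-variance-weighted
statistic.  By default panels are taken as drawn and the *realized*
per-probe significance (two-sample t-test, α = 0.05) is recorded next to the
designated truth — realized fractions therefore scatter continuously around
the design value, and panels where every probe misses significance form the
false-positive pool (<1% individually different).  An `enforce_exact` mode
instead rejection-resamples until exactly the designated probes test
significant, for uses that need the designed fraction realized verbatim.

The three noise constants were calibrated **once**, on a coarse grid, so that
the panel experiment reproduces the published operating point of the method
comparison (detected-region mean percent-significant near 0.5 for both
methods and a false-positive odds ratio well below 1), and then frozen.  At
this operating point the gap between the two methods' means is smaller than
its Monte-Carlo error, so its sign can vary between runs; the false-positive
odds ratio is a small-count statistic (a few dozen qualifying panels out of
3,000) and fluctuates accordingly between 0 and ~0.2.

## Evaluation harness

Region-level confusion follows the asymmetric convention: significant calls
overlapping ≥ 1 truth probe are TP (several calls on one truth interval all
count), significant non-overlapping calls FP, non-significant non-overlapping
calls TN, and truth intervals with no significant overlap FN.  Because the TN
count depends on the caller's candidate set, the probe-level 2×2 (probe in a
significant call × probe in truth) is the more comparable metric and is what
the AUC uses: each probe is scored with the best 1 − p among covering calls
(0 if uncovered).  AUC is the Mann–Whitney statistic with ties counted ½
(via scikit-learn) and a stratified bootstrap 95% CI.  "Significant" defaults
to BH q < 0.05; a nominal-p mode exists for small designs where FDR
resolution is out of reach.  Power tables report the fraction of truth
intervals found per stratum with Wilson binomial CIs.

## Problem sizes used by the shipped studies

The desk-scale benchmark (`tilemeta benchmark`, `examples/power_study.py`,
and the corresponding test) uses a 10,000-probe template with 156 hidden DMRs
over effects {0.1, 0.5, 1, 2} × lengths {5, 15, 30}, analysed at 5/10/20
samples per group with B = 500; the panel comparison uses the full design
grid (lengths 5–30, five design fractions, 100 replicates each, B = 1000).
The full-size experiment (100,000 probes, ~1,456 DMRs, effects 0.1–2,
lengths 5–30, B = 1000) is available in `scripts/full_benchmark.py`.

## Numerical and design notes

* Coordinates: input positions are 1-based probe starts; regions span the
  first to last member probe with no fragment-length padding (probe length is
  not modelled).  BED export converts to 0-based half-open.
* Missing data: `NA` allowed in the matrix body (per-probe complete-case
  fits); missing phenotype values are an error.  Constant covariates are
  dropped with a warning; collinear designs raise.
* Permutations are drawn with a seeded generator; every pipeline output is a
  deterministic function of (inputs, configuration, seed).
* Fisher's exact odds ratio in the method comparison is the sample
  (unconditional) odds ratio, 0 when the meta-analysis admits no qualifying
  false positive.
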