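# Methods

This note records the models implemented in `lrcausal`, the parameters that
matter, what the synthetic generators do and do not emulate, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or the examples do not themselves
compute.

## Cell ordering

All time-series machinery consumes an ordering of cells. Cells are sorted
lexicographically by (declared stage index, pseudotime, cell id); cells
without pseudotime sort after timed cells within their stage. The stage order
is always declared explicitly, never inferred from string sort. When no
pseudotime is available at all, `fallback_pseudotime` projects cells onto the
first principal component of the top-variable genes, sign-oriented so stage
means are nondecreasing — a deliberately simple stand-in for a full
trajectory method, adequate for monotone programs (its test asserts Spearman
≥ 0.9 against a planted monotone truth) and not for branching topologies.

Autocrine analyses index the ordered cells by rank (0..n−1): the Granger
regression is invariant to the position labels given a fixed order.
Pseudotime ties are broken by adding k·1e−9 within the tie where strictly
increasing positions are required.

## Interaction score

Within one lineage, IS_t = √(ligand_t · receptor_t) per ordered cell —
non-negative, symmetric, zero whenever either side is silent. Across
lineages, the interpolated sender-ligand and receiver-receptor signals are
multiplied pointwise on the common grid, the grid-level analogue of
(mean ligand in type A) × (mean receptor in type B). Per-condition pseudo-bulk
scores use that cell-type-level product form.

## Co-variation screen

Autocrine: Pearson correlation between ligand and receptor series over
ordered cells, cutoff |PCC| > 0.1. Paracrine: Spearman on interpolated grids,
cutoff SCC > 0.2 (one-sided, following the reference convention). Constant
series have undefined correlation; they are recorded as 0 with a flag and
never pass. Correlation is computed on the matrix as provided (raw or log);
the scale is the caller's choice and is documented in the I/O module.

The 0.1 default descends from a double-tangent construction: rank the
positive correlations ascending, let A and B be the curve ends, C the point
of maximal perpendicular distance from chord AB, D the point of maximal
perpendicular distance from chord AC (searched between A and C); D's ordinate
is the cutoff. "Tangency" is operationalized as the discrete
perpendicular-distance argmax — equivalent for concave curves sampled
discretely — with ties broken toward the smaller rank index. A curve whose
points all lie on AB has no tangent point; the function refuses and advises a
manual cutoff.

## Regulons and temporal TFs

The reference analysis used an external mutual-information network package
for this stage. Re-implementing it verbatim is out of scope; the network here
is a permutation-calibrated Spearman co-expression net with the same
interface and downstream contract (a temporal-TF list with activities), and
regulons produced by external software can be imported from TSV
(`read_regulons`). Per TF, the null distribution of |rho| is built from
`n_perm = 100` cell-permutations of the TF profile against all genes; targets
exceed the (1 − alpha_net) null quantile, alpha_net = 0.01.

Master-regulator analysis: upper-tail hypergeometric test of the overlap
between a TF's targets and the trajectory-variable gene set within the gene
universe, BH-adjusted, called at adjusted p < 0.01. Variable genes default to
the top-N by variance of the kernel-smoothed profile along the ordering
(bandwidth 0.1 of the trajectory). The pipelines cap N at 40% of the genome:
the enrichment test needs a strict subset to discriminate, and
developmental trajectories have large stage-dependent fractions — the
reference setting (2000 genes) sits in the same regime relative to the
expressed genome. A much smaller cap makes the tTF calls hostage to variance
rank noise among near-tied temporal genes.

Called tTFs are clustered by Ward linkage on Euclidean distances between
per-TF z-scored profiles (z-scoring so shape, not amplitude, drives the
distances), cut at k = 6, renumbered by ascending activity-peak position so
cluster 1 is the earliest program and labels are invariant to input order.
Cluster activity is the mean member z-scored profile (`--raw-activity`
equivalent: `zscore=False`).

## Granger causal test

x Granger-causes y if lagged x improves linear prediction of y beyond lagged
y. With lag L over the n − L usable rows:

    restricted:    y_t ~ 1 + y_{t−1..t−L}
    unrestricted:  y_t ~ 1 + y_{t−1..t−L} + x_{t−1..t−L}
    F = ((RSS_r − RSS_u)/L) / (RSS_u / (n − L − (2L + 1)))

with p from F(L, n − 3L − 1). This is numerically the standard Wald/F Granger
test; the suite verifies agreement with an independent from-scratch OLS
oracle to 1e−10 and cross-checks statsmodels' `ssr_ftest`. Degenerate fits
(constant series, rank-deficient designs, zero residual variance) return
p = 1 with a flag instead of raising, so one flat gene cannot abort a
2000-pair screen. Defaults: lag 1, α = 0.01.

Classification takes, per direction, the minimum p over the k cluster
activities — deliberately without multiplicity correction, matching the
reference procedure; min-p selection inflates each direction's null rate to
roughly k·α. A pair is labelled forward / backward / feedback by which
directions clear α.

**eLR rule.** The package calls a pair an eLR when *both* directions are
significant (`elr_rule="both"`, i.e. feedback), because the two-direction
rule is what keeps the null eLR rate below α under min-p selection
(≈ (kα)² ≈ 0.3% at k = 6, α = 0.01, verified by a null-calibration test);
`elr_rule="either"` (any klass ≠ none) is available for users who want the
broader reading, at ≈ 2kα null rate.

## Paracrine workflow

Order each lineage; interpolate every needed series onto `num_pts = 200`
uniform points of [0, 1] with a Gaussian kernel of bandwidth `winsz = 0.1`
(value at t is Σ w_i v_i / Σ w_i, w_i = exp(−(t−t_i)²/2·winsz²) — a convex
combination, so interpolation is linear in values and never leaves the input
range). Screen by Spearman > 0.2; call receiver master TFs; per pair and per
master TF run both Granger directions at α; among TFs passing either
direction compute SCC between IS and TF series; SCC_ens is the SCC of
maximal absolute value with sign retained ("maximum" of correlations under a
two-sided ±0.8 cutoff is read as maximal magnitude; `scc_ens_rule="max"`
gives the plain maximum). Active ⇔ |SCC_ens| > 0.8.

Zero-preserving imputation (below) is applied to the receiver matrix for the
network/master-regulator stage only, mirroring the reference step order
(interpolation and screening precede imputation; the imputed matrix is used
to build the transcriptional network). Feeding auto-rank-imputed matrices
into the correlation screen is actively harmful: a near-rank-1
reconstruction makes every gene an affine image of one loading vector and
every screen correlation ±1.

## Zero-preserving imputation

A low-rank (SVD) reconstruction of the log-scale matrix where, per gene,
reconstructed entries with magnitude below that gene's most-negative
reconstructed value are set to zero — symmetric-around-zero reconstruction
error marks the noise floor — surviving entries are affine-rescaled to the
gene's original nonzero mean/sd, negatives are clamped at zero, and all-zero
genes pass through unchanged. Rank "auto" takes the last of the top-50
singular values whose spacing to the next exceeds the tail-spacing noise
floor (mean + 6 sd of the second-half spacings). On a planted rank-2 matrix
with 30% dropout the suite verifies ≥ 90% of dropped true-positive entries
are restored.

## Validation statistics

Enrichment ratio of annotation set A in query set B: |A ∩ B| / |B| within a
declared universe (default: all matrix genes), with exact hypergeometric
upper (over-enrichment) and lower (depletion) tails.

Transcription-inhibition delta per pair:
delta = |log10(IS_inhibited + 1) − log10(IS_late2cell + 1)| — the early
2-cell baseline cancels algebraically, an identity the suite checks to
1e−12. Affected pairs: two rounds of hierarchical clustering (complete
linkage, Euclidean, cut at 2 each round — the cut height is this package's
deterministic choice); round 1 keeps the higher-variance cluster, round 2
returns the larger-mean-delta cluster. Clustering runs on the raw score
profiles: baseline magnitude participates in round 1, and the delta rule
discriminates in round 2. Group comparison: one-sided Welch t-test
(called-pair deltas hypothesized lower), identical constant groups reporting
p = 0.5 by the symmetric-null convention.

## Synthetic data

The generators are the package's stated world; their defaults are fixed and
are not tuned per test.

* `simulate_var_pair` — bivariate VAR(1)-with-lag coupling, AR 0.5 each,
  burn-in 100, stationarity enforced via the companion matrix. Theoretical
  Granger causality equals the requested direction.
* `simulate_embryo` — 200 cells at sorted-uniform pseudotimes, 6 equal-width
  named stages, 500 genes: 6 TF clusters × 5 TFs (Gaussian-bump archetype,
  width 0.15, amplitude 2, plus AR(1) innovations), 8 targets per TF
  (0.8× TF + noise), 60 LR pairs of which 8 planted
  (feedback/backward/forward cycle, coupling 0.8 at lag 1 injected in
  log-space between the pair's latent and its cluster's innovation signal),
  measurement noise sd 0.2, no dropout by default (Smart-seq-like regime).
  Ligand and receptor follow the same latent with small independent noise, so
  planted pairs pass the screen and IS is an affine image of the latent.
* `simulate_two_lineages` — 180 sender / 260 receiver cells (deliberately
  unequal), a latent ligand→receptor→TF→ligand VAR chain per true pair on a
  coarse 40-step time axis (so its dynamics live on timescales the winsz=0.1
  kernel can resolve; the closed loop's gain is capped to spectral radius
  0.95 — the nominal coupling 0.8 is explosive around a positive 3-cycle),
  plus a shared logistic developmental ramp carried by all three genes, which
  is what the screen correlation and SCC_ens respond to while the VAR
  innovations carry directionality. Droplet-style dropout (rate 0.3 in the
  shipped examples) and archetype-driven extra master TFs complete the world.

What the generators do **not** emulate: UMI count noise (negative binomial),
batch effects, branching trajectories, doublets. A green end-to-end test
establishes that the pipeline recovers planted lead–lag structure under
Gaussian noise and dropout — not that it would on raw droplet counts.

## Known limitations

* **Interpolation inflates Granger false positives.** Smoothing to bandwidth
  0.1 of the trajectory leaves ~10 effective degrees of freedom while the F
  test sees 200 grid points. `interpolation_sensitivity` measures rejection
  rates on *independent* interpolated AR(1) pairs of 0.27–0.94 for winsz
  0.02–0.3 (0.72 at the default 0.1). Interpolated-grid Granger p-values are
  therefore a screen, not calibrated significance, and the |SCC_ens| > 0.8
  gate is the de-facto filter; in a zero-coupling simulated world a
  double-digit percentage of screened null pairs still comes out "active".
  Conclusions from the paracrine workflow should rest on effect sizes and
  orthogonal evidence, not on these p-values alone.
* Min-p over clusters is uncorrected (by design, matching the reference); an
  optional Bonferroni-over-clusters reading can be had by multiplying the
  reported minima by k.
* The two-round affected-pair clustering is sensitive to baseline score
  magnitude (round 1 clusters raw profiles); with strong magnitude
  heterogeneity and several variability classes the cut-at-2 scheme can keep
  the wrong half. It behaves as intended in the flat-vs-collapsed regime it
  was designed for.
* The fallback pseudotime is PC1-based and assumes an approximately monotone
  dominant program; use a dedicated trajectory tool for anything branched
  (the pipelines accept any precomputed pseudotime).
* Quantile normalization is provided as a helper but deliberately not wired
  into any pipeline stage.
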