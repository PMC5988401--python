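# Methods

## Visibility mapping

Both visibility criteria are implemented with *strict* inequalities: equal
values block horizontal visibility and exactly collinear points block
natural visibility. This is what makes the NVG exactly invariant under
affine-plus-linear-trend transforms and the HVG exactly invariant under
strictly increasing rescalings, and it fixes the tie behaviour
deterministically (ties in real recordings are rare; in quantized data they
simply produce slightly sparser graphs). Node ids are 0-based time indices
everywhere; graphs are undirected and unweighted, and the canonical storage
is a sorted edge list (adjacency matrices are exported views only).

Two independent NVG constructions are maintained deliberately. The naive
construction sweeps each left endpoint rightwards keeping the running
maximum slope — a literal O(N²) restatement of the criterion that serves as
the oracle. The fast construction uses divide and conquer: the maximum of a
segment blocks every line of sight across it (the segment's chord at the
maximum's position is a convex combination of the endpoint values, hence
never strictly above the maximum), so only edges incident to the maximum
can span it; those are found by two running-max-slope sweeps and the
flanking sub-segments recurse. The contract between the two is exact
edge-set equality, enforced on randomized suites including constant,
monotone and heavily tied series. The HVG uses the standard monotone-stack
scan (O(N)); with ties, an equal-height pair is linked once and the older
index is retired, which reproduces the strict criterion.

For whole-multiplex work only degree sequences are needed downstream, so
`nvg_degree_matrix` shares the left-endpoint sweep across all columns of a
T×M matrix; it is tested to agree column-by-column with the single-series
graphs.

## Interlayer mutual information

MI between two layers is the plug-in mutual information of their degree
sequences paired by time stamp. Design choices, all configurable only where
noted:

- **Log base**: natural log (nats) by default; every output file records
  its units, and a base-2 option is exposed. The definition leaves the base
  open, so it is treated as configuration.
- **Estimator**: raw empirical joint/marginal frequencies over exact
  integer degrees — no binning, no Miller–Madow-style bias correction. The
  plug-in estimator is positively biased at small N, but the bias acts as a
  common offset when comparing conditions at fixed N, which is the only use
  made of the values here.
- **Alignment**: joint pairing is strictly by node index (the shared time
  stamp); no alternative alignment is attempted.
- **Degenerate layers**: a constant degree sequence has zero entropy, so
  any MI involving it is exactly 0 (never NaN); tiny negative round-off is
  clamped to 0.
- **⟨MI⟩**: the per-network average runs over unordered off-diagonal ROI
  pairs, each counted once; the diagonal (layer entropy) is excluded, and a
  singleton network has no defined average (an error, not 0).

The diagonal identity MI(α, α) = H(α) is asserted to 1e-12 and doubles as a
correctness check of the joint-distribution code.

## Temporal communities

Each layer is partitioned with the Louvain modularity heuristic
(networkx implementation, resolution 1 by default), run `n_runs = 100`
times with sub-seeds spawned from a single user seed; the best run by
modularity is kept (ties: fewest modules, then lexicographically smallest
canonical labelling), which makes the output deterministic given the seed.
Best-of-n was chosen over consensus clustering as the simplest
deterministic realization of repeated runs. Module labels are canonicalized
by first appearance in time order.

Partition similarity uses the Sorensen index `2|A∩B|/(|A|+|B|)` per module
pair and, for whole partitions, NMI with the `2I/(H₁+H₂)` normalization by
default (`max` and `joint` normalizations are available, since toolboxes
differ on this point). NMI of any pair involving a one-module partition is
defined as 0. A descriptive contiguity score (fraction of interior nodes
whose both temporal neighbours share their module) is reported but not
hard-thresholded: temporal contiguity is an empirical tendency of smooth
signals, not a guarantee.

## Robust group statistics

- **Harrell–Davis quantiles**: weights `w_i = I_{i/n}(a,b) − I_{(i−1)/n}(a,b)`
  with `a = (n+1)q`, `b = (n+1)(1−q)`; location-scale equivariant, monotone
  in q, weights sum to 1.
- **Bayesian bootstrap HDI**: each draw reweights observations with a flat
  Dirichlet vector and evaluates the weighted HD quantile (cumulative
  weights replace the i/n grid in the Beta increments); the interval is the
  narrowest window containing the requested mass of the draws. Default
  2000 draws; fewer than 100 triggers a warning.
- **Shift function**: HD decile differences `x_q − y_q` for
  q = 0.1 … 0.9, each bracketed by ±c·SE with SE the bootstrap standard
  error of the difference and c = 80.1/min(n_x, n_y)² + 2.73, Wilcox's
  calibration constant for simultaneous coverage of the nine intervals at
  familywise level ≈ 0.05. The calibration is verified by simulation
  (familywise error within 0.05 ± 0.02 under equal distributions at
  n = 100 per group).
- **KS**: two-sample statistic via scipy; the asymptotic critical value
  `c(α)·√((n₁+n₂)/(n₁n₂))`, `c(α) = √(−ln(α/2)/2)`, gives 0.39 at
  α = 0.001 for n = 49 vs 50.
- **Group test**: the default is an F test of the group factor in a linear
  model of the scalar ⟨MI⟩ with covariates (age, framewise displacement)
  as nuisance regressors; an omnibus multivariate option (Pillai trace
  over several networks jointly) is provided. Rank-deficient designs are a
  hard error. Holm's step-down correction handles multiplicity across
  networks.
- **Outliers**: the default rule flags observation i when the median of
  its pairwise absolute distances to the other points exceeds 2.24 × the
  median of all pairwise distances — a documented stand-in chosen because
  it uses only pairwise distances and assumes no distributional symmetry;
  a MAD-median variant is switchable. The cut 2.24 (≈ √χ²₀.₉₅,₁) follows
  the robust-outlier convention.

## Synthetic generator

`generate_subject` draws, for ROI i in network g,
`x_i = √ρ_g·z_g + √(1−ρ_g)·ε_i` with a shared network latent `z_g` and
i.i.d. Gaussian noise, band-pass filters the result (4th-order Butterworth,
zero-phase forward–backward, default 0.01–0.08 Hz at dt = 2 s), trims 8
samples per edge against filter transients, and standardizes per ROI. The
coupling ρ is exact ground truth for the expected interlayer structure:
ρ = 0 gives independent layers, ρ = 1 identical ones, and mean
within-network ⟨MI⟩ is monotone in ρ (verified over ρ ∈ {0, 0.3, 0.6, 0.9},
20 seeds, M = 6, T = 150).

The latent-factor construction was preferred over VAR processes because the
coupling parameter maps directly onto the quantity the analysis estimates.
Cohort defaults mirror a four-group clinical design (121/50/49/40
subjects); desk-scale analyses and tests use M = 27 ROIs in nine 3-ROI
networks and T = 150 raw samples (134 after trimming), sizes at which every
simulation in the test suite and the acceptance script completes in
minutes. Synthetic age and framewise-displacement covariates support
configurable group confounding for exercising covariate adjustment. All
randomness descends from one master seed via `SeedSequence` spawning.

What the generator does **not** emulate: hemodynamic response convolution,
scanner drift and motion artifacts, spatially correlated noise between
networks, and heavy-tailed BOLD amplitude distributions. Passing tests
therefore demonstrate correct recovery of coupling-induced interlayer
structure under idealized band-limited Gaussian conditions, not performance
on real fMRI.

## Pipeline and formats

Time-series tables are CSV/TSV with rows = time points and a header of ROI
labels (the common neuroimaging export); a square table is rejected as
ambiguous unless orientation is forced, and a ROIs-in-rows layout is
readable via a transpose flag. Missing values are hard errors naming the
offending cell — silently dropping time points would corrupt the node
alignment of the multiplex. Every output embeds the configuration hash,
seeds and units; identical configurations reproduce output trees byte for
byte. The CLI (`simulate`, `build`, `mi`, `communities`, `compare`,
`pipeline`) is a thin layer over the library functions.

## Known limitations

- The plug-in MI bias grows as layers' degree supports widen relative to
  N; comparisons should be made at fixed N only.
- The divide-and-conquer NVG degrades to O(N²) on monotone series (the
  split is maximally unbalanced); this is a constant-factor concern only at
  the series lengths targeted here.
- Louvain is a heuristic: best-of-100 stabilizes but does not guarantee
  the modularity optimum, and partition granularity depends on the
  resolution parameter (default 1).
- The shift-function calibration constant is Wilcox's closed form for nine
  deciles and is accurate for moderate n (≳ 20); very small groups should
  rely on the KS statistic instead.
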