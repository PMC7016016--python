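# Methods

This note documents the models implemented in `plasmahca`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Clustering models

**Distances.** The generalized Minkowski dissimilarity
$d_{st} = (\sum_j |X_{sj} - X_{tj}|^p)^{1/p}$ is computed for any
$p > 0$. For $p < 1$ the triangle inequality can fail; this is
intentional — small fractional orders weight many moderate coordinate
differences more heavily relative to a single large one, probing cluster
structure that Euclidean distance misses. Linkage operates on the
dissimilarities as given.

**Linkage.** Ward (merge minimizing the increase in within-cluster sum
of squares) and WPGMA (weighted average:
$d(ij,k) = (d(i,k) + d(j,k))/2$), both via
`scipy.cluster.hierarchy.linkage`. Heights follow the convention where a
singleton pair merges at its input distance (for Ward this means
$h = \sqrt{2\,\Delta SS}$). Both methods are reducible, so merge heights
are non-decreasing; a violation raises a warning rather than an error.
Tie-breaking among equal-distance pairs follows scipy's deterministic
nearest-neighbor-chain order; on continuous data ties have probability
zero, and the test suite verifies exact agreement with greedy
brute-force agglomeration on random instances up to n = 8.

**Inconsistency clustering.** For merge $k$ at depth $dep$, let $S$ be
the heights of the merge itself (level 1) and of all internal merges
within $dep$ levels below it; leaves contribute nothing. The coefficient
is $(h_k - \bar S)/\mathrm{sd}(S)$ with the sample standard deviation,
defined as 0 when $|S| = 1$ or the spread is zero. This matches the
long-standing statistics-toolbox convention (cross-checked against
`scipy.cluster.hierarchy.inconsistent` in the tests). A partition is cut
by grouping each leaf under its highest ancestor whose own coefficient
and all descendant coefficients are strictly below the cutoff;
uncovered leaves become singletons. Because the subtree maximum of the
coefficient is monotone toward the root, "consistent" merges form a
downward-closed set and the cut is well defined. Cluster labels are
always renumbered 1..K by first sample occurrence so partitions from
different models are comparable.

Note the coefficient is bounded by $(m-1)/\sqrt{m}$ for $|S| = m$
heights; at depth 2 ($m \le 3$) no coefficient can exceed
$2/\sqrt{3} \approx 1.155$, so depth-2 base models with cutoffs of 1.2
and above always return a single cluster and are discarded by the
retention rule.

**Consensus combination.** Each retained base model (one per grid cell
with $\ge 2$ clusters) contributes a co-membership indicator; the
consensus dissimilarity between two samples is one minus the fraction of
retained models in which they share a cluster (0 = always together,
1 = never). Distance matrices are cached per $p$ (20 computations, not
2100) and subtree inconsistency maxima per $(p, dep)$; identical
partitions across grid cells are counted with multiplicity rather than
re-accumulated.

**Final consensus partition (open design point).** The combination step
defines consensus *distances* but not how final clusters derive from
them. The implementation builds a WPGMA tree over the consensus
dissimilarities and cuts it in the widest gap between successive merge
heights (ties resolved toward fewer clusters; if every merge sits at the
same height the result is one cluster). A fixed-height cut is also
supported, but a majority cut at 0.5 is *not* a good default: the
inconsistency coefficient is scale-invariant, so the low end of the
cutoff grid (cut ≈ 1.0–1.3) fragments even perfectly separated Gaussian
data into tens of clusters. Those fragmenting models are retained (they
have ≥ 2 clusters) and push within-cluster consensus distances to
≈ 0.53 — just above 0.5 — so a majority cut shatters clusters that every
sensible base model agrees on (measured ARI 0.14 on the well-separated
two-cluster benchmark, versus 1.0 with the gap cut). The gap cut
separates the co-clustering core from the between-cluster plateau
without a tunable threshold.

**Conventional model's k.** When not supplied, k is chosen in 2..10 to
maximize the relative gap between successive Ward merge heights — a
reproducible stand-in for the common practice of reading k off the
dendrogram.

## QC pipeline

Order: marker filters → duplicate collapse → plate scaling → log
transform → Grubbs exclusion.

- *Duplicate CV filter*: a marker is dropped when the fraction of
  samples with duplicate-pair CV ≥ 0.25 reaches 20% (both boundaries
  inclusive).
- *Control CV filter*: per marker, the CV of each pooled control's four
  wells (two runs × two duplicates) is averaged over the three controls
  (and plates); a marker is dropped when the average is strictly greater
  than 0.25.
- *Plate scaling*: each control's per-plate value (mean of its wells) is
  divided by that control's grand mean across plates, and the three
  ratios are averaged into a per-plate, per-marker factor; sample values
  are divided by the factor. Computing grand means per control position
  (default) or pooled per marker is configurable; the two coincide when
  controls are balanced. After scaling, per-plate control means agree
  across plates to 1e-9 relative tolerance (tested).
- *Working value*: the mean of the two duplicate wells.
- *Log transform*: base 10 by default (configurable); markers must be
  strictly positive, and the offending sample and marker are named
  otherwise.
- *Grubbs exclusion*: two-sided Grubbs at α = 0.05 per marker on the
  log values, iterated (re-test after each removal) until nothing is
  flagged; any sample flagged in at least one marker is excluded.
  Critical value: $\frac{n-1}{\sqrt n}\sqrt{t^2/(n-2+t^2)}$ with $t$ the
  upper $\alpha/2n$ Student-t quantile at $n-2$ df. Iteration stops
  quietly if removals shrink a column below n = 3 or to zero variance.
  Exclusion is idempotent on the constructed test fixtures; it is not a
  mathematical invariant (removing samples flagged by one marker can in
  principle expose new outliers in another).

## Simulation scenarios

Every scenario draws 11 variables and 100 samples per group over 35
trials; trial $t$ uses seed $\text{base\_seed} + t$, so all outputs are
pure functions of the scenario and seed. The preset families emulate the
qualitative benchmark designs; the exact moment parameters behind the
original figure panels are not published, so the presets parameterize
what matters ordinally:

- **distant** (default separation 8 within-group sd per variable, all 11
  variables differ) — essentially non-overlapping groups;
- **close** (separation 1.5 sd) — groups share means on the first six
  variables and take offsets of opposite signs on the remaining five;
- **predicted** (separation 0.5 sd, compound-symmetric covariance with
  ρ = 0.5) — heavily overlapping correlated markers, the regime a real
  plasma cohort is expected to occupy (Bhattacharyya overlap is orders
  of magnitude larger than in the distant family, asserted in tests);
- **uniform** vs **variable**: shared covariance scale versus
  group-specific sd scales (1.0/2.0 for two groups, 1.0/2.0/1.5 for
  three); for variable covariances, separation is measured in units of
  the largest group sd.

The plate emulator assigns samples to plates in contiguous blocks,
multiplies each plate by a lognormal per-marker bias, carries three
pooled controls per plate (the same aliquot everywhere — the property
that makes plate scaling identifiable), and splits values into duplicate
wells $v(1 \pm cv/\sqrt 2)$ with random sign, so duplicate-pair CVs are
exact up to rounding. It does not emulate detection limits, standard
curves, missingness, or heteroscedastic assay noise; QC tests passing on
it show the pipeline's algebra is right, not that real MSD data are this
well behaved.

## Evaluation and statistics

ARI is the Hubert–Arabie chance-corrected index (computed via
scikit-learn, validated against brute-force pair counting). Models are
compared with a two-sided pooled-variance t-test on per-trial ARIs;
degenerate zero-variance comparisons report p = 1 when means agree.
Trials in which every consensus base model collapses to one cluster are
recorded as missing, with the count reported, and excluded from means.

Per-marker cluster statistics follow the variance-gated scheme: Levene
centered on the mean at α = 0.05, then pooled t / Welch–Satterthwaite t
(two clusters) or ANOVA + Tukey HSD / Welch ANOVA + Dunnett T3 (three or
more). Dunnett T3 needs studentized-maximum-modulus quantiles, which
have no closed form; they are estimated by fixed-seed Monte Carlo
(100,000 draws), making T3 p-values deterministic, with the Šidák bound
as an upper-bound cross-check. Tests run on log values while descriptive
means ± SEM are reported on the original pg/mL scale. No multiplicity
correction is applied across markers — intentionally, to match prevailing
practice in panel characterization; interpret single-marker p-values
accordingly.

## Problem sizes and numerical notes

The benchmark suites run the full design (35 trials, 200 samples, the
complete 2100-model grid) for the headline distant-cluster scenarios;
the directional family-ordering checks use 8 trials per scenario, and
the null-calibration check of the omnibus test uses 2,000 simulated
datasets of three 20-sample groups. A full consensus fit of one
200-sample trial takes well under a second; `scripts/acceptance.py`
completes in about a minute.

Grid values are generated from integer tenths (p = i/10, cut = j/10) so
the grid always has exactly 20 × 5 × 21 cells with no floating-point
drift. Dendrogram cuts are implemented as connected components over the
kept merges via union–find, which stays correct even for non-monotone
height sequences. Consensus matrices are validated on every construction
(symmetry, zero diagonal, entries in [0, 1]).

## Known limitations

- The final-partition rule for the consensus model (widest-gap cut) is
  this package's choice for a step the underlying protocol leaves
  unspecified; alternatives (fixed height, inconsistency cut on the
  consensus tree) are one call away via `consensus_partition`.
- Preset parameters are qualitative emulations, not the unpublished
  originals; only ordinal and threshold behavior should be compared.
- Ward linkage is meaningful on Euclidean input only; the library does
  not stop you from handing it other dissimilarities.
- The QC emulator's noise model is multiplicative and symmetric; filters
  behave differently on data with additive floors or censoring.
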