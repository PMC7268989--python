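# Methods

## Model and procedure

`wings` treats each phenotype as a feature vector of gene-level association
scores over a common gene panel. Scores are −log10-transformed *P*-values:
the transform is strictly monotone decreasing, stretches the significant
region (P below the Bonferroni threshold 0.05/17,651 ≈ 2.83×10⁻⁶) onto
(5.55, ∞), and thereby makes *shared significant* genes the dominant
contributors to Euclidean distances between phenotypes. Clustering raw
*P*-values instead groups phenotypes by shared nonsignificant architecture,
which is rarely of interest; `ward_linkage` therefore refuses `pvalue`-scale
input unless explicitly overridden.

Agglomeration is Ward's method: merge the pair of clusters minimising
d(R,S) = N_R·N_S/(N_R+N_S)·‖C_R−C_S‖², the increase in total within-cluster
sum of squared errors. The implementation maintains merging costs with the
Lance–Williams recurrence (O(N²) memory, O(N³) time worst case — trivial at
N ≤ a few hundred phenotypes), but its contract is the brute-force
definition, and the test suite enforces exact equality of merge order and
heights against a from-scratch recomputation on small instances, plus
agreement with an independent library implementation on larger ones.

A cluster's **branch length** is the dendrogram height at which it is
absorbed into its parent minus the height at which it formed. Long branches
mark clusters that form early (tight) and survive long (separated).
Prioritization:

1. collect all *small* clusters — size ≤ T, default ⌈N/3⌉ — and sort their
   branch lengths ascending;
2. take consecutive differences (gaps);
3. flag outlier gaps under the configured criterion;
4. the threshold is the minimum branch length that exceeds the median of the
   sorted lengths *and* lies immediately above a flagged gap; absent such a
   length, there are no prioritized clusters.

Clusters with branch length ≥ threshold are prioritized and ranked by
descending branch length. Nested prioritized clusters are reported — a tight
subcluster inside a prioritized cluster is itself a finding.

## Outlier criteria

* **median** (default): |g − median| > 3 × 1.4826 × MAD. The 1.4826 factor
  is the normal-consistency constant, making the scaled MAD estimate an SD;
  robust, no normality assumption.
* **mean**: |g − mean| > 3 × SD (sample SD, ddof = 1). Fast, conservative,
  assumes approximate normality.
* **quartile**: outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear
  interpolation between order statistics (the common convention; the choice
  must be pinned for reproducibility).
* **grubbs**: iterative two-sided Grubbs test at α = 0.05; the most extreme
  gap is removed and flagged while G = max|g−ḡ|/s exceeds
  ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student-t quantile on
  n−2 df, stopping at no rejection or n < 3.

All four are scale-equivariant, so the full prioritization decision is
invariant under positive rescaling of the score matrix (property-tested).
Degenerate spread (MAD or SD exactly 0) flags any gap strictly greater than
the centre — the limit of the rule; constant gap vectors yield no flags.

## Numerical and design choices

* **Height convention.** Default heights are √(2·cost), under which merging
  two singletons records their Euclidean distance (the convention of the
  common `linkage` implementations). Raw costs are available
  (`rawcost`) because thresholding is not invariant to monotone height
  transforms; the convention used is embedded in every output.
* **Tie-breaks.** Equal merging costs are resolved by the smallest
  (left, right) node-id pair; equal branch lengths rank by smaller size,
  then lexicographic member list. Runs are bit-reproducible.
* **Singleton leaves are not prioritization candidates** (default). A leaf's
  branch length equals its first-merge height, which lies on the scale of
  typical inter-phenotype distances. Including leaves floods the candidate
  pool: at weak sharing the step-4 median rises above every genuine
  multi-phenotype cluster's branch length and recovery collapses to zero.
  Excluding leaves reproduces the expected benchmark behaviour;
  `include_singletons=True` restores them (above-threshold clusters smaller
  than `min_reported_size` are then reported separately, not ranked).
* **Step-4 median** is computed over the size-filtered candidate lengths
  (the list sorted in step 1), not over all node branch lengths.
* **Gap attribution.** Gap gᵢ = Lᵢ₊₁ − Lᵢ belongs to the branch above it, so
  the selected threshold sits on the far side of the outlier gap and the
  prioritized clusters are the ones separated *by* the gap.
* **P = 0 handling.** External gene-score files may contain zeros
  (machine-precision tests); they are clamped to 10⁻³⁰⁰ before the transform
  rather than rejected, keeping distances finite.

## Simulation protocol

One simulated matrix has N phenotypes × 17,651 genes; every phenotype gets
exactly 175 significant entries (1%, P < 2.83×10⁻⁶). Structure is planted
by:

1. M ~ Uniform{round(0.03N) … round(0.15N)} clusters (floor 1; endpoints by
   half-away rounding — N = 100 gives 3…15);
2. per cluster: size ~ Uniform{2…8}, members drawn without replacement from
   the remaining phenotype pool; a set of `round_half_away(f · 175)` shared
   genes drawn from the remaining gene pool and removed from it (f the
   shared fraction; f = 1/10/25/50/75% gives 2/18/44/88/131 genes — the
   half-away rule is the unique simple rounding consistent with all five);
   every member receives the shared genes as significant plus its own
   distinct draws from the remaining pool up to 175;
3. unclustered phenotypes draw 175 significant genes from the remaining
   pool.

Nonshared significant genes of different phenotypes may coincide by chance
(two unclustered phenotypes overlap in ≈ 175²/17,651 ≈ 1.7 genes on
average); only shared-cluster genes are removed from the pool. If drawn
cluster sizes exhaust the phenotype pool, sizes are truncated (logged) —
relevant only at small N. Cell values come from two samplers: significant
P-values log-uniform on [10⁻²⁰, 2.83×10⁻⁶), nonsignificant uniform on
[2.83×10⁻⁶, 1]. These defaults are a synthetic stand-in for an empirical
gene-score distribution, which can be substituted via `empirical_pools`
(any *P*-value list, partitioned exactly at the threshold).

## Evaluation

A planted cluster is *recovered* only by an exactly matching prioritized
member set. **Power** is pooled across simulations (recovered / total
planted). **Top-x precision** is per simulation with x planted clusters
the percentage recovered within the x highest ranks, averaged over
simulations. **Standard precision/recall** are set-based; F1 = 2pr/(p+r) on
fractions, 0 when p + r = 0, and precision is 0 by convention (logged) when
nothing is prioritized. Benchmarks fix T = 8 and the median criterion and
spawn per-simulation seeds from one root seed.

The standard benchmark cells use 100 simulations each; the sensitivity sweep
uses a single 100-phenotype, 75%-shared instance with exactly 13 clusters
whose sizes are redrawn (deterministically under the seed) until they span
2–7 end to end, matching the instance definition; thresholds 2–19 are
crossed with all four criteria on one dendrogram.

## What the synthetic pools do not emulate — known limitations

* The synthetic significant pool has a light, bounded tail (scores ≤ 20).
  Empirical gene-score pools from machine-precision tests contain far more
  extreme values, and chance sharing of extreme scores creates long-branch
  *false-positive* clusters. Consequences under the defaults: top-x
  precision is near 100% (false positives never outrank planted clusters),
  whereas on empirical-pool data precision materially below 100% and
  decreasing with N is expected; the row-shuffle null still shows counts
  decaying toward zero with cluster size (≈ 4–6 pairs and ≈ 1 triple per
  shuffle, but a nonzero ~0.6 mean count of size-≥4 clusters, rather than
  essentially none). Passing benchmarks therefore demonstrate recovery
  power and ranking mechanics, not empirical false-positive rates.
* No linkage-disequilibrium-induced correlation between physically adjacent
  genes is simulated; scores are exchangeable across the gene panel.
* Gene-score computation itself (PEGASUS/PASCAL/VEGAS) is out of scope; the
  tool consumes any regional-score matrix.
* No statistical significance is attached to prioritized clusters; the
  ranking is by branch length only, and the shuffle null is the provided
  calibration instrument.
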