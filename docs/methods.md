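# Methods

## Scope and model

`clustab` addresses two linked questions in exploratory analysis of
expression and SNP matrices: *given k, which partition?* and *which k at
all?* Its components:

1. **Partitional clustering.** For continuous data, Lloyd's k-means: given
   X = {x₁,…,x_N} ⊂ ℝᵈ, alternate nearest-centroid assignment under squared
   Euclidean distance with mean-centroid updates, minimizing
   f(P) = Σⱼ Σ_{x∈Cⱼ} ‖x − μⱼ‖². For genotype matrices coded 0/1/2
   (homozygous reference / heterozygous / homozygous alternative), k-modes:
   the distance is the allele-sharing distance (ASD) — per SNP, 2 minus the
   number of alleles the two genotypes share, i.e. |x_l − y_l| under 0/1/2
   coding — and the centroid update takes the per-locus mode.
2. **Partition similarity.** The maximum cluster assignment (MCA) index: for
   partitions P, Q build the k×k contingency table of cluster intersection
   sizes and find the bijection π maximizing Σᵢ |Cᵢ ∩ D_{π(i)}|, a linear
   assignment problem. MCA = matched/n ∈ (0, 1]; 1 iff the partitions agree
   up to relabeling. The index is linear in n (interpretable as "fraction of
   objects that stayed together"), unlike pair-counting indices.
3. **Chance correction.** A raw index I is corrected to
   (I − E(I)) / (I_max − E(I)), with E(I) estimated by Monte Carlo under one
   of three null hypotheses: *random label* (uniform surjective labelings —
   worst case, lower bound), *random partition* (uniform over the S(n,k) set
   partitions into exactly k non-empty blocks), or *random prototype*
   (random rows as prototypes, nearest-prototype assignment — data-driven,
   tightest bound for centroid clustering).
4. **Cluster-number estimation.** For each candidate k, subsample the rows,
   cluster each subsample (best of several restarts by quantization error),
   and compare all clusterings pairwise with MCA on the intersection of
   their subsamples; do the same for baseline partitions on independent
   subsamples. The gap between the median clustering MCA and the median
   baseline MCA measures excess stability; the chosen k maximizes the gap,
   and a one-sided Mann–Whitney U test (clustering MCA > baseline MCA) at
   that k can reject the clustering altogether ("no structure found").

## Determinism and the parallel contract

All randomness flows from numpy `SeedSequence` streams: restart r of a run
seeded s uses `SeedSequence((s, r))`; the stability protocol derives one
stream per (seed, k, repetition, role). Runs are therefore reproducible
bit-for-bit, and results are independent of execution order.

Worker parallelism is a pure throughput knob. Rows are partitioned into
fixed 4096-row blocks *regardless of the worker count*; workers only decide
how many blocks are processed concurrently (a thread pool; numpy releases
the GIL inside the kernels), and block partial results — per-cluster sums
and counts for the mean update, genotype frequency tables for the mode
update — are reduced in block order. Since neither the block boundaries nor
the reduction order depend on the worker count, floating-point results are
bit-identical for every `workers ≥ 1`. This is asserted directly in the
test suite on instances spanning multiple blocks.

## Numerical and algorithmic choices

- **Convergence.** A run stops when the label vector repeats between
  consecutive iterations (exact, float-safe), with a `max_iter` safety cap
  (default 100).
- **Ties.** Nearest-centroid ties break to the lowest centroid index;
  per-locus mode ties break to the smallest genotype code; best-k gap ties
  break to the smallest k (parsimony). All deterministic.
- **Empty clusters.** If an update leaves cluster j empty, its centroid is
  reseated at the point farthest from its assigned centroid (ties: lowest
  row index). Returned results never contain an empty cluster.
- **Best-state tracking.** The mean update is the exact minimizer of the
  squared-error objective, so the k-means objective is non-increasing over
  iterations and the converged state is the run's best. The per-locus mode,
  however, is not the minimizer of the L1-form ASD (the median is), so a
  k-modes iteration can in principle increase the objective. The driver
  therefore tracks the best full-support (labels, centroids, objective)
  state visited and returns that state; for k-means this coincides with the
  converged state, for k-modes it makes the returned objective the minimum
  over all visited configurations. Restart selection compares these
  returned objectives and keeps the smallest (first on ties).
- **Initialization.** Centroids are k *distinct* rows drawn uniformly
  without replacement (requesting more clusters than distinct rows is a
  degenerate-input error). Prototype baseline draws sample row indices
  without replacement and may produce empty clusters; the MCA machinery
  handles those by zero-padding the contingency table, which cannot change
  the assignment optimum.
- **Partitions over subsamples.** Two partitions are compared on the
  intersection of their index sets, with n = intersection size — the
  standard choice in the stability literature.
- **Uniform set-partition sampling.** Element m of a partition of m
  elements into j blocks is a new block with probability
  S(m−1, j−1)/S(m, j), else it joins one of the j blocks of a uniform
  partition of the rest, chosen uniformly; S(·,·) computed by the standard
  recurrence in exact integer arithmetic. This yields exact uniformity over
  the S(n,k) partitions (validated against enumeration by chi-square).
- **Rank test.** One-sided Mann–Whitney U ("clustering more stable than
  baseline"): exact when both samples have ≤ 25 tie-free values, otherwise
  the normal approximation with tie correction. Two completely tied samples
  return p = 0.5 (no evidence).
- **No closed form for E(MCA).** Expected MCA under the nulls is estimated
  by Monte Carlo over pairs of independent draws (default 500), matching
  how real clusterings are compared. Exhaustive enumeration on tiny cases
  (e.g. n = 4, k = 2 under random label: E(MCA) = 34/49) anchors the
  estimator in tests. Empirically E(MCA) under random label is not
  monotone in n at fixed k; it dips for n slightly above k before rising
  toward its large-n limit.

## Synthetic data generators

The generators define the study conditions for testing and for the
reproduction script; they emulate specific, simple structures:

- **Uniform**: i.i.d. Uniform[0,1] features; structureless (null runtime /
  no-structure behavior).
- **Gaussian clusters**: k spherical Gaussians, sd σ, centers mutually at
  least `separation` apart (for k ≤ d, scaled standard-basis vectors give
  exactly that distance), sizes equal up to remainder, rows shuffled. The
  headline experiment uses 2,000 points, 100 dimensions, k = 3,
  separation = 10σ.
- **Microarray**: p genes × n arrays with k gene clusters. Cluster
  centroids are k evenly spaced scalars symmetric about 0, rescaled so
  their population variance equals σ²_between (default 4.0); genes are
  assigned round-robin; gene means ~ N(centroid, σ²_within, default 0.25);
  gene variances x/(n−1) with x ~ χ²(n); each cluster receives a
  Poisson-distributed number of correlated gene pairs with mean
  c·p_k(p_k−1)/2, c = 5/(100p), pair covariance r·σᵢσⱼ with r ~ U(−1,1);
  arrays are drawn as X = Y·Tᵀ + μ_g with Σ = T·Tᵀ (Cholesky). Inserting
  arbitrary pair covariances can break positive definiteness; on
  factorization failure all pair entries are halved and the factorization
  retried (≤ 20 times), with the shrinkage count recorded in the metadata.
  An explicit per-cluster pair-count override supports controlled
  covariance-recovery experiments.
- **SNP populations**: Balding–Nichols-style Beta-Binomial model — per SNP
  an ancestral frequency f ~ U(0.1, 0.9); per population a frequency
  ~ Beta(f(1−F)/F, (1−f)(1−F)/F) with F = `divergence` (acts like an F_ST,
  default 0.2); genotypes ~ Binomial(2, freq). This produces separable
  populations for k-modes testing; it is a deliberately simple stand-in for
  real genotype panels.

What these generators do **not** emulate: heavy-tailed expression noise,
batch effects, missingness, linkage disequilibrium between SNPs, unequal
population sizes, or cluster shapes that are not spherical/compact. Passing
tests on them demonstrates correctness of the algorithms and of the
stability protocol under its own model assumptions, not performance on any
particular real dataset.

## Problem sizes used in the shipped experiments

The headline reproduction (scripts/acceptance.py and the corresponding
test) runs the estimation protocol on 2,000 × 100 matrices with 10
clustering and 10 baseline repetitions per k over k ∈ {2..10}, 90%
subsamples and 10 restarts per repetition — 180 clustering runs plus 90
baseline draws per dataset. These sizes were chosen as the package's
standard desk-scale experiment; larger runs only tighten the Monte-Carlo
spread of the per-k MCA distributions.

## I/O and reproducibility conventions

Matrices are plain TSV/CSV; labels are one integer per line (0-based,
1-based on request); results are JSON embedding a run manifest (command,
parameters, input SHA-256 digests, tool version). Wall-clock timestamps go
to the log rather than into result files so that identical invocations
produce byte-identical outputs. Per-k MCA samples are exported as tidy TSV
for external plotting.

## Known limitations

- k-modes returns the best visited configuration, which is a local (not
  certified global) optimizer, as with any Lloyd-type search; restarts are
  the mitigation.
- The random-label rejection sampler is inefficient when k is close to n
  (acceptance probability k!·S(n,k)/kⁿ); for the k ≪ n regimes targeted
  here rejection is rare.
- The stability protocol inherits k-means' bias toward spherical clusters;
  a different base clusterer would need its own prototype-baseline
  assignment rule.
- Very large k with `random_partition` baselines requires big-integer
  Stirling tables (exact but O(n·k) big-int work); the default baseline is
  `random_prototype`, which has no such cost.
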