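"""Synthetic data generators for clustering experiments.

Four constructions:

* structureless matrices with i.i.d. Uniform[0,1] features (runtime and
  null-behavior testing);
* planted spherical Gaussian clusters with a guaranteed minimum center
  separation (ground truth for cluster-number estimation);
* a correlated-gene artificial microarray: gene-cluster centroids spaced
  to a target between-cluster variance, gene means scattered around them
  with a within-cluster variance, chi-square distributed gene variances,
  a sparse set of correlated gene pairs, and arrays drawn from the
  resulting multivariate normal via Cholesky factorization;
* a Beta-Binomial population-structure model producing 0/1/2 genotype
  matrices with separable subpopulations for k-modes testing.

All generators are bit-for-bit reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .matrix import CONTINUOUS, GENOTYPE, DataMatrix


@dataclass(frozen=True)
class MicroarraySimConfig:
    """Parameters of the artificial microarray simulator.

    ``p`` genes measured on ``n`` arrays, ``k`` gene clusters;
    ``var_between`` is the variance of the cluster centroid values,
    ``var_within`` the variance of gene means around their centroid.
    ``n_correlated_pairs`` overrides the Poisson draw of correlated pairs
    per cluster when not None (useful for controlled experiments).
    """

    p: int
    n: int
    k: int
    var_between: float = 4.0
    var_within: float = 0.25
    seed: int | None = None
    n_correlated_pairs: int | None = None

    def validate(self) -> None:
        if not (self.p >= self.k >= 1):
            raise ValueError(f"need p >= k >= 1, got p={self.p}, k={self.k}")
        if self.n < 2:
            raise ValueError("need at least 2 arrays")
        if self.var_between <= 0 or self.var_within < 0:
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated matrix with its planted ground truth and the generator
    parameters actually realized (sufficient to reconstruct the model)."""

    matrix: DataMatrix
    true_labels: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)


def gen_uniform(n_rows: int, n_cols: int, seed: int | None = None) -> DataMatrix:
    """Structureless matrix: every entry i.i.d. Uniform[0, 1]."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    return DataMatrix(rng.random((n_rows, n_cols)), kind=CONTINUOUS)


def _separated_centers(k: int, d: int, separation: float,
                       rng: np.random.Generator) -> np.ndarray:
    """k centers in d dimensions with pairwise distance >= separation.

    For k <= d, scaled standard-basis vectors give exactly ``separation``
    between every pair; otherwise random directions are rescaled until the
    minimum pairwise distance suffices.
    """
    if k == 1:
        return np.zeros((1, d))
    if k <= d:
        centers = np.zeros((k, d))
        centers[np.arange(k), np.arange(k)] = separation / np.sqrt(2.0)
        return centers
    centers = rng.standard_normal((k, d))
    for _ in range(100):
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)
        m = dist.min()
        if m >= separation:
            return centers
        centers *= (separation / m) if m > 0 else 2.0
        if m == 0:
            centers += rng.standard_normal((k, d)) * 1e-6
    return centers


def gen_gaussian_clusters(n_rows: int, n_cols: int, k: int,
                          separation: float = 10.0, sd: float = 1.0,
                          seed: int | None = None) -> SimulatedDataset:
    """k spherical Gaussian clusters of (near-)equal size.

    Cluster centers are mutually at least ``separation`` apart; points are
    isotropic normal with standard deviation ``sd`` around their center.
    Sizes differ by at most one. Rows are shuffled so cluster membership
    is not positional.
    """
    if not 1 <= k <= n_rows:
        raise ValueError(f"need 1 <= k <= n_rows, got k={k}")
    rng = np.random.default_rng(seed)
    centers = _separated_centers(k, n_cols, separation, rng)
    base, extra = divmod(n_rows, k)
    sizes = np.array([base + (1 if j < extra else 0) for j in range(k)])
    labels = np.repeat(np.arange(k), sizes)
    values = centers[labels] + rng.standard_normal((n_rows, n_cols)) * sd
    order = rng.permutation(n_rows)
    return SimulatedDataset(
        matrix=DataMatrix(values[order], kind=CONTINUOUS),
        true_labels=labels[order],
        meta={"centers": centers, "sd": sd, "separation": separation},
    )


def correlated_pair_probability(p: int) -> float:
    """Probability that any given gene pair is correlated:
    c = 5 * 10^-(log10(p) + 2) = 5 / (100 p)."""
    return 5.0 * 10.0 ** -(np.log10(p) + 2.0)


def gen_microarray(cfg: MicroarraySimConfig) -> SimulatedDataset:
    """Simulate a gene-clustered microarray experiment.

    Procedure: (1) k pairwise-equidistant scalar cluster centroids,
    evenly spaced and symmetric about 0, rescaled so their population
    variance equals ``var_between``; (2) genes assigned round-robin for
    balanced clusters; (3) gene means Normal(centroid, var_within);
    (4) gene variances x/(n-1) with x ~ chi-square(n); (5) per cluster a
    Poisson number of correlated gene pairs (mean c * p_k(p_k-1)/2 with
    c = 5/(100 p)), each with covariance r * sigma_i * sigma_j,
    r ~ U(-1, 1); (6) covariance matrix assembled and, if not positive
    definite, off-diagonal pair entries halved until the Cholesky
    factorization succeeds (at most 20 times, shrinkage recorded in
    meta); (7) arrays X = Y T' + mu_g with Y ~ N(0, I), Sigma = T T'.

    Returns the genes x arrays matrix with gene cluster labels.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p, n, k = cfg.p, cfg.n, cfg.k

    centroids = np.arange(k, dtype=float) - (k - 1) / 2.0
    if k > 1:
        centroids *= np.sqrt(cfg.var_between / centroids.var())
    labels = np.arange(p) % k  # round-robin, balanced

    mu_g = centroids[labels] + (
        rng.standard_normal(p) * np.sqrt(cfg.var_within)
    )
    sigma2_g = rng.chisquare(n, size=p) / (n - 1)
    sigma_g = np.sqrt(sigma2_g)

    c = correlated_pair_probability(p)
    pairs: list[tuple[int, int, float]] = []
    for j in range(k):
        members = np.flatnonzero(labels == j)
        p_k = members.size
        max_pairs = p_k * (p_k - 1) // 2
        if max_pairs == 0:
            continue
        if cfg.n_correlated_pairs is not None:
            n_pairs = min(cfg.n_correlated_pairs, max_pairs)
        else:
            n_pairs = min(int(rng.poisson(c * max_pairs)), max_pairs)
        if n_pairs == 0:
            continue
        flat = rng.choice(max_pairs, size=n_pairs, replace=False)
        for f in flat:
            a, b = _unrank_pair(int(f), p_k)
            r = rng.uniform(-1.0, 1.0)
            pairs.append((int(members[a]), int(members[b]), float(r)))

    cov = np.diag(sigma2_g)
    for i, j, r in pairs:
        cov[i, j] = cov[j, i] = r * sigma_g[i] * sigma_g[j]

    shrinkage = 0
    chol = None
    for attempt in range(21):
        try:
            chol = np.linalg.cholesky(cov)
            break
        except np.linalg.LinAlgError:
            shrinkage += 1
            if attempt == 20:
                raise
            for i, j, _ in pairs:
                cov[i, j] *= 0.5
                cov[j, i] *= 0.5

    y = rng.standard_normal((n, p))
    arrays = y @ chol.T + mu_g  # rows ~ N(mu_g, Sigma)
    realized_pairs = [
        (i, j, float(cov[i, j] / (sigma_g[i] * sigma_g[j])))
        for i, j, _ in pairs
    ]
    return SimulatedDataset(
        matrix=DataMatrix(arrays.T.copy(), kind=CONTINUOUS),  # genes x arrays
        true_labels=labels,
        meta={
            "centroids": centroids,
            "gene_means": mu_g,
            "gene_variances": sigma2_g,
            "correlated_pairs": realized_pairs,
            "pair_probability": c,
            "shrinkage_halvings": shrinkage,
        },
    )


def _unrank_pair(f: int, m: int) -> tuple[int, int]:
    """Map a flat index in [0, m(m-1)/2) to an (a, b) pair, a < b < m."""
    a = 0
    remaining = m - 1
    while f >= remaining:
        f -= remaining
        a += 1
        remaining -= 1
    return a, a + 1 + f


def gen_snp(n_individuals: int, m_snps: int, k_pops: int,
            divergence: float = 0.2,
            seed: int | None = None) -> SimulatedDataset:
    """Population-structured genotype matrix (Beta-Binomial model).

    Each SNP has an ancestral allele frequency ~ U(0.1, 0.9); each
    population's frequency is drawn from Beta(f(1-F)/F, (1-f)(1-F)/F)
    with F = ``divergence`` (the Balding-Nichols construction, so F acts
    like an F_ST), and genotypes are Binomial(2, freq) coded 0/1/2.
    Individuals are split across populations as evenly as possible and
    shuffled.
    """
    if not 1 <= k_pops <= n_individuals:
        raise ValueError("need 1 <= k_pops <= n_individuals")
    if not 0 < divergence < 1:
        raise ValueError("divergence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.1, 0.9, size=m_snps)
    scale = (1.0 - divergence) / divergence
    base, extra = divmod(n_individuals, k_pops)
    sizes = [base + (1 if j < extra else 0) for j in range(k_pops)]
    labels = np.repeat(np.arange(k_pops), sizes)
    freqs = rng.beta(ancestral * scale, (1.0 - ancestral) * scale,
                     size=(k_pops, m_snps))
    genotypes = rng.binomial(2, freqs[labels])
    order = rng.permutation(n_individuals)
    return SimulatedDataset(
        matrix=DataMatrix(genotypes[order], kind=GENOTYPE),
        true_labels=labels[order],
        meta={"ancestral_freq": ancestral, "pop_freq": freqs,
              "divergence": divergence},
    )
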