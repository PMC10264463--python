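"""Population-structure covariates: VanRaden GRM and its principal components.

The genomic relationship matrix is G = ZZ′ / c with Z the dosage matrix
centered at twice the sample allele frequencies and c = Σ_j 2p_j(1 − p_j).
The leading eigenvectors of G, scaled by the square roots of their
eigenvalues, are used as fixed-effect covariates in the association
models; with 20 full-sib families the first ~19 components separate the
family structure and typically carry most of the genotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import Population

DEFAULT_K = {"major3_plus97": 19, "infinitesimal_100": 18}


@dataclass(frozen=True)
class StructureCovariates:
    """Principal-component scores of the GRM used as scan covariates.

    ``variance_explained`` follows the PCA *of the relationship matrix*:
    G is doubly centered (rows/columns of the VanRaden form sum to zero),
    so the principal components of G-as-data share G's eigenvectors and
    carry component variances λ_k², giving shares λ_k²/Σλ_j².  This is
    the "percentage of variance in the genotypic data" figure reported
    when running a PCA on a relationship matrix; the plain eigenvalue
    shares λ_k/Σλ_j are kept in ``dosage_variance_explained``.
    """

    scores: np.ndarray              # n × K (eigenvectors · sqrt eigenvalues)
    variance_explained: np.ndarray  # PCA-of-G share per retained component
    dosage_variance_explained: np.ndarray  # eigenvalue share per component
    K: int
    cumulative_variance: float      # fraction in [0, 1] for the K components


def grm(pop: Population | np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from marker dosages."""
    M = pop.marker_dosages if isinstance(pop, Population) else np.asarray(pop)
    M = M.astype(float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    Z = M[:, poly] - 2.0 * p[poly]
    c = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    return Z @ Z.T / c


def pca_covariates(G: np.ndarray, K: int) -> StructureCovariates:
    """Top-K principal components of the GRM as score covariates.

    Eigenvalues are clipped at zero for the variance shares (G is PSD up
    to round-off).  Each eigenvector's largest-magnitude entry is made
    positive so outputs are reproducible across LAPACK builds.
    """
    G = np.asarray(G, float)
    n = G.shape[0]
    if not 1 <= K < n:
        raise ValueError("K must satisfy 1 <= K < n_individuals")
    evals, evecs = np.linalg.eigh(G)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                         np.arange(n)])
    evecs = evecs * np.where(flip == 0, 1.0, flip)
    sq_total = np.sum(evals ** 2)
    share = evals[:K] ** 2 / sq_total if sq_total > 0 else np.zeros(K)
    lin_total = evals.sum()
    lin_share = evals[:K] / lin_total if lin_total > 0 else np.zeros(K)
    scores = evecs[:, :K] * np.sqrt(evals[:K])
    return StructureCovariates(scores=scores, variance_explained=share,
                               dosage_variance_explained=lin_share,
                               K=K, cumulative_variance=float(share.sum()))


def select_k(G: np.ndarray, min_variance: float = 0.85) -> int:
    """Smallest K whose components explain at least ``min_variance``.

    Uses the same PCA-of-G variance shares as :func:`pca_covariates`.
    """
    evals = np.clip(np.linalg.eigvalsh(G)[::-1], 0.0, None) ** 2
    cum = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(cum, min_variance) + 1)
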