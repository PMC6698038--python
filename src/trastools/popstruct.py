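"""Population-structure corrections and study-wide significance thresholds.

The association model corrects stratification with the first principal
components of the genotype matrix as fixed effects and a genomic kinship
matrix as the random-effect covariance.  The per-test significance bar is a
Bonferroni correction based on the effective number of independent markers
(Li-Ji eigenvalue estimate), with a relaxed 1/m "suggestive" bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "CovariateSet",
    "ThresholdSet",
    "compute_kinship",
    "compute_pcs",
    "effective_marker_count",
    "significance_thresholds",
]

_RIDGE = 1e-6
_EIG_FLOOR = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric positive semi-definite relatedness matrix over samples."""

    samples: list[str]
    K: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if np.max(np.abs(self.K - self.K.T)) > 1e-10:
            raise ValueError("kinship matrix is not symmetric")

    def reorder(self, samples: list[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in samples])
        return KinshipMatrix(list(samples), self.K[np.ix_(idx, idx)])


@dataclass
class CovariateSet:
    """Fixed-effect design: intercept column followed by PC scores."""

    samples: list[str]
    W: np.ndarray  # (n, 1 + n_pcs)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[0] != len(self.samples):
            raise ValueError("covariate shape mismatch")
        if not np.allclose(self.W[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")
        if np.linalg.matrix_rank(self.W) < self.W.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    def reorder(self, samples: list[str]) -> "CovariateSet":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in samples])
        return CovariateSet(list(samples), self.W[idx])


@dataclass(frozen=True)
class ThresholdSet:
    """Study-wide per-test significance thresholds.

    ``bonferroni_p`` = alpha / m_eff gates "associated" loci;
    ``suggestive_p`` = 1 / m_total gates suggestive loci.
    """

    m_total: int
    m_eff: float
    alpha: float
    bonferroni_p: float
    suggestive_p: float


def compute_kinship(G: GenotypeMatrix, estimator: str = "centered") -> KinshipMatrix:
    """Genomic kinship from all SNPs.

    centered
        VanRaden-style: K = Z Z' / sum_j 2 p_j (1 - p_j) with Z the
        column-centered dosage matrix.  The denominator scales the mean
        diagonal to ~1.
    standardized
        Each column additionally divided by its standard deviation;
        K = Z_std Z_std' / m (mean diagonal exactly 1).

    A ridge of 1e-6 I is added if the smallest eigenvalue falls below 1e-8.
    """
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before kinship estimation")
    Z = X - X.mean(axis=0)
    if estimator == "centered":
        p = X.mean(axis=0) / 2.0
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("all markers monomorphic; cannot scale kinship")
        K = (Z @ Z.T) / denom
    elif estimator == "standardized":
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            j = int(np.argmax(sd == 0))
            raise ValueError(
                f"zero-variance marker {G.snps[j].snp_id!r} under the "
                "standardized estimator (should have been removed in QC)"
            )
        Zs = Z / sd
        K = (Zs @ Zs.T) / G.n_snps
    else:
        raise ValueError(f"unknown kinship estimator {estimator!r}")
    K = (K + K.T) / 2.0
    if np.linalg.eigvalsh(K)[0] < _EIG_FLOOR:
        K = K + _RIDGE * np.eye(K.shape[0])
    return KinshipMatrix(list(G.samples), K)


def compute_pcs(G: GenotypeMatrix, n_pcs: int = 3) -> CovariateSet:
    """Principal-component scores of the centered genotypes, plus intercept.

    Scores are left singular vectors scaled by singular values (i.e. the
    projections onto the principal axes).  Sign convention: the
    largest-magnitude marker loading of each component is positive, which
    makes the decomposition deterministic.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs >= G.n_samples:
        raise ValueError("n_pcs must be smaller than the number of samples")
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before PCA")
    Z = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    W = np.column_stack([np.ones(G.n_samples), scores])
    return CovariateSet(list(G.samples), W)


def _li_ji(lam: np.ndarray) -> float:
    # M_eff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ]
    lam = np.clip(lam, 0.0, None)
    # the floor makes the formula discontinuous at integers; snap eigenvalues
    # within numerical noise of an integer so that e.g. duplicated markers
    # (exact eigenvalue 2) are not counted twice
    near = np.abs(lam - np.round(lam)) < 1e-9
    lam = np.where(near, np.round(lam), lam)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def effective_marker_count(G: GenotypeMatrix, block_size: int = 1000) -> float:
    """Li-Ji effective number of independent markers.

    Eigenvalues of the marker-marker correlation matrix are reduced to
    M_eff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ].  When m exceeds
    ``block_size`` the correlation matrix is formed block-wise over
    consecutive markers and the block estimates are summed, mirroring
    per-chromosome practice.
    """
    X = G.dosages
    if X.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"constant marker column {G.snps[j].snp_id!r}")
    total = 0.0
    for start in range(0, X.shape[1], block_size):
        block = X[:, start:start + block_size]
        if block.shape[1] == 1:
            total += 1.0
            continue
        R = np.corrcoef(block, rowvar=False)
        total += _li_ji(np.linalg.eigvalsh(R))
    return total


def significance_thresholds(m_total: int, m_eff: float, alpha: float = 0.05) -> ThresholdSet:
    """Bonferroni (alpha / m_eff) and suggestive (1 / m_total) thresholds."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_total < 1 or m_eff < 1:
        raise ValueError("marker counts must be >= 1")
    bonf = alpha / m_eff
    sugg = 1.0 / m_total
    assert bonf <= alpha and sugg <= 1.0
    return ThresholdSet(m_total=int(m_total), m_eff=float(m_eff), alpha=float(alpha),
                        bonferroni_p=bonf, suggestive_p=sugg)
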