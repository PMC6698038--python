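"""Exact single-variance-component linear mixed model and per-marker tests.

Model:  y = W a + x b + u + e,   u ~ N(0, sg2 K),   e ~ N(0, se2 I),
with variance ratio delta = se2 / sg2.  The kinship matrix is
eigendecomposed once (K = U S U'); rotating y and W by U' diagonalizes the
covariance so the REML profile likelihood in delta and every marker's GLS fit
cost O(n c) per evaluation.  By default delta is estimated once under the
null model (no marker) and held fixed across markers — the EMMAX
approximation — with an ``exact_per_marker`` escape hatch that re-optimizes
delta for every marker.

Marker tests are Wald tests: (b / se)^2 referred to F(1, n - c - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import GenotypeMatrix
from .popstruct import CovariateSet, KinshipMatrix

__all__ = [
    "MixedModelSpec",
    "NullFit",
    "AssociationResult",
    "reml_loglik",
    "fit_null",
    "score_marker",
    "association_scan",
]

_DELTA_LO, _DELTA_HI = 1e-5, 1e5
_GRID_POINTS = 100


@dataclass
class MixedModelSpec:
    """One phenotype (trait value or one transcript's expression) plus its
    fixed-effect design and kinship."""

    y: np.ndarray
    W: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.W = np.asarray(self.W, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        n = self.y.size
        if self.W.shape[0] != n or self.K.shape != (n, n):
            raise ValueError("mixed model dimensions disagree")
        if np.isnan(self.y).any():
            raise ValueError("phenotype contains missing values after alignment")
        if n < self.W.shape[1] + 2:
            raise ValueError("too few samples for the covariate set")

    @classmethod
    def build(cls, y, covariates: CovariateSet, kinship: KinshipMatrix) -> "MixedModelSpec":
        if covariates.samples != kinship.samples:
            raise ValueError("covariates and kinship are not sample-aligned")
        return cls(y, covariates.W, kinship.K)


@dataclass
class NullFit:
    """REML estimate of delta plus the cached kinship rotation."""

    delta_hat: float
    reml_loglik: float
    U: np.ndarray  # eigenvectors of K
    S: np.ndarray  # eigenvalues of K
    ystar: np.ndarray  # U' y
    Wstar: np.ndarray  # U' W


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    beta_hat: float
    se: float
    p_value: float
    n_used: int
    degenerate: bool = False


def _rotated_reml(ystar, Wstar, S, delta, logdet_WtW):
    """REML log-likelihood at one delta, in the rotated coordinates."""
    n, c = Wstar.shape
    d = S + delta
    A = Wstar.T @ (Wstar / d[:, None])
    b = Wstar.T @ (ystar / d)
    alpha = np.linalg.solve(A, b)
    r = ystar - Wstar @ alpha
    rss = float(np.sum(r * r / d))
    if rss <= 0:
        return -np.inf
    nc = n - c
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return 0.5 * (
        nc * np.log(nc / (2 * np.pi)) - nc - nc * np.log(rss)
        - float(np.sum(np.log(d))) - logdet_A + logdet_WtW
    )


def reml_loglik(spec: MixedModelSpec, delta: float) -> float:
    """REML profile log-likelihood of delta (sg2 profiled out).

    Provided for direct evaluation; :func:`fit_null` uses the cached
    rotation internally.
    """
    S, U = np.linalg.eigh(spec.K)
    ystar, Wstar = U.T @ spec.y, U.T @ spec.W
    _, logdet_WtW = np.linalg.slogdet(spec.W.T @ spec.W)
    return _rotated_reml(ystar, Wstar, S, delta, logdet_WtW)


def fit_null(spec: MixedModelSpec, grid: np.ndarray | None = None,
             refine: bool = True) -> NullFit:
    """Maximize the REML profile likelihood of delta on a log grid.

    The profile is evaluated on ``grid`` (default 100 log-spaced points in
    [1e-5, 1e5]); every local maximum is bracketed and refined with a
    bounded derivative-free scalar optimizer to |d log10 delta| <= 1e-7, and
    the global maximizer is returned.
    """
    if np.var(spec.y) == 0:
        raise ValueError("phenotype has no variance")
    S, U = np.linalg.eigh(spec.K)
    S = np.clip(S, 0.0, None)
    ystar, Wstar = U.T @ spec.y, U.T @ spec.W
    _, logdet_WtW = np.linalg.slogdet(spec.W.T @ spec.W)
    # delta is optimized on the variance-normalized phenotype: the REML
    # profile of delta is scale-free, and normalizing makes the estimate
    # bitwise invariant to rescaling y
    yn = ystar / spec.y.std()
    if grid is None:
        grid = np.logspace(np.log10(_DELTA_LO), np.log10(_DELTA_HI), _GRID_POINTS)
    grid = np.asarray(grid, dtype=float)
    ll = np.array([_rotated_reml(yn, Wstar, S, d, logdet_WtW) for d in grid])
    if not np.isfinite(ll).any():
        raise ValueError("phenotype has no variance (degenerate likelihood)")

    best_delta = float(grid[int(np.nanargmax(ll))])
    best_ll = float(np.nanmax(ll))
    if refine and grid.size >= 3:
        neg = lambda t: -_rotated_reml(yn, Wstar, S, 10.0 ** t, logdet_WtW)
        lg = np.log10(grid)
        # refine every interior local maximum of the gridded profile
        for i in range(1, grid.size - 1):
            if ll[i] >= ll[i - 1] and ll[i] >= ll[i + 1] and np.isfinite(ll[i]):
                res = optimize.minimize_scalar(
                    neg, bounds=(lg[i - 1], lg[i + 1]), method="bounded",
                    options={"xatol": 1e-7},
                )
                if np.isfinite(res.fun) and -res.fun > best_ll:
                    best_ll = float(-res.fun)
                    best_delta = float(10.0 ** res.x)
    return NullFit(delta_hat=best_delta,
                   reml_loglik=_rotated_reml(ystar, Wstar, S, best_delta,
                                             logdet_WtW),
                   U=U, S=S, ystar=ystar, Wstar=Wstar)


def score_marker(fit: NullFit, spec: MixedModelSpec, x: np.ndarray,
                 snp_id: str = "") -> AssociationResult:
    """GLS Wald test of one marker with delta fixed at the null estimate.

    The effect and standard error come from generalized least squares under
    covariance sg2 (K + delta I), using the cached rotation.  A marker
    collinear with the covariates yields p = 1 with a degeneracy flag rather
    than an exception (scans must not abort).
    """
    x = np.asarray(x, dtype=float).ravel()
    n, c = fit.Wstar.shape
    d = fit.S + fit.delta_hat
    xstar = fit.U.T @ x
    X = np.column_stack([fit.Wstar, xstar])
    A = X.T @ (X / d[:, None])
    # collinearity check: weighted residual variance of x given W
    Aw = A[:c, :c]
    bw = A[:c, c]
    xx = A[c, c]
    try:
        resid_var = xx - float(bw @ np.linalg.solve(Aw, bw))
    except np.linalg.LinAlgError:
        resid_var = 0.0
    if not np.isfinite(resid_var) or resid_var <= 1e-10 * max(xx, 1.0):
        return AssociationResult(snp_id, 0.0, np.nan, 1.0, n, degenerate=True)
    b = X.T @ (fit.ystar / d)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    r = fit.ystar - X @ beta
    df = n - c - 1
    sigma2 = float(np.sum(r * r / d)) / df
    se = float(np.sqrt(sigma2 * Ainv[c, c]))
    if se == 0 or not np.isfinite(se):
        return AssociationResult(snp_id, float(beta[c]), np.nan, 1.0, n, degenerate=True)
    fstat = (beta[c] / se) ** 2
    p = float(stats.f.sf(fstat, 1, df))
    p = max(p, np.nextafter(0, 1))  # keep p in (0, 1]
    return AssociationResult(snp_id, float(beta[c]), se, p, n)


def association_scan(y, W: CovariateSet | np.ndarray, K: KinshipMatrix | np.ndarray,
                     G: GenotypeMatrix, threshold_p: float = 1.0,
                     exact_per_marker: bool = False):
    """Scan every SNP in ``G`` against one phenotype.

    Returns ``(results, significant)``: one :class:`AssociationResult` per
    SNP sorted by p ascending (ties broken by snp_id), and the subset with
    p <= ``threshold_p``.
    """
    Wm = W.W if isinstance(W, CovariateSet) else np.asarray(W, dtype=float)
    Km = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    spec = MixedModelSpec(y, Wm, Km)
    fit = fit_null(spec)
    results = []
    for j in range(G.n_snps):
        x = G.dosages[:, j]
        if exact_per_marker and np.std(x) > 0:
            spec_j = MixedModelSpec(spec.y, np.column_stack([Wm, x]), Km)
            try:
                fit_j = fit_null(spec_j)
            except ValueError:
                fit_j = fit
            fit_use = NullFit(fit_j.delta_hat, fit_j.reml_loglik, fit.U, fit.S,
                              fit.ystar, fit.Wstar)
        else:
            fit_use = fit
        results.append(score_marker(fit_use, spec, x, snp_id=G.snps[j].snp_id))
    results.sort(key=lambda r: (r.p_value, r.snp_id))
    significant = [r for r in results if r.p_value <= threshold_p]
    return results, significant


def results_to_frame(results, G: GenotypeMatrix):
    """Tabulate scan results as a DataFrame (snp_id, transcript_id, position,
    beta, se, p, n_used) — the on-disk TSV dialect for both trait and eQTL
    scans."""
    import pandas as pd

    meta = {s.snp_id: s for s in G.snps}
    rows = []
    for r in results:
        s = meta[r.snp_id]
        rows.append((r.snp_id, s.transcript_id, s.position, r.beta_hat, r.se,
                     r.p_value, r.n_used))
    return pd.DataFrame(rows, columns=["snp_id", "transcript_id", "position",
                                       "beta", "se", "p", "n_used"])
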