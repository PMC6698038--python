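"""Module-eigengene/trait correlation and GO-based function prediction.

Module *detection* is out of scope here: co-expression module labels are an
input (from WGCNA-style software or from the simulator's ground truth).
This module summarizes each labeled module by its eigengene — the first
principal-component score vector of the module's standardized expression —
correlates eigengenes with traits, and predicts the function of unannotated
(lncRNA) transcripts by hypergeometric GO over-representation of their
co-expression partners with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PhenotypeTable

__all__ = [
    "EnrichmentResult",
    "UNASSIGNED",
    "module_eigengene",
    "module_trait_correlation",
    "lncrna_partners",
    "correlation_partners",
    "go_enrichment",
]

#: reserved module label for transcripts outside every detected module
UNASSIGNED = "M00"


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k_in_set: int
    K_in_background: int
    n_set: int
    N_background: int
    p_value: float
    q_value: float


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def module_eigengene(E: ExpressionMatrix, modules: dict[str, str],
                     module_label: str) -> np.ndarray:
    """First PC score vector (unit norm) of a module's standardized expression.

    Sign convention: the eigengene correlates positively with the module's
    mean standardized expression profile, so it is invariant to transcript
    order and column sign flips come out deterministic.  A singleton module
    returns its one standardized profile (normalized), with a warning.
    """
    members = [t for t in E.transcripts if modules.get(t) == module_label]
    if not members:
        raise KeyError(f"no transcripts assigned to module {module_label!r}")
    idx = [E.transcripts.index(t) for t in members]
    sub = _standardize(E.values[:, idx])
    if len(members) == 1:
        warnings.warn(f"module {module_label!r} is a singleton")
        v = sub[:, 0]
        return v / np.linalg.norm(v)
    U, s, _ = np.linalg.svd(sub, full_matrices=False)
    eg = U[:, 0]
    mean_profile = sub.mean(axis=1)
    if float(eg @ mean_profile) < 0:
        eg = -eg
    return eg


def module_trait_correlation(eigengenes: dict[str, np.ndarray],
                             P: PhenotypeTable,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r and two-sided p for every (module, trait) pair, with a
    significance flag at raw p < ``alpha``."""
    rows = []
    for label, eg in sorted(eigengenes.items()):
        for trait in P.trait_names:
            y = P.trait(trait)
            ok = ~np.isnan(y)
            if np.std(eg[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((label, trait, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(eg[ok], y[ok])
            rows.append((label, trait, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "significant"])


def lncrna_partners(lncrna_id: str, modules: dict[str, str]) -> set[str]:
    """Co-expression partners of a lncRNA = all other transcripts sharing its
    module label.  Unassigned lncRNA -> empty set with a warning."""
    label = modules.get(lncrna_id, UNASSIGNED)
    if label == UNASSIGNED:
        warnings.warn(f"lncRNA {lncrna_id!r} is not assigned to any module")
        return set()
    return {t for t, m in modules.items() if m == label and t != lncrna_id}


def correlation_partners(E: ExpressionMatrix, lncrna_id: str,
                         min_abs_r: float = 0.7) -> set[str]:
    """Module-free alternative partner definition: transcripts whose
    expression correlates with the lncRNA at |r| >= ``min_abs_r``."""
    x = E.column(lncrna_id)
    if np.std(x) == 0:
        return set()
    xs = (x - x.mean()) / x.std()
    Z = _standardize(E.values)
    r = Z.T @ xs / len(x)
    out = {t for t, rv in zip(E.transcripts, r) if abs(rv) >= min_abs_r}
    out.discard(lncrna_id)
    return out


def go_enrichment(target: set[str], background: set[str],
                  annotation: pd.DataFrame, q_cutoff: float = 0.05,
                  return_all: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of GO terms in ``target``.

    For each term with K annotated transcripts in the background, of which k
    fall in the target set of size n (background size N), the upper-tail
    hypergeometric p is P(X >= k).  Benjamini-Hochberg q-values are computed
    across all tested terms; results are filtered at q <= ``q_cutoff``
    (unless ``return_all``) and sorted by (q, p, term_id).  Terms with K = 0
    are skipped.  Annotations are treated as flat sets (no propagation up
    the ontology graph).
    """
    if not target <= background:
        raise ValueError("target set must be a subset of the background")
    ann = annotation[annotation["transcript_id"].isin(background)]
    N = len(background)
    n = len(target)
    rows = []
    for (term_id, term_name), group in sorted(
            ann.groupby(["term_id", "term_name"], sort=True)):
        members = set(group["transcript_id"])
        K = len(members)
        if K == 0:
            continue
        k = len(members & target)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append([term_id, term_name, k, K, p])
    if not rows:
        return []
    pvals = np.array([r[4] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(term_id=r[0], term_name=r[1], k_in_set=r[2],
                         K_in_background=r[3], n_set=n, N_background=N,
                         p_value=min(r[4], 1.0), q_value=float(min(q, 1.0)))
        for r, q in zip(rows, qvals)
    ]
    results.sort(key=lambda e: (e.q_value, e.p_value, e.term_id))
    if not return_all:
        results = [e for e in results if e.q_value <= q_cutoff]
    return results
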