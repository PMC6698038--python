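"""From scan hits to trait-related transcripts.

A transcript counts as *trait-related* when it is associated with the trait
at both levels: (i) at least one SNP physically located in the transcript
passes the Bonferroni threshold in the mixed-model scan, and (ii) the
transcript's expression correlates with the trait across the population at
raw Pearson P < 0.05 (no multiplicity adjustment on the expression filter —
that is the operative definition; a BH option exists behind a flag).  The
sign of the expression correlation gives the regulation direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PhenotypeTable, SnpRecord
from .popstruct import ThresholdSet

__all__ = [
    "PhenotypeSummary",
    "TraitRelatedTranscript",
    "summarize_phenotypes",
    "map_snps_to_transcripts",
    "expression_trait_correlation",
    "call_trait_related",
    "trait_related_frame",
]


@dataclass
class PhenotypeSummary:
    """Per-trait range/mean/SD/fold-range and pairwise trait correlations."""

    per_trait: pd.DataFrame  # index trait, columns min/max/mean/sd/fold_range
    correlations: pd.DataFrame  # columns trait_a, trait_b, r, p

    def fold_range_display(self, trait: str) -> str:
        v = self.per_trait.loc[trait, "fold_range"]
        return "undefined" if not np.isfinite(v) else f"{v:.1f}"


@dataclass(frozen=True)
class TraitRelatedTranscript:
    """A transcript passing both the genotype and expression filters."""

    transcript_id: str
    trait: str
    n_snps: int
    best_genotype_p: float
    expression_r: float
    expression_p: float
    direction: str  # "+" or "-"


def summarize_phenotypes(P: PhenotypeTable) -> PhenotypeSummary:
    """Population summary: min, max, mean, sd, fold_range = max/min per trait,
    plus pairwise Pearson r with two-sided p (t transform, n-2 df).

    fold_range is undefined (NaN) when min <= 0; rounding to one decimal
    happens only at display time.
    """
    rows = {}
    for t in P.trait_names:
        v = P.traits[t].dropna().to_numpy(dtype=float)
        lo, hi = float(v.min()), float(v.max())
        fold = hi / lo if lo > 0 else np.nan
        rows[t] = {"min": lo, "max": hi, "mean": float(v.mean()),
                   "sd": float(v.std(ddof=1)), "fold_range": fold}
    per_trait = pd.DataFrame.from_dict(rows, orient="index")

    pairs = []
    names = P.trait_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = P.traits[names[i]]
            b = P.traits[names[j]]
            ok = a.notna() & b.notna()
            if a[ok].std() == 0 or b[ok].std() == 0:
                pairs.append((names[i], names[j], np.nan, np.nan))
                continue
            r, p = stats.pearsonr(a[ok], b[ok])
            pairs.append((names[i], names[j], float(r), float(p)))
    corr = pd.DataFrame(pairs, columns=["trait_a", "trait_b", "r", "p"])
    return PhenotypeSummary(per_trait, corr)


def map_snps_to_transcripts(hits, snps: list[SnpRecord]) -> dict[str, list[str]]:
    """Group significant SNP hits by the transcript each SNP lies in.

    ``hits`` is a list of AssociationResult (or anything with ``snp_id``).
    Unknown snp_ids are a hard error.
    """
    where = {s.snp_id: s.transcript_id for s in snps}
    mapping: dict[str, list[str]] = {}
    for h in hits:
        sid = h.snp_id if hasattr(h, "snp_id") else str(h)
        if sid not in where:
            raise KeyError(f"unknown snp_id {sid!r}")
        mapping.setdefault(where[sid], []).append(sid)
    return {t: sorted(ids) for t, ids in sorted(mapping.items())}


def expression_trait_correlation(E: ExpressionMatrix, y: np.ndarray,
                                 candidates: list[str]) -> pd.DataFrame:
    """Pearson correlation of each candidate transcript's expression with the
    trait (two-sided p, t transform with n-2 df).

    Zero-variance expression yields (r = NaN, p = 1) with a flag rather than
    an error.  Samples with a missing trait value are dropped pairwise.
    """
    y = np.asarray(y, dtype=float).ravel()
    ok = ~np.isnan(y)
    rows = []
    for t in candidates:
        e = E.column(t)[ok]
        yy = y[ok]
        if np.std(e) == 0 or np.std(yy) == 0:
            rows.append((t, np.nan, 1.0, True))
            continue
        r, p = stats.pearsonr(e, yy)
        rows.append((t, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["transcript_id", "r", "p", "degenerate"])


def call_trait_related(mapping: dict[str, list[str]], best_p: dict[str, float],
                       correlations: pd.DataFrame, trait: str,
                       thresholds: ThresholdSet, expr_alpha: float = 0.05,
                       adjust: str | None = None) -> list[TraitRelatedTranscript]:
    """Intersect the genotype-significant transcript set with the
    expression-significant set for one trait.

    Parameters
    ----------
    mapping : transcript -> significant SNP ids (from the scan)
    best_p : transcript -> min genotype p over its significant SNPs
    correlations : output of :func:`expression_trait_correlation`
    adjust : None for the raw P < ``expr_alpha`` rule (the default,
        replication-faithful), or "bh" to apply Benjamini-Hochberg to the
        expression p-values first.
    """
    corr = correlations.set_index("transcript_id")
    pvals = corr["p"].copy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        pvals[:] = multipletests(pvals.to_numpy(), method="fdr_bh")[1]
    out = []
    for transcript, snp_ids in mapping.items():
        if transcript not in corr.index:
            continue
        row = corr.loc[transcript]
        if row["degenerate"] or not (pvals[transcript] < expr_alpha):
            continue
        gp = best_p[transcript]
        if gp > thresholds.bonferroni_p:
            continue
        out.append(TraitRelatedTranscript(
            transcript_id=transcript, trait=trait, n_snps=len(snp_ids),
            best_genotype_p=float(gp), expression_r=float(row["r"]),
            expression_p=float(row["p"]),
            direction="+" if row["r"] > 0 else "-",
        ))
    out.sort(key=lambda t: (t.trait, t.transcript_id))
    return out


def trait_related_frame(records: list[TraitRelatedTranscript]) -> pd.DataFrame:
    """Tabulate trait-related calls (the ``trait_related.tsv`` dialect).

    A transcript hitting two or more traits is flagged pleiotropic (one
    locus per SNP-located transcript; there is no physical map on a
    transcriptome reference to merge loci any further).
    """
    rows = [(t.trait, t.transcript_id, t.n_snps, t.best_genotype_p,
             t.expression_r, t.expression_p, t.direction) for t in records]
    df = pd.DataFrame(rows, columns=["trait", "transcript_id", "n_snps",
                                     "best_genotype_p", "expression_r",
                                     "expression_p", "direction"])
    counts = df.groupby("transcript_id")["trait"].nunique() if len(df) else {}
    df["pleiotropic"] = [bool(counts[t] > 1) for t in df["transcript_id"]] if len(df) else []
    return df
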