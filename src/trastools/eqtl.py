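"""eQTL scan over trait-related transcripts and the three-criterion
interrelation network.

An *eQTL* is a SNP significantly associated with a transcript's expression
treated as a quantitative phenotype in the same mixed model used for the
trait scan; the transcript carrying the SNP is the *eQTL-located
transcript*.  A directed interrelation edge B -> A is emitted when

1. a SNP located in transcript B is significantly associated with the
   expression of transcript A (B is an eQTL-located transcript of A),
2. both A and B are trait-related for the same trait, and
3. the expression of A correlates with the expression of B (P < 0.05).

Edges are annotated with the best eQTL p-value (G) and the
expression-correlation p-value (E), mirroring the standard display of such
networks.  Self-edges (cis records, A = B) are excluded from the network and
reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GenotypeMatrix
from .lmm import association_scan
from .popstruct import CovariateSet, KinshipMatrix

__all__ = [
    "EqtlRecord",
    "InterrelationEdge",
    "eqtl_scan",
    "classify_regulatory_position",
    "build_interrelation_network",
    "network_frame",
    "to_networkx",
    "to_dot",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EqtlRecord:
    snp_id: str
    located_transcript_id: str  # transcript carrying the SNP
    target_transcript_id: str  # transcript whose expression is the phenotype
    p_value: float


@dataclass(frozen=True)
class InterrelationEdge:
    """Directed B -> A regulatory relation satisfying all three criteria."""

    trait: str
    source_id: str  # B, the regulator (eQTL-located transcript)
    target_id: str  # A, the regulated transcript
    g_pvalue: float  # best eQTL p of B's SNPs on A's expression
    e_pvalue: float  # expression-expression correlation p
    e_r: float


def eqtl_scan(E: ExpressionMatrix, targets: list[str], W: CovariateSet,
              K: KinshipMatrix, G: GenotypeMatrix, threshold_p: float):
    """One full marker scan per target transcript.

    The variance ratio is re-estimated under the null for every expression
    phenotype (expression phenotypes differ in heritability).  Records are
    kept at p <= ``threshold_p``.  Returns ``(records, counts)`` where
    ``counts`` maps each target to (n associated SNPs, n distinct
    eQTL-located transcripts).
    """
    located = {s.snp_id: s.transcript_id for s in G.snps}
    records: list[EqtlRecord] = []
    counts: dict[str, tuple[int, int]] = {}
    for target in targets:
        try:
            y = E.column(target)
            _, sig = association_scan(y, W, K, G, threshold_p=threshold_p)
        except (ValueError, KeyError) as exc:
            log.warning("eQTL scan skipped target %s: %s", target, exc)
            continue
        here = [EqtlRecord(r.snp_id, located[r.snp_id], target, r.p_value)
                for r in sig]
        records.extend(here)
        counts[target] = (len(here), len({r.located_transcript_id for r in here}))
    return records, counts


def classify_regulatory_position(counts: dict[str, tuple[int, int]],
                                 upstream_max: int = 0,
                                 downstream_min: int = 50) -> dict[str, str]:
    """Label each target by how many SNPs regulate its expression.

    A transcript whose expression no SNP associates with (count <=
    ``upstream_max``) plausibly acts upstream in the pathway; one regulated
    by many loci (count >= ``downstream_min``) plausibly acts downstream.
    """
    labels = {}
    for target, (n_snps, _) in counts.items():
        if n_snps <= upstream_max:
            labels[target] = "upstream-candidate"
        elif n_snps >= downstream_min:
            labels[target] = "downstream-candidate"
        else:
            labels[target] = "intermediate"
    return labels


def build_interrelation_network(trait_related: dict[str, set[str]],
                                eqtl: list[EqtlRecord], E: ExpressionMatrix,
                                corr_alpha: float = 0.05,
                                require_positive_corr: bool = False):
    """Apply the three-criterion rule to eQTL records.

    Parameters
    ----------
    trait_related : trait -> set of trait-related transcript ids
    eqtl : records from :func:`eqtl_scan`
    corr_alpha : significance bar for the expression-expression correlation
    require_positive_corr : additionally require r > 0 (off by default:
        the correlation criterion is two-sided on significance alone)

    Returns ``(edges, cis_records)``; self-edges (cis eQTLs) are excluded
    from the network but returned separately.
    """
    cis = [r for r in eqtl if r.located_transcript_id == r.target_transcript_id]
    best: dict[tuple[str, str, str], float] = {}
    for rec in eqtl:
        b, a = rec.located_transcript_id, rec.target_transcript_id
        if b == a:
            continue
        for trait, related in trait_related.items():
            if b in related and a in related:  # criterion 2
                key = (trait, b, a)
                if rec.p_value < best.get(key, np.inf):  # criterion 1, dedup
                    best[key] = rec.p_value
    edges = []
    for (trait, b, a), gp in best.items():
        eb, ea = E.column(b), E.column(a)
        if np.std(eb) == 0 or np.std(ea) == 0:
            continue
        r, p = stats.pearsonr(ea, eb)
        if p >= corr_alpha:  # criterion 3
            continue
        if require_positive_corr and r <= 0:
            continue
        edges.append(InterrelationEdge(trait, b, a, float(gp), float(p), float(r)))
    edges.sort(key=lambda e: (e.trait, e.g_pvalue, e.source_id, e.target_id))
    return edges, cis


def network_frame(edges: list[InterrelationEdge]) -> pd.DataFrame:
    """Edge list as a DataFrame (the ``network.tsv`` dialect: trait, source,
    target, G, E, r)."""
    return pd.DataFrame(
        [(e.trait, e.source_id, e.target_id, e.g_pvalue, e.e_pvalue, e.e_r)
         for e in edges],
        columns=["trait", "source", "target", "G", "E", "r"])


def to_networkx(edges: list[InterrelationEdge]):
    """Directed graph with G/E annotations, for standard graph tooling."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source_id, e.target_id, trait=e.trait, G=e.g_pvalue,
                   E=e.e_pvalue, r=e.e_r)
    return g


def to_dot(edges: list[InterrelationEdge]) -> str:
    """GraphViz DOT export with G and E values printed on each edge."""
    lines = ["digraph interrelation {"]
    for e in edges:
        lines.append(
            f'  "{e.source_id}" -> "{e.target_id}" '
            f'[label="G={e.g_pvalue:.2g}\\nE={e.e_pvalue:.2g}"];'
        )
    lines.append("}")
    return "\n".join(lines)
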