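"""End-to-end orchestration: QC -> structure -> trait scans -> trait-related
calling -> eQTL -> interrelation network -> module/trait correlation -> GO
enrichment, with a manifest recording parameters, input checksums and
per-stage counts.

Two entry points:

* :func:`run_pipeline_data` — operates on in-memory containers (what tests
  and simulations use);
* :func:`run_full_pipeline` — reads the files named in a
  :class:`PipelineConfig`, runs the same computation, and writes every stage
  table plus ``manifest.json`` into the output directory.

The pipeline itself is deterministic given its inputs; the seed in the
config is only recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexpr import go_enrichment, module_eigengene, module_trait_correlation
from .eqtl import (build_interrelation_network, classify_regulatory_position,
                   eqtl_scan, network_frame)
from .io import (ExpressionMatrix, GenotypeMatrix, PhenotypeTable,
                 intersect_samples, read_expression, read_genotypes,
                 read_go_annotation, read_modules, read_phenotypes)
from .lmm import association_scan, results_to_frame
from .popstruct import (compute_kinship, compute_pcs, effective_marker_count,
                        significance_thresholds)
from .tras import (call_trait_related, expression_trait_correlation,
                   map_snps_to_transcripts, summarize_phenotypes,
                   trait_related_frame)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline_data",
           "run_full_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str
    expression: str
    phenotypes: str
    modules: str | None = None
    go_annotation: str | None = None
    outdir: str = "tras_run"

    maf_floor: float = 0.05
    missing_ceiling: float = 0.2
    n_pcs: int = 3
    #: "total" treats every marker as independent (m_eff = m, replicating
    #: the common practice behind a 0.05/m threshold); "li_ji" uses the
    #: eigenvalue-based effective marker count.
    m_eff_mode: str = "total"
    li_ji_block: int = 1000
    alpha: float = 0.05
    corr_alpha: float = 0.05
    expr_alpha: float = 0.05
    #: eQTL threshold: "bonferroni" reuses alpha/m_eff per target scan
    eqtl_threshold_mode: str = "bonferroni"
    log_transform: bool = True
    kinship_estimator: str = "centered"
    seed: int = 0

    def validate(self):
        for name in ("maf_floor", "missing_ceiling", "alpha", "corr_alpha",
                     "expr_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of range: {v}")
        if self.m_eff_mode not in ("total", "li_ji"):
            raise ValueError("m_eff_mode must be 'total' or 'li_ji'")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")


@dataclass
class PipelineResult:
    thresholds: object
    kinship: object
    covariates: object
    summary: object
    scans: dict  # trait -> DataFrame of all results
    significant: dict  # trait -> list[AssociationResult] at bonferroni
    suggestive: dict  # trait -> list[AssociationResult] at 1/m
    mappings: dict  # trait -> transcript -> [snp ids]
    trait_related: list
    eqtl_records: list
    eqtl_counts: dict
    positions: dict
    edges: list
    cis_records: list
    module_corr: pd.DataFrame | None
    enrichment: dict | None
    counts: dict = field(default_factory=dict)


def run_pipeline_data(G: GenotypeMatrix, E: ExpressionMatrix,
                      P: PhenotypeTable, modules: dict | None = None,
                      go_annotation: pd.DataFrame | None = None,
                      config: PipelineConfig | None = None) -> PipelineResult:
    """Run every analysis stage on aligned in-memory inputs."""
    cfg = config or PipelineConfig("", "", "")
    cfg.validate()

    samples = intersect_samples(G.samples, E.samples, P.samples)
    G = G.reorder(samples)
    E = E.reorder(samples)
    P = P.reorder(samples)
    if cfg.log_transform:
        E = E.log_transform()

    # --- structure ---------------------------------------------------------
    kinship = compute_kinship(G, estimator=cfg.kinship_estimator)
    covariates = compute_pcs(G, n_pcs=cfg.n_pcs)
    if cfg.m_eff_mode == "li_ji":
        m_eff = effective_marker_count(G, block_size=cfg.li_ji_block)
    else:
        m_eff = float(G.n_snps)
    thresholds = significance_thresholds(G.n_snps, m_eff, cfg.alpha)
    summary = summarize_phenotypes(P)

    # --- trait association scans ------------------------------------------
    scans, significant, suggestive, mappings = {}, {}, {}, {}
    trait_related = []
    for trait in P.trait_names:
        y = P.trait(trait)
        ok = ~np.isnan(y)
        if ok.sum() < covariates.W.shape[1] + 2:
            log.warning("trait %s: too few phenotyped samples, skipped", trait)
            continue
        sub = [s for s, keep in zip(samples, ok) if keep]
        results, sig = association_scan(
            y[ok], covariates.reorder(sub), kinship.reorder(sub),
            G.reorder(sub), threshold_p=thresholds.bonferroni_p)
        scans[trait] = results_to_frame(results, G)
        significant[trait] = sig
        suggestive[trait] = [r for r in results
                             if r.p_value <= thresholds.suggestive_p]
        mapping = map_snps_to_transcripts(sig, G.snps)
        mappings[trait] = mapping
        if mapping:
            by_snp = {r.snp_id: r.p_value for r in sig}
            best_p = {tr: min(by_snp[s] for s in ids)
                      for tr, ids in mapping.items()}
            corr = expression_trait_correlation(E, y, sorted(mapping))
            trait_related.extend(call_trait_related(
                mapping, best_p, corr, trait, thresholds,
                expr_alpha=cfg.expr_alpha))

    # --- eQTL scan over trait-related transcripts --------------------------
    targets = sorted({t.transcript_id for t in trait_related})
    eqtl_p = thresholds.bonferroni_p if cfg.eqtl_threshold_mode == "bonferroni" \
        else cfg.alpha
    eqtl_records, eqtl_counts = eqtl_scan(E, targets, covariates, kinship, G,
                                          threshold_p=eqtl_p)
    positions = classify_regulatory_position(eqtl_counts)

    # --- interrelation network ---------------------------------------------
    related_sets = {}
    for t in trait_related:
        related_sets.setdefault(t.trait, set()).add(t.transcript_id)
    edges, cis = build_interrelation_network(related_sets, eqtl_records, E,
                                             corr_alpha=cfg.corr_alpha)

    # --- module eigengenes x traits ----------------------------------------
    module_corr = None
    if modules:
        present = {t: m for t, m in modules.items() if t in set(E.transcripts)}
        labels = sorted({m for m in present.values() if m != "M00"})
        eigengenes = {}
        for lab in labels:
            try:
                eigengenes[lab] = module_eigengene(E, present, lab)
            except KeyError:
                continue
        module_corr = module_trait_correlation(eigengenes, P,
                                               alpha=cfg.corr_alpha)

    # --- lncRNA function prediction ----------------------------------------
    enrichment = None
    if go_annotation is not None and modules:
        annotated = set(go_annotation["transcript_id"])
        background = {t for t in E.transcripts if t in annotated}
        enrichment = {}
        related_ids = {t.transcript_id for t in trait_related}
        lnc_like = sorted(related_ids - annotated)
        for lid in lnc_like:
            lab = modules.get(lid, "M00")
            if lab == "M00":
                continue
            partners = {t for t, m in modules.items()
                        if m == lab and t != lid} & background
            if not partners:
                continue
            enrichment[lid] = go_enrichment(partners, background,
                                            go_annotation)

    counts = {
        "n_samples": len(samples),
        "n_snps": G.n_snps,
        "n_transcripts": len(E.transcripts),
        "m_eff": m_eff,
        "per_trait": {
            t: {"n_significant_snps": len(significant.get(t, [])),
                "n_snp_located_transcripts": len(mappings.get(t, {})),
                "n_suggestive_snps": len(suggestive.get(t, [])),
                "n_trait_related": sum(1 for x in trait_related
                                       if x.trait == t)}
            for t in P.trait_names},
        "n_eqtl_records": len(eqtl_records),
        "n_eqtl_located_transcripts":
            len({r.located_transcript_id for r in eqtl_records}),
        "n_network_edges": len(edges),
    }
    return PipelineResult(thresholds, kinship, covariates, summary, scans,
                          significant, suggestive, mappings, trait_related,
                          eqtl_records, eqtl_counts, positions, edges, cis,
                          module_corr, enrichment, counts)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes all stage tables and a manifest."""
    config.validate()
    for name in ("genotypes", "expression", "phenotypes"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} input does not exist: {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "STALE"
    stale.write_text("run in progress\n")

    G = read_genotypes(config.genotypes, maf_floor=config.maf_floor,
                       missing_ceiling=config.missing_ceiling)
    E = read_expression(config.expression)
    P = read_phenotypes(config.phenotypes)
    modules = read_modules(config.modules) if config.modules else None
    go = read_go_annotation(config.go_annotation) if config.go_annotation else None

    res = run_pipeline_data(G, E, P, modules, go, config)

    hdr = (f"# trastools {__version__} alpha={config.alpha} "
           f"m_eff={res.thresholds.m_eff:.10g} "
           f"bonferroni_p={res.thresholds.bonferroni_p:.6g} "
           f"suggestive_p={res.thresholds.suggestive_p:.6g}\n")

    def _write(df: pd.DataFrame, name: str):
        with open(out / name, "w") as fh:
            fh.write(hdr)
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                      float_format="%.10g")

    for trait, df in res.scans.items():
        _write(df, f"assoc_{trait}.tsv")
    _write(trait_related_frame(res.trait_related), "trait_related.tsv")
    _write(pd.DataFrame(
        [(r.snp_id, r.located_transcript_id, r.target_transcript_id, r.p_value)
         for r in res.eqtl_records],
        columns=["snp_id", "located_transcript", "target_transcript", "p"]),
        "eqtl.tsv")
    _write(network_frame(res.edges), "network.tsv")
    _write(res.summary.per_trait.reset_index(names="trait"),
           "phenotype_summary.tsv")
    _write(res.summary.correlations, "trait_correlations.tsv")
    if res.module_corr is not None:
        _write(res.module_corr, "module_trait.tsv")
    if res.enrichment is not None:
        rows = [(lid, e.term_id, e.term_name, e.k_in_set, e.K_in_background,
                 e.n_set, e.N_background, e.p_value, e.q_value)
                for lid, results in res.enrichment.items() for e in results]
        _write(pd.DataFrame(rows, columns=[
            "lncrna", "term_id", "term_name", "k", "K", "n", "N", "p", "q"]),
            "enrichment.tsv")

    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {name: {"path": str(getattr(config, name)),
                          "sha256": _sha256(getattr(config, name))}
                   for name in ("genotypes", "expression", "phenotypes",
                                "modules", "go_annotation")
                   if getattr(config, name)},
        "thresholds": {"m_total": res.thresholds.m_total,
                       "m_eff": res.thresholds.m_eff,
                       "bonferroni_p": res.thresholds.bonferroni_p,
                       "suggestive_p": res.thresholds.suggestive_p},
        "counts": res.counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True) + "\n")
    stale.unlink()
    return res
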