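"""Desk-scale synthetic cohorts with the statistical structure the pipeline
assumes, plus ground-truth tables and recovery scoring.

The generator emulates a clonal landrace association panel: ~102 accessions
from a few subpopulations, biallelic SNPs anchored to transcripts of a de
novo transcriptome, transcript abundance driven by co-expression module
factors plus cis and cascade (trans) genetic effects, and three positively
correlated quantitative traits calibrated to bulb weight (g), bulb diameter
(mm) and clove number scales.

Key modeling choices
--------------------
* Clonality: each accession's diploid genotype is drawn once (Balding-
  Nichols subpopulation frequencies at the configured Fst); there is no
  recombination and no Hardy-Weinberg enforcement — heterozygous accessions
  stay heterozygous.
* Regulatory cascades follow two motifs: a single-link motif
  (B1 genotype -> B1 expression -> A1 expression -> trait) and a convergent
  motif (B2 and B3 -> A2 -> trait), with the convergent target shared
  pleiotropically by two traits.  Link variances are sized so that every
  planted transcript's best SNP explains enough trait variance (~0.23-0.26)
  to clear a 0.05/m Bonferroni bar at n = 102.
* Planted causal SNPs are drawn without subpopulation differentiation so
  that recovery experiments measure the planted architecture rather than
  residual stratification; background SNPs carry the full Fst structure.
* Trait-trait correlations (defaults 0.92 BW-BD, 0.23 BW-CN, 0.36 BD-CN)
  are produced jointly by the shared convergent target and a correlated
  residual (polygenic + environmental) layer; the decomposition is solved
  from the targets at validation time and infeasible budgets fail fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, GenotypeMatrix, PhenotypeTable, SnpRecord,
                 write_expression, write_genotypes, write_go_annotation,
                 write_modules, write_phenotypes)
from .popstruct import compute_kinship

__all__ = ["SimulationConfig", "TruthTable", "Cohort", "simulate_cohort",
           "evaluate_recovery", "RecoveryReport", "realized_fst"]


@dataclass
class SimulationConfig:
    """All knobs of the generator.  Defaults are the study conditions."""

    n_samples: int = 102
    n_snps: int = 2000
    n_transcripts: int = 1000
    n_subpops: int = 3
    fst: float = 0.15

    trait_names: tuple = ("BW", "BD", "CN")
    trait_units: tuple = ("g", "mm", "count")
    trait_means: tuple = (21.0, 41.2, 12.7)
    trait_sds: tuple = (7.4, 6.7, 4.9)
    #: target Pearson correlations (BW-BD, BW-CN, BD-CN)
    trait_corr: tuple = (0.92, 0.23, 0.36)

    include_cascades: bool = True
    #: the single-link cascade regulates its trait negatively (exercises
    #: regulation-direction calling; mirrors negative regulators in panels)
    negative_single_link: bool = True
    cis_var: float = 0.95  # variance of a planted B transcript from its cis SNP
    single_link_path: float = 0.50  # var of A1 from B1's expression
    single_link_cis: float = 0.47  # var of A1 from its own cis SNP
    single_link_weight: float = 0.55  # var of CN from A1
    convergent_path: float = 0.3266  # var of A2 from each of B2, B3
    convergent_cis: float = 0.3168  # var of A2 from its own cis SNP
    shared_weight: float = 0.75  # var of BW and of BD from A2 (pleiotropy)
    ld_tag_flip: float = 0.08  # per-sample redraw prob for the LD tag SNP

    module_trait_r: float = 0.452  # target corr of one module factor with CN
    h_bg: float = 0.2  # polygenic share of each trait's residual

    n_modules: int = 10
    module_snr: float = 2.0
    assigned_fraction: float = 0.8
    lncrna_fraction: float = 0.03

    #: trait -> tuple of variance fractions for direct (non-expression-
    #: mediated) SNP effects, e.g. {"CN": (0.30,)}
    direct_snp_vars: dict = field(default_factory=dict)

    mean_log_expression: float = 6.0
    sd_log_expression: float = 1.0
    missing_rate: float = 0.0
    seed: int = 1

    # ---- derived structure -------------------------------------------------
    def _core_weights(self) -> dict:
        """Per-trait variance decomposition implied by the targets."""
        r_bwbd, r_bwcn, r_bdcn = self.trait_corr
        ws = self.shared_weight if self.include_cascades else 0.0
        w1 = self.single_link_weight if self.include_cascades else 0.0
        w2 = (r_bwcn ** 2 / ws) if ws > 0 else 0.0  # CN's loading on A2
        fv = self.module_trait_r ** 2
        resid = {
            "BW": 1.0 - ws,
            "BD": 1.0 - ws,
            "CN": 1.0 - w1 - w2 - fv,
        }
        core = {("BW", "BD"): ws, ("BW", "CN"): np.sqrt(ws * w2) if ws else 0.0,
                ("BD", "CN"): np.sqrt(ws * w2) if ws else 0.0}
        targets = {("BW", "BD"): r_bwbd, ("BW", "CN"): r_bwcn,
                   ("BD", "CN"): r_bdcn}
        R_e = np.eye(3)
        order = ["BW", "BD", "CN"]
        for (a, b), t in targets.items():
            i, j = order.index(a), order.index(b)
            denom = np.sqrt(resid[a] * resid[b])
            if denom <= 0:
                raise ValueError("infeasible variance budget: no residual variance")
            R_e[i, j] = R_e[j, i] = (t - core[(a, b)]) / denom
        return {"ws": ws, "w1": w1, "w2": w2, "fv": fv, "resid": resid, "R_e": R_e}

    def validate(self) -> dict:
        """Check every variance fraction and the residual-correlation
        decomposition; raise before any generation if infeasible."""
        if self.n_samples < 4 or self.n_snps < 1 or self.n_transcripts < 1:
            raise ValueError("cohort dimensions too small")
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if tuple(self.trait_names) != ("BW", "BD", "CN"):
            raise ValueError("the generator models exactly the BW/BD/CN trait trio")
        for name, v in [("cis_var", self.cis_var), ("h_bg", self.h_bg),
                        ("module_trait_r", abs(self.module_trait_r)),
                        ("assigned_fraction", self.assigned_fraction)]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.single_link_path + self.single_link_cis > 1:
            raise ValueError("infeasible variance budget for the single-link target")
        if 2 * self.convergent_path + self.convergent_cis > 1:
            raise ValueError("infeasible variance budget for the convergent target")
        d = self._core_weights()
        for t, r in d["resid"].items():
            if r < 0:
                raise ValueError(f"infeasible variance budget for trait {t}")
        if np.any(np.abs(d["R_e"]) > 1 + 1e-9):
            raise ValueError("infeasible residual correlation (|r| > 1)")
        if np.linalg.eigvalsh(d["R_e"])[0] < -1e-9:
            raise ValueError("infeasible residual correlation (not PSD)")
        for trait, vs in self.direct_snp_vars.items():
            if trait not in self.trait_names:
                raise ValueError(f"direct SNP effect on unknown trait {trait!r}")
            if sum(vs) > 1 or any(v < 0 for v in vs):
                raise ValueError("direct SNP variance fractions infeasible")
        if self.include_cascades and self.n_snps < 12:
            raise ValueError("need at least 12 SNPs for the planted architecture")
        return d


@dataclass
class TruthTable:
    """Everything the generator planted, keyed by emitted identifiers."""

    subpop: dict  # sample -> subpopulation index
    causal_snps: dict  # trait -> {snp_id: variance fraction} (direct + cis)
    snp_groups: dict  # transcript -> [primary cis snp, LD tag snp]
    direct_snps: dict  # trait -> [snp_id]
    causal_transcripts: dict  # trait -> {transcript_id: direction "+"/"-"}
    cascade_edges: list  # (trait, source_transcript, target_transcript)
    null_pairs: list  # (source, target) planted non-interacting ordered pairs
    module_labels: dict  # transcript -> module label
    cn_module: str  # the module whose factor drives CN
    enriched_terms: dict  # module -> signature GO term id
    lncrna_ids: list

    def to_json(self) -> str:
        d = asdict(self)
        d["cascade_edges"] = [list(e) for e in self.cascade_edges]
        d["null_pairs"] = [list(e) for e in self.null_pairs]
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class Cohort:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix  # abundance scale (not log-transformed)
    phenotypes: PhenotypeTable
    modules: dict
    go_annotation: pd.DataFrame
    truth: TruthTable

    def write(self, outdir) -> dict:
        """Write all tables through the io writers; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out / "genotypes.vcf",
            "expression": out / "expression.tsv",
            "phenotypes": out / "phenotypes.tsv",
            "modules": out / "modules.tsv",
            "go": out / "go_annotation.tsv",
            "truth": out / "truth.json",
            "config": out / "config.txt",
        }
        write_genotypes(self.genotypes, paths["genotypes"])
        write_expression(self.expression, paths["expression"])
        write_phenotypes(self.phenotypes, paths["phenotypes"])
        write_modules(self.modules, paths["modules"])
        write_go_annotation(self.go_annotation, paths["go"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        cfg = asdict(self.config)
        lines = [f"{k} = {v}" for k, v in sorted(cfg.items())]
        paths["config"].write_text("\n".join(lines) + "\n")
        return {k: str(v) for k, v in paths.items()}


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def _balding_nichols(rng, n_per_pop, n_snps, fst):
    """Dosages under the Balding-Nichols model: ancestral frequency
    Uniform(0.1, 0.9), subpopulation frequencies Beta-distributed at the
    configured Fst, one diploid draw per accession (clonal)."""
    p_anc = rng.uniform(0.1, 0.9, size=n_snps)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    cols = []
    for _ in range(len(n_per_pop)):
        cols.append(rng.beta(a, b))
    blocks = [rng.binomial(2, np.clip(pf, 0.01, 0.99), size=(npop, n_snps))
              for pf, npop in zip(cols, n_per_pop)]
    return np.vstack(blocks).astype(float)


def _undifferentiated_snp(rng, n) -> np.ndarray:
    """One planted SNP with a single population-wide frequency (and thus no
    stratification signal); redrawn until polymorphic with MAF >= 0.1."""
    while True:
        p = rng.uniform(0.25, 0.75)
        d = rng.binomial(2, p, size=n).astype(float)
        f = d.mean() / 2
        if 0.1 <= f <= 0.9 and d.std() > 0:
            return d


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one cohort (genotypes, expression, phenotypes, modules, GO
    annotation) plus its :class:`TruthTable`, fully reproducible from
    ``config.seed``."""
    derived = config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    samples = [f"L{i + 1:03d}" for i in range(n)]
    transcripts = [f"T{i + 1:04d}" for i in range(config.n_transcripts)]

    # subpopulations (balanced, remainder to the first pops)
    base = n // config.n_subpops
    n_per_pop = [base + (1 if i < n % config.n_subpops else 0)
                 for i in range(config.n_subpops)]
    subpop = {}
    k = 0
    for ipop, cnt in enumerate(n_per_pop):
        for _ in range(cnt):
            subpop[samples[k]] = ipop
            k += 1

    # ---- planted architecture ---------------------------------------------
    planted_names = ["B1", "A1", "B2", "B3", "A2"] if config.include_cascades else []
    n_direct = sum(len(v) for v in config.direct_snp_vars.values())
    n_planted_snps = 2 * len(planted_names) + n_direct
    n_background = config.n_snps - n_planted_snps
    if n_background < 0:
        raise ValueError("n_snps too small for the planted architecture")

    G_bg = _balding_nichols(rng, n_per_pop, n_background, config.fst)

    planted_transcripts: dict[str, str] = {}
    if planted_names:
        chosen = rng.choice(config.n_transcripts, size=len(planted_names),
                            replace=False)
        planted_transcripts = {nm: transcripts[i]
                               for nm, i in zip(planted_names, chosen)}

    planted_cols: list[np.ndarray] = []
    planted_meta: list[tuple[str, str]] = []  # (role, transcript_id)
    snp_groups: dict[str, list[str]] = {}
    cis_dosage: dict[str, np.ndarray] = {}
    for nm in planted_names:
        d = _undifferentiated_snp(rng, n)
        cis_dosage[nm] = d
        tag = d.copy()
        flip = rng.random(n) < config.ld_tag_flip
        tag[flip] = rng.binomial(2, d.mean() / 2, size=int(flip.sum()))
        planted_cols += [d, tag]
        planted_meta += [(f"cis:{nm}", planted_transcripts[nm]),
                         (f"tag:{nm}", planted_transcripts[nm])]
    direct_dosage: dict[str, list[np.ndarray]] = {}
    for trait, vs in sorted(config.direct_snp_vars.items()):
        direct_dosage[trait] = []
        for _ in vs:
            d = _undifferentiated_snp(rng, n)
            direct_dosage[trait].append(d)
            planted_cols.append(d)
            planted_meta.append((f"direct:{trait}", None))

    # ---- assemble the genotype matrix (planted columns shuffled in) -------
    m = config.n_snps
    all_cols = ([G_bg[:, j] for j in range(n_background)] + planted_cols)
    roles = [None] * n_background + [meta for meta in planted_meta]
    order = rng.permutation(m)
    dosages = np.column_stack([all_cols[j] for j in order])
    roles = [roles[j] for j in order]

    # transcript anchoring and positions
    alleles = ["A", "C", "G", "T"]
    pos_used: dict[str, set] = {}
    snps: list[SnpRecord] = []
    role_by_snp: dict[str, tuple] = {}
    for j in range(m):
        role = roles[j]
        if role is not None and role[1] is not None:
            tr = role[1]
        else:
            tr = transcripts[int(rng.integers(config.n_transcripts))]
        used = pos_used.setdefault(tr, set())
        pos = int(rng.integers(1, 2000))
        while pos in used:
            pos = int(rng.integers(1, 2000))
        used.add(pos)
        ref, alt = rng.choice(alleles, size=2, replace=False)
        sid = f"S{j + 1:05d}"
        snps.append(SnpRecord(sid, tr, pos, str(ref), str(alt)))
        if role is not None:
            role_by_snp[sid] = role
    genotypes = GenotypeMatrix(samples, snps, dosages,
                               qc_log={"source": "simulate_cohort",
                                       "seed": config.seed})

    # invert role map: planted name -> [cis snp id, tag snp id]
    cis_snp: dict[str, str] = {}
    tag_snp: dict[str, str] = {}
    direct_snp_ids: dict[str, list[str]] = {t: [] for t in direct_dosage}
    for sid, (kind, _tr) in role_by_snp.items():
        what, _, name = kind.partition(":")
        if what == "cis":
            cis_snp[name] = sid
        elif what == "tag":
            tag_snp[name] = sid
        elif what == "direct":
            direct_snp_ids[name].append(sid)
    for nm in planted_names:
        snp_groups[planted_transcripts[nm]] = [cis_snp[nm], tag_snp[nm]]

    # ---- expression latents ------------------------------------------------
    factors = rng.standard_normal((n, config.n_modules))
    module_names = [f"M{i + 1:02d}" for i in range(config.n_modules)]
    cn_module = module_names[config.n_modules // 2]
    f_star = factors[:, config.n_modules // 2]

    latent = np.empty((n, config.n_transcripts))
    module_labels: dict[str, str] = {}
    planted_set = set(planted_transcripts.values())
    n_assigned = int(round(config.assigned_fraction * config.n_transcripts))
    loading = np.sqrt(config.module_snr / (1 + config.module_snr))
    noiseload = np.sqrt(1 / (1 + config.module_snr))
    assign_idx = 0
    for i, tr in enumerate(transcripts):
        if tr in planted_set:
            continue  # filled below
        if assign_idx < n_assigned:
            mod = module_names[assign_idx % config.n_modules]
            module_labels[tr] = mod
            fm = factors[:, assign_idx % config.n_modules]
            latent[:, i] = loading * fm + noiseload * rng.standard_normal(n)
            assign_idx += 1
        else:
            module_labels[tr] = "M00"
            latent[:, i] = rng.standard_normal(n)

    cascade_edges: list[tuple] = []
    causal_transcripts: dict[str, dict] = {t: {} for t in config.trait_names}
    lat_planted: dict[str, np.ndarray] = {}
    if config.include_cascades:
        c = config.cis_var
        e = lambda: rng.standard_normal(n)
        z = {nm: _standardize(cis_dosage[nm]) for nm in planted_names}
        lat_planted["B1"] = np.sqrt(c) * z["B1"] + np.sqrt(1 - c) * e()
        q1, c1 = config.single_link_path, config.single_link_cis
        lat_planted["A1"] = (np.sqrt(q1) * _standardize(lat_planted["B1"])
                             + np.sqrt(c1) * z["A1"]
                             + np.sqrt(max(1 - q1 - c1, 0.0)) * e())
        lat_planted["B2"] = np.sqrt(c) * z["B2"] + np.sqrt(1 - c) * e()
        lat_planted["B3"] = np.sqrt(c) * z["B3"] + np.sqrt(1 - c) * e()
        q2, c2 = config.convergent_path, config.convergent_cis
        lat_planted["A2"] = (np.sqrt(q2) * _standardize(lat_planted["B2"])
                             + np.sqrt(q2) * _standardize(lat_planted["B3"])
                             + np.sqrt(c2) * z["A2"]
                             + np.sqrt(max(1 - 2 * q2 - c2, 0.0)) * e())
        for nm in planted_names:
            i = transcripts.index(planted_transcripts[nm])
            latent[:, i] = lat_planted[nm]
        # cascade modules: each motif is its own co-expression cluster
        module_labels[planted_transcripts["B1"]] = "M11"
        module_labels[planted_transcripts["A1"]] = "M11"
        for nm in ("B2", "B3", "A2"):
            module_labels[planted_transcripts[nm]] = "M12"
        tr_of = planted_transcripts
        sgn = "-" if config.negative_single_link else "+"
        causal_transcripts["CN"].update({tr_of["A1"]: sgn, tr_of["B1"]: sgn})
        for t in ("BW", "BD"):
            causal_transcripts[t].update({tr_of["A2"]: "+", tr_of["B2"]: "+",
                                          tr_of["B3"]: "+"})
        cascade_edges = [("CN", tr_of["B1"], tr_of["A1"]),
                         ("BW", tr_of["B2"], tr_of["A2"]),
                         ("BW", tr_of["B3"], tr_of["A2"]),
                         ("BD", tr_of["B2"], tr_of["A2"]),
                         ("BD", tr_of["B3"], tr_of["A2"])]

    # ---- traits ------------------------------------------------------------
    ws, w1, w2, fv = derived["ws"], derived["w1"], derived["w2"], derived["fv"]
    resid, R_e = derived["resid"], derived["R_e"]
    L = np.linalg.cholesky(R_e + 1e-10 * np.eye(3))
    K = compute_kinship(genotypes).K
    evals, evecs = np.linalg.eigh(K)
    K_half = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    g_mixed = K_half @ rng.standard_normal((n, 3)) @ L.T
    e_mixed = rng.standard_normal((n, 3)) @ L.T
    r_mat = np.column_stack([
        _standardize(np.sqrt(config.h_bg) * _standardize(g_mixed[:, j])
                     + np.sqrt(1 - config.h_bg) * _standardize(e_mixed[:, j]))
        for j in range(3)])

    a1s = _standardize(lat_planted["A1"]) if config.include_cascades else 0.0
    a2s = _standardize(lat_planted["A2"]) if config.include_cascades else 0.0
    sign1 = -1.0 if config.negative_single_link else 1.0
    raw = {
        "BW": np.sqrt(ws) * a2s + np.sqrt(resid["BW"]) * r_mat[:, 0],
        "BD": np.sqrt(ws) * a2s + np.sqrt(resid["BD"]) * r_mat[:, 1],
        "CN": (sign1 * np.sqrt(w1) * a1s + np.sqrt(w2) * a2s
               + np.sqrt(fv) * _standardize(f_star)
               + np.sqrt(resid["CN"]) * r_mat[:, 2]),
    }
    causal_snps: dict[str, dict] = {t: {} for t in config.trait_names}
    if config.include_cascades:
        causal_snps["CN"] = {cis_snp["A1"]: config.single_link_cis * w1,
                             cis_snp["B1"]: config.cis_var * config.single_link_path * w1}
        for t in ("BW", "BD"):
            causal_snps[t] = {
                cis_snp["A2"]: config.convergent_cis * ws,
                cis_snp["B2"]: config.cis_var * config.convergent_path * ws,
                cis_snp["B3"]: config.cis_var * config.convergent_path * ws,
            }
    values = {}
    for t in config.trait_names:
        base = raw[t]
        vs = config.direct_snp_vars.get(t, ())
        if vs:
            tot = sum(vs)
            parts = [np.sqrt(v) * _standardize(d)
                     for v, d in zip(vs, direct_dosage[t])]
            base = sum(parts) + np.sqrt(1 - tot) * _standardize(base)
            for v, sid in zip(vs, direct_snp_ids[t]):
                causal_snps[t][sid] = v
        i = config.trait_names.index(t)
        v = config.trait_means[i] + config.trait_sds[i] * _standardize(base)
        if t == "CN":
            v = np.maximum(v, 0.5)  # clove counts are strictly positive
        elif t == "BW":
            v = np.maximum(v, 0.1)
        else:
            v = np.maximum(v, 1.0)
        values[t] = np.round(v, 4)
    pheno = PhenotypeTable(
        samples,
        pd.DataFrame(values, index=samples)[list(config.trait_names)],
        units=dict(zip(config.trait_names, config.trait_units)))

    # ---- abundance ---------------------------------------------------------
    mu, sd = config.mean_log_expression, config.sd_log_expression
    abundance = np.round(2.0 ** (mu + sd * latent), 3)
    expression = ExpressionMatrix(samples, transcripts, abundance)

    # ---- GO annotation and lncRNA tags ------------------------------------
    lnc = set()
    if config.include_cascades:
        lnc |= {planted_transcripts["B1"], planted_transcripts["A2"]}
    extra = rng.choice(config.n_transcripts,
                       size=max(1, int(config.lncrna_fraction * config.n_transcripts)),
                       replace=False)
    lnc |= {transcripts[i] for i in extra if transcripts[i] not in planted_set}
    annotated = [t for t in transcripts if t not in lnc]
    rows = []
    enriched_terms = {}
    for imod, mod in enumerate(module_names):
        term = f"GO:{1000 + imod:07d}"
        enriched_terms[mod] = term
        members = [t for t in annotated if module_labels.get(t) == mod]
        take = rng.random(len(members)) < 0.7
        for t, keep in zip(members, take):
            if keep:
                rows.append((t, term, f"signature process {mod}"))
    for iterm in range(20):
        term = f"GO:{2000 + iterm:07d}"
        take = rng.random(len(annotated)) < 0.05
        for t, keep in zip(annotated, take):
            if keep:
                rows.append((t, term, f"background process {iterm}"))
    go = pd.DataFrame(rows, columns=["transcript_id", "term_id", "term_name"])

    # planted null pairs: ordered pairs among planted + the two strongest
    # module transcripts that are NOT planted edges
    null_pairs = []
    if config.include_cascades:
        hubs = [t for t in transcripts
                if module_labels.get(t) == cn_module][:2]
        nodes = [planted_transcripts[nm] for nm in planted_names] + hubs
        edge_set = {(s, t) for (_, s, t) in cascade_edges}
        for s in nodes:
            for t in nodes:
                if s != t and (s, t) not in edge_set:
                    null_pairs.append((s, t))

    truth = TruthTable(
        subpop=subpop, causal_snps=causal_snps, snp_groups=snp_groups,
        direct_snps=direct_snp_ids, causal_transcripts=causal_transcripts,
        cascade_edges=cascade_edges, null_pairs=null_pairs,
        module_labels=dict(module_labels), cn_module=cn_module,
        enriched_terms=enriched_terms, lncrna_ids=sorted(lnc))

    # optional missingness injected last so the truth dosages stay exact
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        genotypes = GenotypeMatrix(samples, snps,
                                   np.where(mask, np.nan, dosages),
                                   qc_log=dict(genotypes.qc_log))

    return Cohort(config, genotypes, expression, pheno, dict(module_labels),
                  go, truth)


def realized_fst(G: GenotypeMatrix, subpop: dict) -> float:
    """Mean per-SNP Fst estimate: Var_s(p_s) / (p(1-p)) across subpopulations."""
    labels = np.array([subpop[s] for s in G.samples])
    pops = sorted(set(labels))
    freqs = np.vstack([G.dosages[labels == p].mean(axis=0) / 2 for p in pops])
    pbar = G.dosages.mean(axis=0) / 2
    denom = pbar * (1 - pbar)
    ok = denom > 1e-6
    return float(np.mean(freqs[:, ok].var(axis=0, ddof=1) / denom[ok]))


@dataclass
class RecoveryReport:
    """Per-stage sensitivity / false-discovery recount against the truth."""

    snp_sensitivity_bonferroni: float | None
    snp_sensitivity_suggestive: float | None
    snp_false_positives: int
    trait_related_recall: float | None
    trait_related_precision: float | None
    direction_accuracy: float | None
    edge_recall: float | None
    edge_false_null_pairs: int
    enriched_term_recall: float | None


def _frac(hits, total):
    return None if total == 0 else hits / total


def evaluate_recovery(truth: TruthTable, *, significant_snps: dict,
                      suggestive_snps: dict | None = None,
                      trait_related=None, edges=None,
                      enrichment: dict | None = None) -> RecoveryReport:
    """Score pipeline outputs against the planted truth.

    Parameters
    ----------
    significant_snps : trait -> iterable of snp_ids passing the Bonferroni bar
    suggestive_snps : trait -> iterable of snp_ids passing the 1/m bar
    trait_related : list of TraitRelatedTranscript calls
    edges : list of InterrelationEdge
    enrichment : module -> list of EnrichmentResult (for modules whose
        signature term was planted)

    A planted causal signal counts as detected when its cis SNP *or* the
    SNP's LD tag passes the bar.  Cascade edges are scored at the
    transcript-pair level (recovered for any trait).
    """
    groups = {tr: set(g) for tr, g in truth.snp_groups.items()}

    def snp_sens(per_trait):
        hit = tot = 0
        fp = 0
        for trait, causal in truth.causal_snps.items():
            found = set(per_trait.get(trait, ()))
            signal_groups = []
            for sid in causal:
                grp = next((g for g in groups.values() if sid in g), {sid})
                signal_groups.append(grp)
            for grp in signal_groups:
                tot += 1
                if grp & found:
                    hit += 1
            allowed = set().union(*signal_groups) if signal_groups else set()
            fp += len(found - allowed)
        return _frac(hit, tot), fp

    sens_b, fp = snp_sens(significant_snps)
    sens_s = None
    if suggestive_snps is not None:
        sens_s, _ = snp_sens(suggestive_snps)

    tr_recall = tr_prec = dir_acc = None
    if trait_related is not None:
        truth_pairs = {(t, tr): d for t, m in truth.causal_transcripts.items()
                       for tr, d in m.items()}
        calls = {(c.trait, c.transcript_id): c.direction for c in trait_related}
        if truth_pairs:
            tr_recall = _frac(sum(1 for k in truth_pairs if k in calls),
                              len(truth_pairs))
        if calls:
            tr_prec = _frac(sum(1 for k in calls if k in truth_pairs), len(calls))
            on_truth = [(k, d) for k, d in calls.items() if k in truth_pairs]
            if on_truth:
                dir_acc = _frac(sum(1 for k, d in on_truth
                                    if d == truth_pairs[k]), len(on_truth))

    edge_recall = None
    false_null = 0
    if edges is not None:
        got_pairs = {(e.source_id, e.target_id) for e in edges}
        truth_edge_pairs = {(s, t) for (_, s, t) in truth.cascade_edges}
        if truth_edge_pairs:
            edge_recall = _frac(len(truth_edge_pairs & got_pairs),
                                len(truth_edge_pairs))
        false_null = sum(1 for p in truth.null_pairs if tuple(p) in got_pairs)

    term_recall = None
    if enrichment is not None and truth.enriched_terms:
        hit = tot = 0
        for mod, results in enrichment.items():
            want = truth.enriched_terms.get(mod)
            if want is None:
                continue
            tot += 1
            if any(r.term_id == want for r in results):
                hit += 1
        term_recall = _frac(hit, tot)

    return RecoveryReport(
        snp_sensitivity_bonferroni=sens_b,
        snp_sensitivity_suggestive=sens_s,
        snp_false_positives=fp,
        trait_related_recall=tr_recall,
        trait_related_precision=tr_prec,
        direction_accuracy=dir_acc,
        edge_recall=edge_recall,
        edge_false_null_pairs=false_null,
        enriched_term_recall=term_recall,
    )
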