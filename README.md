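# trastools

Transcriptome-referenced association study (TRAS) and eQTL-interrelation
analysis for clonal crop populations.

## The problem

Many crops — garlic is the motivating case — combine a huge, unassembled
genome with a strictly asexual life cycle, so neither genome-based GWAS nor
biparental QTL mapping is available. TRAS sidesteps the genome: SNPs are
called against a de novo **transcriptome** reference (each "chromosome" is a
transcript; positions are offsets within the transcript), association mapping
runs on a panel of clonal landraces, and candidate transcripts are validated
at the expression level in the same population. Because every marker sits
inside a transcript, significant SNPs point directly at candidate genes, and
treating each transcript's expression as a phenotype (eQTL analysis) lets the
same marker panel resolve regulatory relationships among the candidates.

`trastools` implements that analysis end to end for quantitative yield traits
(bulb weight **BW** in g, bulb diameter **BD** in mm, clove number **CN**),
plus a synthetic-cohort generator that emulates a ~102-landrace panel so every
stage can be benchmarked against planted ground truth without any download.

## The model

Per-marker tests use the single-variance-component linear mixed model

```
y = W a + x b + u + e,    u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)
```

where `y` is a trait (or one transcript's expression), `W` holds an intercept
and the first 3 genotype principal components (stratification), `x` is the
alt-allele dosage of one SNP, and `K` is the VanRaden genomic kinship built
from all SNPs. The variance ratio `delta = se^2/sg^2` is estimated by REML
through the eigendecomposition of `K` (exact EMMA-style profile likelihood),
then held fixed across markers (EMMAX approximation; an exact per-marker mode
exists). Each marker gets a Wald test `(b/se)^2 ~ F(1, n-c-1)`.

Study-wide significance uses Bonferroni at the effective number of
independent markers (`alpha / m_eff`, Li–Ji eigenvalue estimate or
`m_eff = m`), with a relaxed suggestive bar of `1/m`. A transcript is
**trait-related** when (1) a SNP inside it passes the Bonferroni bar and
(2) its expression correlates with the trait at Pearson P < 0.05. eQTL scans
over the trait-related transcripts then feed the **three-criterion
interrelation rule**: a directed edge B -> A requires a SNP in B associated
with A's expression, both A and B trait-related for the same trait, and
correlated A/B expression (P < 0.05). Co-expression modules are summarized by
their eigengene (first PC of standardized module expression) and correlated
with traits; unannotated (lncRNA-like) candidates are functionally annotated
by hypergeometric GO over-representation of their module partners with
Benjamini–Hochberg FDR control.

## Worked example

Generate a default synthetic cohort (102 accessions, 2,000 transcript-anchored
SNPs, 1,000 transcripts, three correlated traits with planted regulatory
cascades) and run every stage:

```bash
trastools simulate demo --seed 1
trastools all demo
```

The second command prints the per-stage counts (abridged):

```
{
 "n_samples": 102,
 "n_snps": 1942,
 "per_trait": {
  "BW": {"n_significant_snps": 3, "n_snp_located_transcripts": 2, "n_trait_related": 2},
  "BD": {"n_significant_snps": 4, "n_snp_located_transcripts": 3, "n_trait_related": 3},
  "CN": {"n_significant_snps": 4, "n_snp_located_transcripts": 2, "n_trait_related": 2}
 },
 "n_eqtl_records": 15,
 "n_eqtl_located_transcripts": 5,
 "n_network_edges": 4
}
```

Reading: QC keeps 1,942 of 2,000 SNPs (MAF >= 0.05); the scans find the
planted causal SNPs (e.g. 4 CN-significant SNPs falling in 2 transcripts —
the planted regulator/target pair); both filters together call 7
trait-related transcripts; and the eQTL stage links them into 4 directed
edges. `demo/results/network.tsv` carries the edge annotations, `G` (best
eQTL p-value of the regulator's SNPs on the target's expression) and `E`
(expression-correlation p-value):

```
trait  source  target  G              E              r
BD     T0465   T0660   7.31e-12       5.85e-11       0.59
BD     T0671   T0660   2.98e-07       5.97e-07       0.47
```

i.e. SNPs in `T0465` and `T0671` regulate the expression of `T0660`, the
planted convergent cascade. `demo/truth.json` holds the ground truth for
scoring (`trastools.simulate.evaluate_recovery`).

Stage-level subcommands (`qc`, `structure`, `assoc`, `tras`, `eqtl`,
`network`, `modules`, `enrich`, `phenosummary`) re-run individual pieces on
the same directory; the library API (`trastools.run_pipeline_data`) does the
same in memory.

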