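# Methods

This note documents the statistical models, the synthetic-cohort design and
the numerical choices behind `trastools`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mixed-model association engine

The engine fits `y = W a + x b + u + e` with `u ~ N(0, sg^2 K)`,
`e ~ N(0, se^2 I)` and tests one marker `x` at a time.

* **Rotation.** `K = U S U'` is eigendecomposed once per phenotype; rotating
  `y`, `W` and `x` by `U'` diagonalizes the covariance, so every likelihood
  evaluation and every marker's GLS fit is O(n·c).
* **REML profile in `delta = se^2/sg^2`.** `sg^2` is profiled out
  analytically. The profile is evaluated on 100 log-spaced points in
  `[1e-5, 1e5]`; every interior local maximum is refined with a bounded
  derivative-free scalar optimizer to `|d log10 delta| <= 1e-7` and the
  global maximizer kept. REML (not ML) is used, the convention for variance
  components. `delta` is optimized on the variance-normalized phenotype —
  the profile is scale-free, and normalizing makes the estimate exactly
  invariant to rescaling `y` (the reported log-likelihood is still evaluated
  on the raw phenotype).
* **EMMAX approximation.** `delta` is estimated once under the null
  (no-marker) model and fixed across the scan; `exact_per_marker=True`
  re-optimizes it per marker. For eQTL scans the null is re-fit for every
  expression phenotype, since expression phenotypes differ in heritability.
* **Test.** Wald `(b/se)^2` against `F(1, n-c-1)` where `c` counts the
  covariate columns including the intercept. A marker collinear with the
  covariates (weighted residual variance below `1e-10` of its scale) returns
  `p = 1` with a degeneracy flag instead of raising, so scans never abort.
* **Reductions.** With `K = I` the engine is algebraically ordinary least
  squares; the tests assert agreement with OLS p-values to 1e-8 and with
  explicitly inverted dense GLS to 1e-8.

## Structure correction and thresholds

* **Kinship.** Default "centered" estimator is VanRaden's:
  `K = Z Z' / sum_j 2 p_j (1-p_j)` with `Z` column-centered dosages; the
  denominator puts the mean diagonal near 1. A "standardized" variant
  divides each column by its SD. Column centering makes `Z` rank-deficient
  (rows of the raw `K` sum to zero), so the smallest eigenvalue is ~0 and a
  ridge of `1e-6 I` is added whenever it falls below `1e-8` — in practice
  always. Heterozygotes are kept as dosage 1 and no Hardy–Weinberg filter is
  applied: the panel is clonal, heterozygosity is fixed within an accession.
* **PCs.** Scores are `U Sigma` from the SVD of centered dosages; the sign
  of each component is fixed by making its largest-magnitude marker loading
  positive. Default 3 PCs as fixed effects.
* **Effective marker count.** Li–Ji: `M_eff = sum_i [I(lam_i >= 1) +
  (lam_i - floor(lam_i))]` over eigenvalues of the marker correlation
  matrix, computed block-wise (default 1,000 consecutive markers) and
  summed, mirroring per-chromosome practice. Eigenvalues within `1e-9` of an
  integer are snapped first: the floor makes the formula discontinuous at
  integers, and without snapping a duplicated marker pair (exact eigenvalues
  {2, 0}) would count as ~2 instead of 1 through floating-point noise.
* **Thresholds.** `bonferroni_p = alpha/m_eff`, `suggestive_p = 1/m_total`.
  The default pipeline mode treats all markers as independent
  (`m_eff = m`), replicating the common 0.05/m practice at the study scale
  (0.05/19,912 ≈ 2.5e-6; 1/19,912 ≈ 5e-5); `li_ji` is the principled
  alternative behind a flag.

## Trait-related transcripts and the interrelation network

The genotype filter takes the transcripts carrying Bonferroni-significant
SNPs (best SNP p per transcript); the expression filter is raw Pearson
P < 0.05 of (log2-transformed) expression against the trait, deliberately
without multiplicity adjustment — that is the operative definition of the
validation step; a BH option exists behind a flag. Regulation direction is
the sign of the correlation. One locus is reported per SNP-located
transcript (a transcriptome reference has no physical map to merge loci
further); transcripts hitting two or more traits are flagged pleiotropic.

Interrelation edges B→A require (1) a SNP in B associated with A's
expression at the eQTL threshold, (2) A and B trait-related for the same
trait, (3) correlated A/B expression at P < 0.05. Criterion 3 accepts either
correlation sign by default (`require_positive_corr` enforces r > 0).
Self-edges (cis records) are excluded from the network and reported
separately. `g_pvalue` is the minimum over B's qualifying SNPs; edges are
deduplicated per (trait, source, target). Targets regulated by no SNP are
labelled upstream candidates; by >= 50 SNPs, downstream candidates.

## Modules and GO enrichment

Module detection is out of scope; labels are inputs. Each module is
summarized by its eigengene — the first left singular vector of the
per-transcript standardized expression submatrix, unit norm, sign fixed to
correlate positively with the module's mean profile ("module eigenvalues"
cannot be correlated with a trait across samples; the eigengene is the only
dimensionally consistent reading). lncRNA co-expression partners are the
transcripts sharing the lncRNA's module (a correlation-threshold alternative
exists for module-free use). Enrichment is the hypergeometric upper tail
P(X >= k) per term with BH q-values across all tested terms; annotations are
flat sets (no propagation up the ontology graph — a known limitation).

## The synthetic cohort

The generator's defaults are the study conditions: 102 accessions in 3
subpopulations, Balding–Nichols genotypes at Fst 0.15 (ancestral frequencies
Uniform(0.1, 0.9), Beta-distributed subpopulation frequencies, one diploid
draw per accession — clonal, no recombination, no HWE enforcement), 2,000
transcript-anchored SNPs and 1,000 transcripts at desk scale, and the
BW/BD/CN trait trio rescaled to 21.0±7.4 g, 41.2±6.7 mm and 12.7±4.9 with
target correlations 0.92 (BW–BD), 0.23 (BW–CN), 0.36 (BD–CN). Clove counts
are clipped to be positive (a <1% edge event at these scales).

Expression is built on a log2 latent scale (mean 6, SD 1) and exponentiated
to abundance, so the pipeline's log2(x+1) transform recovers the latent
structure almost exactly; 10 module factors drive 80% of transcripts at
signal-to-noise 2.

**Planted architecture.** Two cascade motifs mirror the shapes such networks
take in practice:

* single-link (CN): cis SNP → regulator B1 (93–95% of its variance) →
  target A1 (50% from B1, 47% from A1's own cis SNP) → CN (55% of trait
  variance, negative sign by default so direction-calling is exercised);
* convergent (BW and BD, pleiotropic): B2 and B3 (cis 95%) each contribute
  ~33% of A2, which also has its own cis SNP (~32%) and explains 75% of both
  BW and BD.

Link variances were sized by a power analysis *before* any recovery test was
run: each planted transcript's best SNP explains ~0.23–0.26 of its trait, the
variance needed for a single marker to clear the 0.05/2,000 Bonferroni bar
with ~0.9 power at n = 102 (the same order as the 30%-variance planted-SNP
benchmark). Each planted transcript carries a second SNP in tight LD
(per-sample redraw probability 0.08) — multiple associated SNPs per
transcript, as marker panels show. Planted causal SNPs are drawn without
subpopulation differentiation, a deliberate design choice so that recovery
experiments measure the planted architecture rather than residual
stratification; background SNPs carry the full Fst structure.

The trait-correlation targets are met jointly: BW–CN and part of BD–CN come
from CN's small loading on the shared convergent target (pleiotropy), the
remainder from a correlated residual layer (Cholesky-mixed polygenic +
environmental noise; polygenic share 0.2 via the realized kinship square
root). The decomposition is solved from the targets at validation time and
infeasible budgets fail before generation. One module factor additionally
feeds CN so that its eigengene–CN correlation targets 0.452. GO annotation
plants one signature term per module (70% coverage) over 20 background
terms; a few transcripts (including two planted ones) are left unannotated
as lncRNA-like.

**What the generator does not emulate:** genome-scale LD beyond the
single-tag-SNP device, expression population structure for non-planted
transcripts, count-level measurement noise, replicate/year structure
(phenotypes are per-accession means), and missing genotypes by default
(available via `missing_rate`). Passing recovery tests therefore show the
pipeline's filters behave as designed under the stated architecture, not
that comparable power holds for arbitrary real data.

## Problem sizes used in tests and the acceptance script

Desk-scale runs use the default 2,000 SNPs × 1,000 transcripts × 102
accessions (one full pipeline ≈ 2–3 s). Calibration uses 25 null cohorts of
200 markers; recovery uses 20 cohorts at the default scale; enrichment
calibration uses 100 random-target draws on a 600-transcript background.
These sizes keep every simulated estimate's Monte-Carlo error well inside
the asserted bands.

## Known limitations

* Single variance component only; no multivariate-trait or Bayesian sparse
  models.
* The expression filter's raw P < 0.05 is intentionally unadjusted;
  expect false positives at scale (the BH flag exists).
* Flat-set GO testing; no ontology propagation.
* The Li–Ji block approximation ignores between-block correlation, slightly
  overestimating `m_eff` for long-range LD (conservative thresholds).
* `classify_regulatory_position` thresholds (0 / 50 SNPs) are descriptive
  labels, not inference.
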