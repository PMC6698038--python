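"""Readers, writers and in-memory containers for every table the pipeline touches.

Genotypes arrive as VCF whose CHROM column holds a *transcript* identifier
(the reference is a de novo transcriptome, not a genome) and whose POS is the
1-based offset of the SNP within that transcript.  Expression, phenotypes,
module assignments and GO annotations are plain TSV with a header row.

All containers hold numpy arrays sample-major (rows = accessions) and are
aligned downstream through :func:`intersect_samples` / ``reorder``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "SnpRecord",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_modules",
    "write_modules",
    "read_go_annotation",
    "write_go_annotation",
    "intersect_samples",
]

#: header comment prepended to every TSV this package writes
_HEADER_TAG = "# trastools"


class ParseError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP anchored to a transcript.

    ``position`` is 1-based and inclusive, matching VCF POS.
    """

    snp_id: str
    transcript_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix (entries 0/1/2, mean-imputed).

    Heterozygotes are retained as dosage 1: the population is clonal, so
    heterozygosity is fixed within an accession and no Hardy-Weinberg
    filtering applies.  ``dosages`` is float because missing calls are
    mean-imputed per SNP after QC; ``n_missing`` records how many calls were
    imputed per SNP.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray  # (n, m) float
    n_missing: np.ndarray | None = None
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError("dosage matrix shape does not match sample/SNP lists")
        if self.n_missing is None:
            self.n_missing = np.zeros(m, dtype=int)
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in genotype matrix")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def transcript_ids(self) -> list[str]:
        """Transcript carrying each SNP (length m, with repeats)."""
        return [s.transcript_id for s in self.snps]

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per SNP (dosages are already imputed)."""
        return self.dosages.mean(axis=0) / 2.0

    def reorder(self, samples: list[str]) -> "GenotypeMatrix":
        idx = _sample_indexer(self.samples, samples, "genotype matrix")
        return replace(self, samples=list(samples), dosages=self.dosages[idx])

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]


@dataclass
class ExpressionMatrix:
    """Samples x transcripts non-negative abundance matrix.

    ``transformed`` records whether log2(value + 1) has been applied; all
    correlation and eQTL computations in this package expect the transformed
    scale (variance stabilization for abundance data).
    """

    samples: list[str]
    transcripts: list[str]
    values: np.ndarray  # (n, t) float
    transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.transcripts)):
            raise ValueError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if not self.transformed and np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def log_transform(self) -> "ExpressionMatrix":
        if self.transformed:
            return self
        return replace(self, values=np.log2(self.values + 1.0), transformed=True)

    def reorder(self, samples: list[str]) -> "ExpressionMatrix":
        idx = _sample_indexer(self.samples, samples, "expression matrix")
        return replace(self, samples=list(samples), values=self.values[idx])

    def column(self, transcript_id: str) -> np.ndarray:
        try:
            j = self.transcripts.index(transcript_id)
        except ValueError:
            raise KeyError(f"transcript {transcript_id!r} not in expression matrix")
        return self.values[:, j]


@dataclass
class PhenotypeTable:
    """Samples x traits table of quantitative phenotypes.

    Values may already be per-accession means across replicates.  ``units``
    maps trait name to its unit string (e.g. BW -> g, BD -> mm, CN -> count).
    """

    samples: list[str]
    traits: pd.DataFrame  # index = samples, one column per trait
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.traits.index) != list(self.samples):
            self.traits = self.traits.loc[self.samples]
        for t in self.traits.columns:
            if self.traits[t].notna().sum() < 3:
                raise ValueError(f"trait {t!r} has fewer than 3 non-missing values")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name].to_numpy(dtype=float)

    def reorder(self, samples: list[str]) -> "PhenotypeTable":
        _sample_indexer(self.samples, samples, "phenotype table")
        return PhenotypeTable(list(samples), self.traits.loc[samples], dict(self.units))


def _sample_indexer(have: list[str], want: list[str], what: str) -> np.ndarray:
    pos = {s: i for i, s in enumerate(have)}
    missing = [s for s in want if s not in pos]
    if missing:
        raise KeyError(f"samples absent from {what}: {missing[:5]}")
    return np.array([pos[s] for s in want], dtype=int)


def intersect_samples(*sample_lists: list[str]) -> list[str]:
    """Common samples across inputs, in a canonical (lexicographic) order.

    Sorting makes the intersection independent of the ordering of any input
    file, so every downstream module sees the same alignment.
    """
    common = set(sample_lists[0])
    for lst in sample_lists[1:]:
        common &= set(lst)
    if not common:
        raise ValueError("sample intersection across inputs is empty")
    return sorted(common)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, maf_floor: float = 0.05, missing_ceiling: float = 0.2) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a QC'd dosage matrix.

    CHROM is interpreted as the transcript identifier.  Multi-allelic and
    non-SNP records are skipped with a warning.  SNPs that are monomorphic,
    below the MAF floor, or above the missingness ceiling are removed;
    removal counts are recorded in ``qc_log``.  Missing dosages are
    mean-imputed per SNP after QC.

    Raises
    ------
    ParseError
        If the file cannot be parsed as VCF, or zero SNPs survive QC.
    """
    if not 0 <= maf_floor <= 0.5:
        raise ValueError("maf_floor must be in [0, 0.5]")
    if not 0 <= missing_ceiling <= 1:
        raise ValueError("missing_ceiling must be in [0, 1]")
    try:
        from cyvcf2 import VCF
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_skipped_multiallelic = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped_multiallelic += 1
            warnings.warn(
                f"skipping non-biallelic/non-SNP record at {var.CHROM}:{var.POS}"
            )
            continue
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rec = SnpRecord(snp_id, var.CHROM, var.POS, var.REF, var.ALT[0])
        col = np.empty(len(samples))
        for k, gt in enumerate(var.genotypes):
            a = gt[:-1]  # last element is the phased flag
            col[k] = np.nan if any(x < 0 for x in a) else float(sum(x > 0 for x in a))
        snps.append(rec)
        columns.append(col)
    if not snps:
        raise ParseError(f"no biallelic SNP records in {path}")

    raw = np.column_stack(columns)
    return _qc_dosages(samples, snps, raw, maf_floor, missing_ceiling,
                       extra_log={"skipped_multiallelic": n_skipped_multiallelic})


def _qc_dosages(samples, snps, raw, maf_floor, missing_ceiling, extra_log=None) -> GenotypeMatrix:
    n = raw.shape[0]
    miss_frac = np.isnan(raw).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(raw, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    n_distinct = np.array(
        [len(np.unique(raw[~np.isnan(raw[:, j]), j])) for j in range(raw.shape[1])]
    )
    high_miss = miss_frac > missing_ceiling
    mono = (n_distinct < 2) & ~high_miss
    low_maf = (maf < maf_floor) & ~mono & ~high_miss
    keep = ~(high_miss | mono | low_maf)
    if not keep.any():
        raise ParseError("zero SNPs survive QC")
    kept = raw[:, keep]
    n_missing = np.isnan(kept).sum(axis=0).astype(int)
    # mean imputation per SNP, after QC, before any matrix algebra
    col_mean = np.nanmean(kept, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(kept))
    kept[nan_r, nan_c] = col_mean[nan_c]
    log = {
        "n_input": raw.shape[1],
        "removed_high_missing": int(high_miss.sum()),
        "removed_monomorphic": int(mono.sum()),
        "removed_low_maf": int(low_maf.sum()),
        "n_kept": int(keep.sum()),
        "maf_floor": maf_floor,
        "missing_ceiling": missing_ceiling,
    }
    log.update(extra_log or {})
    return GenotypeMatrix(
        samples=list(samples),
        snps=[s for s, k in zip(snps, keep) if k],
        dosages=kept,
        n_missing=n_missing,
        qc_log=log,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 (GT field only).

    Non-integer (imputed) dosages are rounded to the nearest genotype for
    output; missing calls are emitted as ``./.``.
    """
    contigs = sorted({s.transcript_id for s in G.snps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=trastools\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j, snp in enumerate(G.snps):
            calls = []
            for d in G.dosages[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(_GT_CODE[float(round(d))])
            fh.write(
                f"{snp.transcript_id}\t{snp.position}\t{snp.snp_id}\t"
                f"{snp.ref_allele}\t{snp.alt_allele}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})


def read_expression(path, log_transform: bool = False) -> ExpressionMatrix:
    """Read a samples x transcripts abundance TSV.

    The header row holds transcript ids and the first column sample ids.
    Negative or non-numeric cells are hard errors (the offending coordinates
    are named).
    """
    df = _read_tsv(path)
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(
                f"non-numeric expression value at sample={bad!r}, transcript={col!r}"
            )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"negative expression value at sample={df.index[i]!r}, "
            f"transcript={df.columns[j]!r}"
        )
    mat = ExpressionMatrix(
        samples=[str(s) for s in df.index],
        transcripts=[str(c) for c in df.columns],
        values=values,
    )
    return mat.log_transform() if log_transform else mat


def write_expression(E: ExpressionMatrix, path, params: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_TAG} expression transformed={E.transformed} {params}\n")
        df = pd.DataFrame(E.values, index=E.samples, columns=E.transcripts)
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")


def read_phenotypes(path, units: dict | None = None) -> PhenotypeTable:
    """Read a samples x traits TSV; "NA" and empty cells become missing."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     na_values=["NA", ""], dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate sample id in phenotype table: {dup!r}")
    df = df.apply(pd.to_numeric, errors="raise")
    return PhenotypeTable([str(s) for s in df.index], df, units or {})


def write_phenotypes(P: PhenotypeTable, path, params: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_TAG} phenotypes units={P.units} {params}\n")
        out = P.traits.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")


def read_modules(path) -> dict[str, str]:
    """Read transcript -> module-label assignments (TSV: transcript_id, module)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError("module table needs columns: transcript_id, module")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_modules(modules: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_TAG} module assignments\n")
        fh.write("transcript_id\tmodule\n")
        for t, m in modules.items():
            fh.write(f"{t}\t{m}\n")


def read_go_annotation(path) -> pd.DataFrame:
    """Read a GAF-lite GO TSV: transcript_id, term_id, term_name."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"transcript_id", "term_id"}
    if not need.issubset(df.columns):
        raise ParseError("GO annotation needs columns: transcript_id, term_id[, term_name]")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df[["transcript_id", "term_id", "term_name"]]


def write_go_annotation(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_TAG} GO annotation\n")
        annotation.to_csv(fh, sep="\t", index=False, lineterminator="\n")
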