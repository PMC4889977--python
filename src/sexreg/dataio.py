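"""Shared data model and file I/O.

All statistics live elsewhere; this module only defines the typed containers
used across the pipeline (genotypes, expression, annotation, peaks, allelic
counts, GWAS catalog) and reads/writes their on-disk formats.

Conventions fixed project-wide:

* sex is coded male = 0, female = 1, so sex and genotype-by-sex regression
  coefficients are positive when the effect is larger in females;
* VCF and gene annotation use 1-based inclusive coordinates, BED intervals
  are 0-based half-open;
* missing genotypes are NaN in dosage matrices and excluded per gene-variant
  pair from regressions (complete-case analysis);
* on chromosome X, males are hemizygous: a male carries one allele, coded
  either ``full_dosage`` (ref = 0, alt = 2, so one male allele carries the
  same regression dosage as a female homozygote) or ``haploid`` (ref = 0,
  alt = 1).  ``full_dosage`` is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MALE = 0
FEMALE = 1

X_CHROM_NAMES = frozenset({"X", "chrX", "x", "chrx", "23"})

FULL_DOSAGE = "full_dosage"
HAPLOID = "haploid"


def is_x(chrom: str | np.ndarray) -> np.ndarray | bool:
    """True for chromosome-X labels under common naming schemes."""
    if isinstance(chrom, str):
        return chrom in X_CHROM_NAMES
    return np.isin(np.asarray(chrom, dtype=object), list(X_CHROM_NAMES))


@dataclass
class SampleInfo:
    """Cohort sample sheet: ids plus sex codes (0 = male, 1 = female)."""

    sample_ids: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        if len(self.sample_ids) != len(self.sex):
            raise ValueError("sample_ids and sex must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if not np.isin(self.sex, [MALE, FEMALE]).all():
            raise ValueError("sex codes must be 0 (male) or 1 (female)")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_male(self) -> int:
        return int((self.sex == MALE).sum())

    @property
    def n_female(self) -> int:
        return int((self.sex == FEMALE).sum())


@dataclass
class GenotypeMatrix:
    """Variant x sample dosage matrix with X-aware coding metadata.

    ``dosage`` holds floats with NaN for missing calls.  Autosomal dosages
    are 0/1/2; chrX male dosages are {0, 2} under ``full_dosage`` or {0, 1}
    under ``haploid``; chrX female dosages are 0/1/2.
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    samples: SampleInfo
    x_coding: str = FULL_DOSAGE

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.x_coding not in (FULL_DOSAGE, HAPLOID):
            raise ValueError(f"unknown x_coding {self.x_coding!r}")
        n_var = len(self.variant_ids)
        if not (len(self.chrom) == len(self.pos) == self.dosage.shape[0] == n_var):
            raise ValueError("variant metadata and dosage rows disagree")
        if self.dosage.shape[1] != self.samples.n:
            raise ValueError("dosage columns and samples disagree")
        if (self.pos <= 0).any():
            raise ValueError("positions must be positive (1-based)")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def row(self, variant_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(variant_id)
        return self.dosage[idx[0]]


@dataclass
class GeneAnnotation:
    """Gene coordinates with TSS/TES normalized to genomic orientation.

    ``table`` columns: gene_id, chrom, tss, tes, strand.  After construction
    tss <= tes in genomic coordinates regardless of strand; ``strand`` keeps
    the transcriptional orientation for strand-aware windows.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"gene_id", "chrom", "tss", "tes", "strand"}
        if not required.issubset(t.columns):
            raise ValueError(f"annotation missing columns {required - set(t.columns)}")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_ids in annotation")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        lo = np.minimum(t["tss"], t["tes"])
        hi = np.maximum(t["tss"], t["tes"])
        t["tss"], t["tes"] = lo.astype(np.int64), hi.astype(np.int64)
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def strand_tss(self) -> pd.Series:
        """Transcription start in transcriptional orientation (promoter end)."""
        t = self.table
        return pd.Series(
            np.where(t["strand"] == "+", t["tss"], t["tes"]),
            index=t.index, name="strand_tss",
        )


COUNTS = "counts"
RESIDUALS = "residuals"


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values: raw counts or corrected residuals."""

    gene_ids: np.ndarray
    values: np.ndarray
    samples: SampleInfo
    kind: str = RESIDUALS

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in (COUNTS, RESIDUALS):
            raise ValueError(f"unknown expression kind {self.kind!r}")
        if self.values.shape != (len(self.gene_ids), self.samples.n):
            raise ValueError("values shape must be (n_genes, n_samples)")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.kind == COUNTS:
            if (self.values < 0).any() or (self.values != np.round(self.values)).any():
                raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(gene_id)
        return self.values[idx[0]]


@dataclass
class PeakCountMatrix:
    """ATAC peak x sample integer counts with BED (0-based half-open) intervals."""

    peaks: pd.DataFrame  # columns peak_id, chrom, start, end
    counts: np.ndarray
    samples: SampleInfo

    def __post_init__(self) -> None:
        p = self.peaks.reset_index(drop=True)
        required = {"peak_id", "chrom", "start", "end"}
        if not required.issubset(p.columns):
            raise ValueError(f"peaks missing columns {required - set(p.columns)}")
        if p["peak_id"].duplicated().any():
            raise ValueError("duplicate peak_ids")
        if (p["start"] >= p["end"]).any():
            raise ValueError("BED intervals require start < end")
        self.peaks = p
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if (self.counts != np.round(self.counts)).any() or (self.counts < 0).any():
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(p), self.samples.n):
            raise ValueError("counts shape must be (n_peaks, n_samples)")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class AseTable:
    """Haplotype-resolved allelic counts per (individual, gene, site).

    Columns: individual, gene_id, site, ref_count, alt_count, h, sex.
    ``h`` is the phased regulatory-genotype contrast in {-1, 0, +1}: the sign
    says which haplotype carries the regulatory alt allele; h = 0 rows
    (regulatory-homozygous individuals) inform the baseline only.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"individual", "gene_id", "site", "ref_count", "alt_count", "h", "sex"}
        if not required.issubset(t.columns):
            raise ValueError(f"ase table missing columns {required - set(t.columns)}")
        for c in ("ref_count", "alt_count"):
            if (t[c] < 0).any():
                raise ValueError("allelic counts must be non-negative")
        if not t["h"].isin([-1, 0, 1]).all():
            raise ValueError("h must be in {-1, 0, +1}")
        if not t["sex"].isin([MALE, FEMALE]).all():
            raise ValueError("sex must be 0/1")
        self.table = t


@dataclass
class GwasCatalog:
    """Trait-associated variants: (trait, variant_id, gwas_p, chrom, pos)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"trait", "variant_id", "gwas_p", "chrom", "pos"}
        if not required.issubset(t.columns):
            raise ValueError(f"catalog missing columns {required - set(t.columns)}")
        if len(t) and not ((t["gwas_p"] > 0) & (t["gwas_p"] <= 1)).all():
            raise ValueError("gwas_p must lie in (0, 1]")
        self.table = t


# ---------------------------------------------------------------------------
# genotype coding helpers
# ---------------------------------------------------------------------------

@dataclass
class VcfReadStats:
    """Counters accumulated while decoding genotypes."""

    n_variants: int = 0
    n_male_het_x: int = 0  # impossible hemizygous het calls set to missing
    n_missing: int = 0


def _dosage_from_alleles(alleles: list[int], on_x: bool, sex: int,
                         x_coding: str, stats: VcfReadStats) -> float:
    """Map a genotype call (list of allele indices, -1 = missing) to a dosage."""
    alleles = [a for a in alleles if a is not None]
    if not alleles or any(a < 0 for a in alleles):
        stats.n_missing += 1
        return np.nan
    if any(a > 1 for a in alleles):
        raise ValueError("only biallelic variants are supported")
    if not on_x or sex == FEMALE:
        if len(alleles) == 1:  # haploid call outside male X: treat as diploid hom
            return float(2 * alleles[0])
        return float(sum(alleles))
    # male on X: haploid call, or homozygous diploid call; het is impossible
    if len(alleles) == 2 and alleles[0] != alleles[1]:
        stats.n_male_het_x += 1
        stats.n_missing += 1
        return np.nan
    allele = alleles[0]
    return float(2 * allele) if x_coding == FULL_DOSAGE else float(allele)


def read_vcf(path: str, sample_sex_map: Mapping[str, int],
             x_coding: str = FULL_DOSAGE) -> tuple[GenotypeMatrix, VcfReadStats]:
    """Read a VCF (GT field only) into a GenotypeMatrix.

    Every sample must appear in ``sample_sex_map``.  On chrX, male calls with
    one allele or homozygous diploid calls are coded per ``x_coding``;
    heterozygous male chrX calls are impossible under hemizygosity and are
    set to missing, counted in the returned stats.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    unknown = [s for s in sample_ids if s not in sample_sex_map]
    if unknown:
        raise ValueError(f"samples missing from sex map: {unknown[:5]}")
    sex = np.array([sample_sex_map[s] for s in sample_ids], dtype=np.int8)
    samples = SampleInfo(np.array(sample_ids, dtype=object), sex)

    stats = VcfReadStats()
    ids, chroms, poss, rows = [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"line {i + 1} ({rec.CHROM}:{rec.POS}): only biallelic records supported")
        on_x = is_x(rec.CHROM)
        row = np.empty(samples.n)
        for j, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1]]  # last element is the phased flag
            try:
                row[j] = _dosage_from_alleles(alleles, on_x, int(sex[j]), x_coding, stats)
            except ValueError as exc:
                raise ValueError(f"line {i + 1} sample {sample_ids[j]}: {exc}") from exc
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        rows.append(row)
        stats.n_variants += 1
    dosage = np.vstack(rows) if rows else np.empty((0, samples.n))
    gm = GenotypeMatrix(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                        np.array(poss, dtype=np.int64), dosage, samples, x_coding)
    if stats.n_male_het_x:
        logger.warning("set %d heterozygous male chrX calls to missing", stats.n_male_het_x)
    return gm, stats


def write_vcf(path: str, genotypes: GenotypeMatrix) -> None:
    """Write a minimal VCF 4.2 (GT only) for a biallelic GenotypeMatrix."""
    g = genotypes
    sexes = g.samples.sex
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.samples.sample_ids)) + "\n")
        for v in range(g.n_variants):
            on_x = is_x(str(g.chrom[v]))
            gts = []
            for j, d in enumerate(g.dosage[v]):
                if np.isnan(d):
                    gts.append("./." if not (on_x and sexes[j] == MALE) else ".")
                elif on_x and sexes[j] == MALE:
                    allele = int(d) // 2 if g.x_coding == FULL_DOSAGE else int(d)
                    gts.append(str(allele))
                else:
                    d = int(d)
                    gts.append(["0/0", "0/1", "1/1"][d])
            fh.write(f"{g.chrom[v]}\t{g.pos[v]}\t{g.variant_ids[v]}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def sex_aware_maf(dosage_row: np.ndarray, sex: np.ndarray, on_x: bool,
                  x_coding: str = FULL_DOSAGE) -> float:
    """Minor allele frequency with correct X allele counting.

    Each male contributes one allele on chrX (regardless of the dosage
    coding), each female two; autosomes count two alleles for everyone.
    Missing calls are excluded.  Raises on an all-missing row.
    """
    d = np.asarray(dosage_row, dtype=float)
    sex = np.asarray(sex)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all genotypes missing: MAF undefined")
    d, s = d[ok], sex[ok]
    if on_x:
        male = s == MALE
        male_alt = d[male] / (2.0 if x_coding == FULL_DOSAGE else 1.0)
        alt = male_alt.sum() + d[~male].sum()
        total = male.sum() + 2 * (~male).sum()
    else:
        alt = d.sum()
        total = 2 * len(d)
    f = alt / total
    return float(min(f, 1.0 - f))


# ---------------------------------------------------------------------------
# tabular readers/writers
# ---------------------------------------------------------------------------

def write_samples(path: str, samples: SampleInfo) -> None:
    pd.DataFrame({"sample_id": samples.sample_ids, "sex": samples.sex}).to_csv(
        path, sep="\t", index=False)


def read_samples(path: str) -> SampleInfo:
    t = pd.read_csv(path, sep="\t")
    return SampleInfo(t["sample_id"].to_numpy(dtype=object), t["sex"].to_numpy())


def write_expression(path: str, expr: ExpressionMatrix) -> None:
    df = pd.DataFrame(expr.values, index=pd.Index(expr.gene_ids, name="gene_id"),
                      columns=expr.samples.sample_ids)
    if expr.kind == COUNTS:
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(path: str, samples: SampleInfo, kind: str = RESIDUALS) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(map(str, samples.sample_ids)):
        df = df[[str(s) for s in samples.sample_ids]]
    return ExpressionMatrix(df.index.to_numpy(dtype=object), df.to_numpy(float), samples, kind)


def write_annotation(path: str, ann: GeneAnnotation) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t"))


def write_peaks(bed_path: str, counts_path: str, peaks: PeakCountMatrix) -> None:
    peaks.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        bed_path, sep="\t", index=False, header=False)
    pd.DataFrame(peaks.counts, index=pd.Index(peaks.peaks["peak_id"], name="peak_id"),
                 columns=peaks.samples.sample_ids).to_csv(counts_path, sep="\t")


def read_peaks(bed_path: str, counts_path: str, samples: SampleInfo) -> PeakCountMatrix:
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "peak_id"])
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = counts.loc[bed["peak_id"]]
    return PeakCountMatrix(bed[["peak_id", "chrom", "start", "end"]],
                           counts.to_numpy().astype(np.int64), samples)


def write_ase(path: str, ase: AseTable) -> None:
    ase.table.to_csv(path, sep="\t", index=False)


def read_ase(path: str) -> AseTable:
    return AseTable(pd.read_csv(path, sep="\t"))


def write_gwas_catalog(path: str, cat: GwasCatalog) -> None:
    cat.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gwas_catalog(path: str) -> GwasCatalog:
    t = pd.read_csv(path, sep="\t")
    if t.empty:
        t = pd.DataFrame(columns=["trait", "variant_id", "gwas_p", "chrom", "pos"])
    return GwasCatalog(t)
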