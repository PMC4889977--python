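"""Synthetic cohort generator with known ground truth.

Emulates a large whole-blood cohort (default 648 females / 274 males) so
every downstream stage — differential expression/variance, cis-eQTL and
genotype-by-sex interaction mapping, cis-PVE, allele-specific expression,
differential chromatin accessibility, and GWAS sex-bias testing — can be
exercised and validated against simulated truth without any external data.

The generative model mirrors the analysis models:

* genotypes are Hardy-Weinberg draws at allele frequencies uniform on a MAF
  range, with male X hemizygosity (Bernoulli draws coded per ``x_coding``);
  no linkage disequilibrium unless LD proxy blocks are requested;
* expression residuals follow y = mu + b1*g + b2*s + b3*g*s + eps with
  eps ~ N(0, sigma_sex^2); a count version passes the linear predictor
  through exp() into a negative binomial;
* allelic counts are binomial reads with a logistic mean in the phased
  regulatory contrast, its sex interaction, and an individual random effect;
* ATAC peaks are negative-binomial counts with per-sample library sizes and
  a per-sex mean shift on designated sex-specific peaks; X-inactivation
  escape genes get female-open promoter peaks and a female expression shift;
* the GWAS catalog tags simulated causal eQTL variants, optionally adding
  LD proxies by copy-with-mutation.

All draws come from a single ``numpy`` Generator seeded from the config, so
a fixed seed reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .dataio import (FEMALE, MALE, FULL_DOSAGE, AseTable, ExpressionMatrix,
                     GeneAnnotation, GenotypeMatrix, GwasCatalog,
                     PeakCountMatrix, SampleInfo)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the emulated cohort where stated (922 samples split
    648 F / 274 M; ATAC arm of 10 + 10) and otherwise hold realistic
    whole-blood regulatory-genetics magnitudes: cis effects of a few tenths
    of a residual SD, a minority of genes with sex-interacting effects
    (enriched on X), eQTL depletion on X, and ~20% of X genes escaping
    inactivation with female-shifted expression and accessibility.
    """

    n_male: int = 274
    n_female: int = 648
    n_genes_auto: int = 120
    n_genes_x: int = 40
    variants_per_gene: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    x_coding: str = FULL_DOSAGE

    # effect mixtures: (proportion of genes with a nonzero effect, effect sd)
    beta1_mix: tuple[float, float] = (0.5, 0.4)     # genotype (cis-eQTL)
    beta2_mix: tuple[float, float] = (0.3, 0.3)     # sex
    beta3_mix: tuple[float, float] = (0.10, 0.30)   # genotype-by-sex
    x_eqtl_rate_factor: float = 0.5        # eQTL rate on X relative to autosomes
    x_interaction_factor: float = 3.0      # interaction rate on X relative to autosomes
    noise_sd: float = 1.0

    dv_fraction: float = 0.08              # genes with sex-specific variance
    sex_variance_ratio: float = 2.0        # sigma_f/sigma_m (or inverse) for DV genes

    escape_fraction: float = 0.2           # X genes escaping inactivation
    escape_expr_shift: float = 0.5         # female mean expression increase

    # count-model parameters
    count_log_mean: float = 4.0
    nb_dispersion: float = 0.15

    # ASE arm
    ase_depth: float = 50.0                # Poisson read-depth mean
    ase_n_het_per_sex: int = 30
    ase_tau: float = 0.3                   # individual random-intercept sd

    # ATAC arm
    atac_n_per_sex: int = 10
    n_peaks: int = 400
    peak_sex_fraction: float = 0.05
    peak_l2fc: float = 1.5
    peak_mean_log: float = 4.5
    peak_nb_dispersion: float = 0.05
    libsize_sd: float = 0.25               # lognormal sd of sample library factors

    # GWAS arm
    gwas_n_traits: int = 2
    gwas_variants_per_trait: int = 35
    ld_proxies_per_variant: int = 0
    ld_r2: float = 0.8

    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("beta1_mix", "beta2_mix", "beta3_mix"):
            prop, sd = getattr(self, name)
            if not 0 <= prop <= 1 or sd <= 0:
                raise ValueError(f"{name}: proportion in [0,1], sd > 0 required")
        if self.ase_depth <= 0:
            raise ValueError("ase_depth must be positive")
        if not 0 <= self.escape_fraction <= 1:
            raise ValueError("escape_fraction must lie in [0,1]")


@dataclass
class CohortTruth:
    """Ground truth aligned 1:1 with the emitted genes, peaks and variants."""

    genes: pd.DataFrame    # gene_id, chrom, causal_variant, beta1..3, sigma_m/f, escape
    ase: pd.DataFrame      # gene_id, gamma, delta, tau
    peaks: pd.DataFrame    # peak_id, l2fc_fm, sex_specific, linked_gene
    gwas: pd.DataFrame     # trait, variant_id, bias ("female"/"male"/"none")


@dataclass
class Cohort:
    config: SimConfig
    samples: SampleInfo
    genotypes: GenotypeMatrix
    annotation: GeneAnnotation
    expression: ExpressionMatrix          # residual-scale values
    counts: ExpressionMatrix              # NB count version
    ase: AseTable
    atac_samples: SampleInfo
    peaks: PeakCountMatrix
    catalog: GwasCatalog
    truth: CohortTruth


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def make_samples(cfg: SimConfig) -> SampleInfo:
    ids = np.array([f"M{i:04d}" for i in range(cfg.n_male)]
                   + [f"F{i:04d}" for i in range(cfg.n_female)], dtype=object)
    sex = np.array([MALE] * cfg.n_male + [FEMALE] * cfg.n_female, dtype=np.int8)
    return SampleInfo(ids, sex)


def make_annotation(cfg: SimConfig) -> GeneAnnotation:
    """Deterministic gene layout: genes spaced 200 kb apart, 10 kb bodies."""
    rows = []
    spacing, body = 200_000, 10_000
    for i in range(cfg.n_genes_auto):
        tss = 1_000_000 + i * spacing
        rows.append(("gA%04d" % i, "chr1", tss, tss + body, "+" if i % 2 == 0 else "-"))
    for i in range(cfg.n_genes_x):
        tss = 1_000_000 + i * spacing
        rows.append(("gX%04d" % i, "chrX", tss, tss + body, "+" if i % 2 == 0 else "-"))
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "tes", "strand"]))


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator,
                       annotation: GeneAnnotation) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes for ``variants_per_gene`` cis variants per gene.

    Variants for a gene sit within 50 kb of its TSS.  Allele frequencies are
    uniform on ``maf_range``.  Females (and all autosomal samples) draw
    Binomial(2, f); males on X draw Bernoulli(f) scaled per ``x_coding``.
    """
    samples = make_samples(cfg)
    male = samples.sex == MALE
    ids, chroms, poss, rows = [], [], [], []
    lo, hi = cfg.maf_range
    for _, g in annotation.table.iterrows():
        on_x = bool(dataio.is_x(g["chrom"]))
        for v in range(cfg.variants_per_gene):
            f = rng.uniform(lo, hi)
            d = np.empty(samples.n)
            if on_x:
                d[male] = rng.binomial(1, f, male.sum()).astype(float)
                if cfg.x_coding == FULL_DOSAGE:
                    d[male] *= 2
                d[~male] = rng.binomial(2, f, (~male).sum()).astype(float)
            else:
                d = rng.binomial(2, f, samples.n).astype(float)
            ids.append(f"{g['gene_id']}_v{v}")
            chroms.append(g["chrom"])
            poss.append(int(g["tss"]) - 50_000 + v * 20_000 + 1)
            rows.append(d)
    return GenotypeMatrix(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                          np.array(poss, dtype=np.int64), np.vstack(rows),
                          samples, cfg.x_coding)


def _draw_gene_effects(cfg: SimConfig, rng: np.random.Generator,
                       annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-gene truth: effect sizes, sex-specific noise SDs, escape flags."""
    t = annotation.table
    on_x = dataio.is_x(t["chrom"].to_numpy())
    n = len(t)

    def mixture(base_prop: float, sd: float, x_factor: float) -> np.ndarray:
        prop = np.where(on_x, np.minimum(1.0, base_prop * x_factor), base_prop)
        nonzero = rng.random(n) < prop
        return np.where(nonzero, rng.normal(0.0, sd, n), 0.0)

    beta1 = mixture(*cfg.beta1_mix, cfg.x_eqtl_rate_factor)
    beta2 = mixture(*cfg.beta2_mix, 1.0)
    beta3 = mixture(*cfg.beta3_mix, cfg.x_interaction_factor)

    sigma_m = np.full(n, cfg.noise_sd)
    sigma_f = np.full(n, cfg.noise_sd)
    dv = rng.random(n) < cfg.dv_fraction
    f_bigger = rng.random(n) < 0.5
    sigma_f[dv & f_bigger] *= cfg.sex_variance_ratio
    sigma_m[dv & ~f_bigger] *= cfg.sex_variance_ratio

    escape = on_x & (rng.random(n) < cfg.escape_fraction)
    beta2 = np.where(escape, beta2 + cfg.escape_expr_shift, beta2)

    # dedicated trait genes: the GWAS arm needs variants whose regulatory
    # effects are female-biased (beta1 and beta3 both positive) or sex-neutral
    # eQTLs; the last autosomal genes are reserved for these so catalogs of
    # the configured size always have real structure to tag
    trait_gene = np.array([""] * n, dtype=object)
    need = cfg.gwas_variants_per_trait
    auto_idx = np.flatnonzero(~on_x)
    if cfg.gwas_n_traits > 0 and len(auto_idx) >= 2 * need:
        biased_idx = auto_idx[-2 * need:-need]
        null_idx = auto_idx[-need:]
        beta1[biased_idx] = rng.uniform(0.2, 0.4, need)
        beta3[biased_idx] = rng.uniform(0.15, 0.3, need)
        beta1[null_idx] = rng.uniform(0.2, 0.4, need) * rng.choice([-1, 1], need)
        beta3[null_idx] = 0.0
        trait_gene[biased_idx] = "biased"
        trait_gene[null_idx] = "null"

    return pd.DataFrame({
        "gene_id": t["gene_id"], "chrom": t["chrom"],
        "causal_variant": t["gene_id"] + "_v0",
        "beta1": beta1, "beta2": beta2, "beta3": beta3,
        "sigma_m": sigma_m, "sigma_f": sigma_f,
        "dv": dv, "escape": escape, "trait_gene": trait_gene,
    })


def simulate_expression(genotypes: GenotypeMatrix, gene_truth: pd.DataFrame,
                        cfg: SimConfig, rng: np.random.Generator
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Residual-scale and count-scale expression from the generative model."""
    samples = genotypes.samples
    s = samples.sex.astype(float)
    variant_index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    n_genes = len(gene_truth)
    resid = np.empty((n_genes, samples.n))
    for i, row in enumerate(gene_truth.itertuples(index=False)):
        g = genotypes.dosage[variant_index[row.causal_variant]]
        sd = np.where(s == FEMALE, row.sigma_f, row.sigma_m)
        eps = rng.normal(0.0, 1.0, samples.n) * sd
        resid[i] = row.beta1 * g + row.beta2 * s + row.beta3 * g * s + eps
    expr = ExpressionMatrix(gene_truth["gene_id"].to_numpy(dtype=object),
                            resid, samples, dataio.RESIDUALS)
    # count version: same linear predictor on a log scale around count_log_mean
    mu = np.exp(cfg.count_log_mean + 0.25 * resid)
    alpha = cfg.nb_dispersion
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param).astype(float)
    counts_m = ExpressionMatrix(expr.gene_ids.copy(), counts, samples, dataio.COUNTS)
    return expr, counts_m


def simulate_ase(cfg: SimConfig, rng: np.random.Generator,
                 gene_truth: pd.DataFrame) -> tuple[AseTable, pd.DataFrame]:
    """Allelic read counts for each gene's regulatory variant.

    Per heterozygous individual the alt-read fraction is
    logistic(gamma*h + delta*h*s + u_i) with u_i ~ N(0, tau^2); gamma and
    delta scale with the gene's true cis and interaction effects so ASE
    truth is consistent with the eQTL truth.
    """
    rows = []
    truth_rows = []
    for row in gene_truth.itertuples(index=False):
        gamma = 0.5 * row.beta1
        delta = 0.5 * row.beta3
        for sex in (MALE, FEMALE):
            for j in range(cfg.ase_n_het_per_sex):
                ind = f"{row.gene_id}_{'MF'[sex]}{j:03d}"
                h = -1 if rng.random() < 0.5 else 1
                u = rng.normal(0.0, cfg.ase_tau)
                eta = gamma * h + delta * h * sex + u
                p = 1.0 / (1.0 + np.exp(-eta))
                total = max(int(rng.poisson(cfg.ase_depth)), 1)
                alt = int(rng.binomial(total, p))
                rows.append((ind, row.gene_id, f"{row.gene_id}_site0",
                             total - alt, alt, h, sex))
        truth_rows.append((row.gene_id, gamma, delta, cfg.ase_tau))
    table = pd.DataFrame(rows, columns=["individual", "gene_id", "site",
                                        "ref_count", "alt_count", "h", "sex"])
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "gamma", "delta", "tau"])
    return AseTable(table), truth


def make_atac_samples(cfg: SimConfig) -> SampleInfo:
    ids = np.array([f"atacM{i:02d}" for i in range(cfg.atac_n_per_sex)]
                   + [f"atacF{i:02d}" for i in range(cfg.atac_n_per_sex)], dtype=object)
    sex = np.array([MALE] * cfg.atac_n_per_sex + [FEMALE] * cfg.atac_n_per_sex,
                   dtype=np.int8)
    return SampleInfo(ids, sex)


def simulate_peaks(cfg: SimConfig, rng: np.random.Generator,
                   annotation: GeneAnnotation, gene_truth: pd.DataFrame
                   ) -> tuple[SampleInfo, PeakCountMatrix, pd.DataFrame]:
    """NB peak counts with per-sex shifts on sex-specific peaks.

    The first peaks sit 10-30 kb upstream (strand-oriented) of genes so the
    peak-gene linking and expression integration stages have real structure:
    escape genes get a female-open promoter peak, and a fraction of other
    sex-specific peaks land upstream of differentially expressed genes with
    opposing direction (elevated expression with depressed accessibility).
    Remaining peaks are background on chr2.
    """
    atac = make_atac_samples(cfg)
    sexv = atac.sex.astype(float)
    ann = annotation.table.set_index("gene_id")
    truth = gene_truth.set_index("gene_id")

    peak_rows, l2fc_list, linked = [], [], []
    k = 0
    for gene_id, g in ann.iterrows():
        offset = int(rng.integers(10_000, 30_000))
        if g["strand"] == "+":
            start = int(g["tss"]) - offset
        else:
            start = int(g["tes"]) + offset - 500
        start = max(start, 0)
        tr = truth.loc[gene_id]
        if tr["escape"]:
            l2fc = cfg.peak_l2fc          # female-open escape peak
        elif tr["beta2"] != 0 and rng.random() < 0.5:
            # opposing direction: elevated expression, depressed accessibility
            l2fc = -np.sign(tr["beta2"]) * cfg.peak_l2fc
        else:
            l2fc = 0.0
        peak_rows.append((f"pk{k:05d}", str(g["chrom"]), start, start + 500))
        l2fc_list.append(l2fc)
        linked.append(gene_id)
        k += 1
    n_bg = max(cfg.n_peaks - k, 0)
    for i in range(n_bg):
        start = 1_000_000 + i * 5_000
        l2fc = cfg.peak_l2fc * rng.choice([-1, 1]) \
            if rng.random() < cfg.peak_sex_fraction else 0.0
        peak_rows.append((f"pk{k:05d}", "chr2", start, start + 500))
        l2fc_list.append(l2fc)
        linked.append("")
        k += 1

    peaks_df = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"])
    l2fc = np.asarray(l2fc_list)
    lib = np.exp(rng.normal(0.0, cfg.libsize_sd, atac.n))
    base = np.exp(rng.normal(cfg.peak_mean_log, 0.5, len(peaks_df)))
    mu = base[:, None] * lib[None, :] * np.power(2.0, 0.5 * l2fc[:, None]
                                                 * np.where(sexv == FEMALE, 1, -1))
    alpha = cfg.peak_nb_dispersion
    n_param = 1.0 / alpha
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    pcm = PeakCountMatrix(peaks_df, counts.astype(np.int64), atac)
    peak_truth = pd.DataFrame({"peak_id": peaks_df["peak_id"], "l2fc_fm": l2fc,
                               "sex_specific": l2fc != 0, "linked_gene": linked})
    return atac, pcm, peak_truth


def simulate_gwas_catalog(cfg: SimConfig, rng: np.random.Generator,
                          gene_truth: pd.DataFrame,
                          genotypes: GenotypeMatrix
                          ) -> tuple[GwasCatalog, pd.DataFrame, GenotypeMatrix]:
    """Trait catalogs tagging simulated causal eQTL variants.

    Trait 0 ("TRAIT_FBIAS") draws its variants from genes with positive
    interaction effects so female cis effects exceed male ones; further
    traits are unbiased nulls.  Optional LD proxies are generated by
    copy-with-mutation at the requested r-squared and appended to the
    genotype matrix (proxies carry no expression effect).
    """
    pos_map = {v: (c, p) for v, c, p in zip(
        genotypes.variant_ids, genotypes.chrom, genotypes.pos)}
    candidates_biased = gene_truth.loc[
        gene_truth["trait_gene"] == "biased", "causal_variant"].tolist()
    if not candidates_biased:
        candidates_biased = gene_truth.loc[
            (gene_truth["beta3"] > 0.1) & (gene_truth["beta1"] > 0.05),
            "causal_variant"].tolist()
    candidates_null = gene_truth.loc[
        gene_truth["trait_gene"] == "null", "causal_variant"].tolist()
    if not candidates_null:
        candidates_null = gene_truth.loc[
            (gene_truth["beta3"] == 0) & (gene_truth["beta1"].abs() > 0.05),
            "causal_variant"].tolist()

    rows, truth_rows = [], []
    new_ids, new_chrom, new_pos, new_rows = [], [], [], []
    for t in range(cfg.gwas_n_traits):
        biased = t == 0
        trait = "TRAIT_FBIAS" if biased else f"TRAIT_NULL{t}"
        pool = candidates_biased if biased else candidates_null
        if not pool:
            continue
        take = [pool[i % len(pool)] for i in range(cfg.gwas_variants_per_trait)]
        # a variant can only appear once per trait
        take = list(dict.fromkeys(take))
        for v in take:
            chrom, pos = pos_map[v]
            p = float(10.0 ** -rng.uniform(8.5, 30))
            rows.append((trait, v, p, chrom, pos))
            truth_rows.append((trait, v, "female" if biased else "none"))
            for j in range(cfg.ld_proxies_per_variant):
                proxy = f"{v}_ld{j}"
                src = genotypes.row(v)
                flip = rng.random(len(src)) < (1 - np.sqrt(cfg.ld_r2)) / 2
                prox = np.where(flip, 2 - src, src)
                new_ids.append(proxy)
                new_chrom.append(chrom)
                new_pos.append(pos + j + 1)
                new_rows.append(prox)
                rows.append((trait, proxy, p * 10, chrom, pos + j + 1))
                truth_rows.append((trait, proxy, "proxy"))
    if new_ids:
        genotypes = GenotypeMatrix(
            np.concatenate([genotypes.variant_ids, np.array(new_ids, dtype=object)]),
            np.concatenate([genotypes.chrom, np.array(new_chrom, dtype=object)]),
            np.concatenate([genotypes.pos, np.array(new_pos, dtype=np.int64)]),
            np.vstack([genotypes.dosage, np.vstack(new_rows)]),
            genotypes.samples, genotypes.x_coding)
    cat = GwasCatalog(pd.DataFrame(
        rows, columns=["trait", "variant_id", "gwas_p", "chrom", "pos"]))
    truth = pd.DataFrame(truth_rows, columns=["trait", "variant_id", "bias"])
    return cat, truth, genotypes


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> Cohort:
    """Generate the full synthetic study: all arms, aligned truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    annotation = make_annotation(cfg)
    genotypes = simulate_genotypes(cfg, rng, annotation)
    gene_truth = _draw_gene_effects(cfg, rng, annotation)
    expression, counts = simulate_expression(genotypes, gene_truth, cfg, rng)
    ase, ase_truth = simulate_ase(cfg, rng, gene_truth)
    atac_samples, peaks, peak_truth = simulate_peaks(cfg, rng, annotation, gene_truth)
    catalog, gwas_truth, genotypes = simulate_gwas_catalog(cfg, rng, gene_truth, genotypes)
    truth = CohortTruth(genes=gene_truth, ase=ase_truth, peaks=peak_truth,
                        gwas=gwas_truth)
    return Cohort(cfg, genotypes.samples, genotypes, annotation, expression,
                  counts, ase, atac_samples, peaks, catalog, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write every arm of the cohort as plain-text files; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out / "samples.tsv",
        "genotypes": out / "genotypes.vcf",
        "annotation": out / "annotation.tsv",
        "expression": out / "expression.tsv",
        "counts": out / "counts.tsv",
        "ase": out / "ase.tsv",
        "atac_samples": out / "atac_samples.tsv",
        "peaks_bed": out / "peaks.bed",
        "peak_counts": out / "peak_counts.tsv",
        "catalog": out / "gwas_catalog.tsv",
        "truth": out / "truth.json",
    }
    dataio.write_samples(paths["samples"], cohort.samples)
    dataio.write_vcf(paths["genotypes"], cohort.genotypes)
    dataio.write_annotation(paths["annotation"], cohort.annotation)
    dataio.write_expression(paths["expression"], cohort.expression)
    dataio.write_expression(paths["counts"], cohort.counts)
    dataio.write_ase(paths["ase"], cohort.ase)
    dataio.write_samples(paths["atac_samples"], cohort.atac_samples)
    dataio.write_peaks(paths["peaks_bed"], paths["peak_counts"], cohort.peaks)
    dataio.write_gwas_catalog(paths["catalog"], cohort.catalog)
    truth_json = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cohort.config).items()},
        "genes": cohort.truth.genes.to_dict(orient="list"),
        "ase": cohort.truth.ase.to_dict(orient="list"),
        "peaks": cohort.truth.peaks.to_dict(orient="list"),
        "gwas": cohort.truth.gwas.to_dict(orient="list"),
    }
    import json
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, default=lambda o: bool(o)
                  if isinstance(o, np.bool_) else o.item())
    return {k: str(v) for k, v in paths.items()}
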