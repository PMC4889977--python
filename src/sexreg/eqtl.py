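"""cis-eQTL and genotype-by-sex interaction mapping.

Associations are fit per gene-variant pair by ordinary least squares:

* additive model:     y = mu + b1*g + b2*s + e          (joint cohort)
                      y = mu + b1*g + e                 (single-sex strata)
* interaction model:  y = mu + b1*g + b2*s + b3*g*s + e

with classical (homoskedastic) standard errors and Wald t p-values, matching
the Matrix-eQTL-style analysis the pipeline emulates.  Sex is coded
male = 0 / female = 1, so b2 and b3 are positive when larger in females.

Multiple testing is hierarchical: per gene, the best nominal p across the
variants actually fitted is Bonferroni-adjusted by the number of fitted
tests; the per-gene adjusted minima are then Benjamini-Hochberg corrected
across genes ("gene-level FDR").

Variants enter the interaction scan only if the columns {1, g, s} have
numerical rank 3 (tolerance 1e-8 relative to the largest singular value),
excluding genotypes collinear with sex, and only if MAF >= maf_min within
each sex separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import dataio, stats
from .dataio import GeneAnnotation, GenotypeMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

ADDITIVE = "additive"
INTERACTION = "interaction"
JOINT, MALE_STRATUM, FEMALE_STRATUM = "joint", "male", "female"

RANK_TOL = 1e-8


@dataclass
class AssociationRecord:
    gene_id: str
    variant_id: str
    model: str
    stratum: str
    beta1: float
    se1: float
    p: float                      # additive: p(b1); interaction: p(b3)
    n: int
    beta2: float | None = None
    se2: float | None = None
    beta3: float | None = None
    se3: float | None = None
    intercept: float = 0.0
    sigma2: float = 0.0           # residual variance


def cis_pairs(annotation: GeneAnnotation, genotypes: GenotypeMatrix,
              window: float = 1e6) -> pd.DataFrame:
    """Gene-variant pairs with variant position in [tss - window, tes + window].

    TSS/TES are genomic-orientation normalized (tss <= tes), so the window
    extends ``window`` bp beyond both gene ends on the same chromosome.
    """
    w = int(window)
    out = []
    vpos = genotypes.pos
    vchrom = genotypes.chrom
    for row in annotation.table.itertuples(index=False):
        on_chrom = vchrom == row.chrom
        hit = on_chrom & (vpos >= row.tss - w) & (vpos <= row.tes + w)
        for vi in np.flatnonzero(hit):
            out.append((row.gene_id, genotypes.variant_ids[vi], vi))
    return pd.DataFrame(out, columns=["gene_id", "variant_id", "variant_index"])


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS coefficients, classical SEs and residual variance (n-p df)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid / dof)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return beta, se, sigma2


def _wald_p(beta: float, se: float, dof: int) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    t = beta / se
    return float(2 * sps.t.sf(abs(t), dof))


def fit_additive(y: np.ndarray, g: np.ndarray, sex: np.ndarray | None,
                 gene_id: str = "", variant_id: str = "",
                 stratum: str = JOINT) -> AssociationRecord:
    """Additive OLS fit; ``sex=None`` (or a single-sex stratum) drops the
    sex covariate.  Missing genotypes are dropped case-wise."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[ok], g[ok]
    use_sex = sex is not None and stratum == JOINT
    if use_sex:
        s = np.asarray(sex, dtype=float)[ok]
    if np.var(g) == 0:
        raise ValueError("zero genotype variance after filtering")
    if use_sex:
        X = np.column_stack([np.ones_like(y), g, s])
    else:
        X = np.column_stack([np.ones_like(y), g])
    beta, se, sigma2 = _ols(X, y)
    dof = len(y) - X.shape[1]
    rec = AssociationRecord(
        gene_id=gene_id, variant_id=variant_id, model=ADDITIVE, stratum=stratum,
        beta1=float(beta[1]), se1=float(se[1]), p=_wald_p(beta[1], se[1], dof),
        n=len(y), intercept=float(beta[0]), sigma2=sigma2)
    if use_sex:
        rec.beta2, rec.se2 = float(beta[2]), float(se[2])
    return rec


def fit_interaction(y: np.ndarray, g: np.ndarray, sex: np.ndarray,
                    gene_id: str = "", variant_id: str = "") -> AssociationRecord:
    """Interaction OLS fit on [1, g, s, g*s]; p is the Wald p of b3."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    y, g, s = y[ok], g[ok], s[ok]
    keep, reason = collinearity_filter(g, s)
    if not keep:
        raise ValueError(f"variant excluded: {reason}")
    X = np.column_stack([np.ones_like(y), g, s, g * s])
    beta, se, sigma2 = _ols(X, y)
    dof = len(y) - 4
    return AssociationRecord(
        gene_id=gene_id, variant_id=variant_id, model=INTERACTION, stratum=JOINT,
        beta1=float(beta[1]), se1=float(se[1]),
        beta2=float(beta[2]), se2=float(se[2]),
        beta3=float(beta[3]), se3=float(se[3]),
        p=_wald_p(beta[3], se[3], dof), n=len(y),
        intercept=float(beta[0]), sigma2=sigma2)


def collinearity_filter(g: np.ndarray, sex: np.ndarray,
                        tol: float = RANK_TOL) -> tuple[bool, str]:
    """Keep a variant iff the column set {1, g, s} has numerical rank 3.

    Rank is computed from singular values with threshold ``tol`` times the
    largest singular value; genotype constant or identical to sex drops the
    rank to 2 and excludes the variant from interaction fitting.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = ~np.isnan(g)
    M = np.column_stack([np.ones(ok.sum()), g[ok], s[ok]])
    sv = np.linalg.svd(M, compute_uv=False)
    rank = int((sv > tol * sv[0]).sum())
    if rank < 3:
        if np.var(g[ok]) == 0:
            return False, "constant genotype"
        return False, "genotype collinear with sex (rank < 3)"
    return True, ""


@dataclass
class GeneSummary:
    gene_id: str
    n_tests: int
    best_variant: str
    best_p: float
    bonf_p: float
    q: float = np.nan


def gene_level_fdr(records: list[AssociationRecord] | pd.DataFrame) -> pd.DataFrame:
    """Hierarchical FDR: per-gene Bonferroni on the best p, BH across genes.

    Only fitted tests count toward each gene's Bonferroni denominator.
    Ties on p break lexicographically on variant_id for determinism.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([{"gene_id": r.gene_id, "variant_id": r.variant_id,
                            "p": r.p} for r in records])
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "n_tests", "best_variant",
                                     "best_p", "bonf_p", "q"])
    df = df.sort_values(["gene_id", "p", "variant_id"], kind="mergesort")
    best = df.groupby("gene_id", sort=True).first()
    n_tests = df.groupby("gene_id", sort=True).size()
    out = pd.DataFrame({
        "gene_id": best.index,
        "n_tests": n_tests.to_numpy(),
        "best_variant": best["variant_id"].to_numpy(),
        "best_p": best["p"].to_numpy(),
    })
    out["bonf_p"] = np.minimum(1.0, out["n_tests"] * np.maximum(out["best_p"], 1e-300))
    out["q"] = stats.bh_fdr(out["bonf_p"].to_numpy())
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# scan drivers
# ---------------------------------------------------------------------------

def map_cis(expression: ExpressionMatrix, genotypes: GenotypeMatrix,
            annotation: GeneAnnotation, model: str = ADDITIVE,
            stratum: str = JOINT, window: float = 1e6,
            maf_min: float = 0.05, maf_max: float = 0.5,
            restrict_variants: set[str] | None = None
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan all cis pairs; returns (all-pairs table, gene-level summary).

    ``maf_min``/``maf_max`` bound the sex-aware MAF: the joint additive scan
    filters on cohort MAF, the interaction scan on MAF within each sex
    separately; single-sex strata filter within the stratum.  An optional
    ``restrict_variants`` set implements the restricted interaction scan
    over previously detected cis-eQTL variants.
    """
    samples = genotypes.samples
    sex = samples.sex
    if stratum == MALE_STRATUM:
        mask = sex == dataio.MALE
    elif stratum == FEMALE_STRATUM:
        mask = sex == dataio.FEMALE
    else:
        mask = np.ones(samples.n, dtype=bool)
    pairs = cis_pairs(annotation, genotypes, window)
    gene_index = {g: i for i, g in enumerate(expression.gene_ids)}
    records: list[dict] = []
    n_excluded = {"maf": 0, "collinear": 0, "constant": 0}
    for row in pairs.itertuples(index=False):
        if row.gene_id not in gene_index:
            continue
        if restrict_variants is not None and row.variant_id not in restrict_variants:
            continue
        vi = row.variant_index
        on_x = bool(dataio.is_x(str(genotypes.chrom[vi])))
        d_full = genotypes.dosage[vi]
        d = d_full[mask]
        s = sex[mask]
        try:
            if model == INTERACTION:
                mafs = [dataio.sex_aware_maf(d[s == grp], s[s == grp], on_x,
                                             genotypes.x_coding)
                        for grp in (dataio.MALE, dataio.FEMALE)]
                passing = all(maf_min <= m <= maf_max for m in mafs)
            else:
                m = dataio.sex_aware_maf(d, s, on_x, genotypes.x_coding)
                passing = maf_min <= m <= maf_max
        except ValueError:
            passing = False
        if not passing:
            n_excluded["maf"] += 1
            continue
        y = expression.values[gene_index[row.gene_id]][mask]
        try:
            if model == INTERACTION:
                rec = fit_interaction(y, d, s, row.gene_id, row.variant_id)
            else:
                rec = fit_additive(y, d, s if stratum == JOINT else None,
                                   row.gene_id, row.variant_id, stratum)
        except (ValueError, np.linalg.LinAlgError) as exc:
            key = "constant" if "variance" in str(exc) else "collinear"
            n_excluded[key] += 1
            continue
        records.append(vars(rec))
    logger.info("cis scan (%s, %s): %d fits, excluded %s",
                model, stratum, len(records), n_excluded)
    all_pairs = pd.DataFrame(records)
    summary = gene_level_fdr(all_pairs if len(all_pairs) else [])
    return all_pairs, summary


# ---------------------------------------------------------------------------
# X-vs-autosome comparative statistics
# ---------------------------------------------------------------------------

def xa_eqtl_depletion(summary: pd.DataFrame, annotation: GeneAnnotation,
                      fdr_grid: tuple[float, ...] = (0.01, 0.05, 0.1)
                      ) -> pd.DataFrame:
    """Chi-squared test of eQTL discovery rate, X vs autosomes, per FDR
    threshold, with Bonferroni adjustment across the grid."""
    chrom = annotation.table.set_index("gene_id")["chrom"]
    on_x = dataio.is_x(chrom.loc[summary["gene_id"]].to_numpy())
    if on_x.all() or (~on_x).all():
        raise ValueError("need genes on both X and autosomes")
    rows = []
    for thr in fdr_grid:
        sig = summary["q"].to_numpy() < thr
        table = np.array([[int((sig & on_x).sum()), int((~sig & on_x).sum())],
                          [int((sig & ~on_x).sum()), int((~sig & ~on_x).sum())]])
        if sig.sum() == 0:
            logger.info("no discoveries at FDR %.3g; threshold skipped", thr)
            continue
        res = stats.chisq_2xk(table)
        rows.append({"fdr": thr,
                     "prop_x": table[0, 0] / max(on_x.sum(), 1),
                     "prop_auto": table[1, 0] / max((~on_x).sum(), 1),
                     "chi2": res.statistic, "p": res.p_value,
                     "p_bonf": min(1.0, res.p_value * len(fdr_grid))})
    return pd.DataFrame(rows)


def effect_size_compare(beta_a: np.ndarray, beta_b: np.ndarray,
                        score: np.ndarray | None = None, n_bins: int = 5,
                        min_per_bin: int = 5) -> pd.DataFrame:
    """Two-sided Wilcoxon on |effect size| between two record sets.

    With a per-record ``score`` for set comparison within quantile bins
    (e.g. selective-constraint scores), results are reported per bin; bins
    with fewer than ``min_per_bin`` records in either set are NA.
    """
    a = np.abs(np.asarray(beta_a, dtype=float))
    b = np.abs(np.asarray(beta_b, dtype=float))
    if score is None:
        res = stats.wilcoxon_rank_sum(a, b, stats.TWO_SIDED)
        fold = float(b.mean() / a.mean()) if a.mean() > 0 else np.nan
        return pd.DataFrame([{"bin": "all", "n_a": a.size, "n_b": b.size,
                              "fold_b_over_a": fold, "p": res.p_value}])
    score = np.asarray(score, dtype=float)
    edges = np.quantile(score, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.inf
    rows = []
    for i in range(n_bins):
        # score aligns with set a (e.g. X records); compare its bin to all of b
        in_bin = (score >= edges[i]) & (score < edges[i + 1])
        aa = a[in_bin]
        if aa.size < min_per_bin or b.size < min_per_bin:
            rows.append({"bin": i, "n_a": int(aa.size), "n_b": b.size,
                         "fold_b_over_a": np.nan, "p": np.nan})
            continue
        res = stats.wilcoxon_rank_sum(aa, b, stats.TWO_SIDED)
        rows.append({"bin": i, "n_a": int(aa.size), "n_b": b.size,
                     "fold_b_over_a": float(b.mean() / aa.mean()), "p": res.p_value})
    return pd.DataFrame(rows)


def qq_enrichment(p_x: np.ndarray, p_auto: np.ndarray, top_k: int,
                  rng: np.random.Generator | None = None) -> stats.TestResult:
    """One-sided Wilcoxon comparing the top-k -log10 p from X against the
    top-k from autosomes (the QQ-plot enrichment read-out)."""
    p_x = np.sort(np.asarray(p_x, dtype=float))
    p_auto = np.sort(np.asarray(p_auto, dtype=float))
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    if len(p_x) < top_k or len(p_auto) < top_k:
        raise ValueError("top_k exceeds available associations")
    lx = -np.log10(np.maximum(p_x[:top_k], 1e-300))
    la = -np.log10(np.maximum(p_auto[:top_k], 1e-300))
    return stats.wilcoxon_rank_sum(lx, la, stats.GREATER)
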