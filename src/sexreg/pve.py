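"""Per-gene, per-sex proportion of expression variance explained (PVE) by
common cis variants — the cis-heritability contrast behind the male
hemizygosity argument.

A local genetic relationship matrix (GRM) is built from column-standardized
cis dosages, K = Z Z'/m, and a single-variance-component model

    y = g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

is fit by REML via one eigendecomposition of K and a bounded 1-D likelihood
maximization over h^2 = sigma_g^2/(sigma_g^2 + sigma_e^2) in [0, 1].  With
trace(K) = n the h^2 that maximizes the restricted likelihood IS the PVE.
A Haseman-Elston regression (cross-products of standardized phenotypes on
GRM entries, clipped to [0, 1]) is available as a moment-based alternative.

On chrX with the full-dosage male coding, one male allele carries the same
regression dosage as a female homozygote, so additive effects generate twice
the genetic variance in males — the mechanism the sex comparison detects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import dataio, stats
from .dataio import FEMALE, MALE, ExpressionMatrix, GeneAnnotation, GenotypeMatrix
from .sexdiff import match_subsample

logger = logging.getLogger(__name__)

REML = "reml"
HE = "he"


def cis_grm(dosages: np.ndarray) -> np.ndarray:
    """GRM from an m x n dosage block: standardize rows, K = Z'Z / m.

    Rows (variants) are centred and scaled to unit population variance
    within the supplied samples, so diag(K) averages exactly 1 and
    trace(K) = n.  Monomorphic rows are dropped; raises if none remain.
    Missing dosages are mean-imputed per variant before standardization.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[None, :]
    mu = np.nanmean(D, axis=1, keepdims=True)
    D = np.where(np.isnan(D), mu, D)
    sd = D.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no polymorphic variants in window")
    Z = (D[keep] - D[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return Z.T @ Z / Z.shape[0]


@dataclass
class PveEstimate:
    gene_id: str
    stratum: str
    pve: float
    sigma_g2: float
    sigma_e2: float
    n: int
    m_variants: int
    estimator: str
    loglik: float = np.nan


def _reml_h2(y: np.ndarray, K: np.ndarray) -> tuple[float, float, float]:
    """REML over h^2 in [0,1] with an intercept; returns (h2, sigma2, loglik)."""
    n = len(y)
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    p = 1

    def neg_restricted_ll(h2: float) -> float:
        d = h2 * lam + (1.0 - h2)
        d = np.maximum(d, 1e-10)
        xdx = float((xt * xt / d).sum())
        beta = float((xt * yt / d).sum()) / xdx
        r = yt - xt * beta
        rss = float((r * r / d).sum())
        sigma2 = rss / (n - p)
        ll = -0.5 * ((n - p) * np.log(sigma2) + np.log(d).sum()
                     + np.log(xdx) + (n - p))
        return -ll

    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, 1.0 - 1e-8),
                          method="bounded", options={"xatol": 1e-8})
    h2 = float(res.x)
    # snap to boundary when flat at zero
    if neg_restricted_ll(0.0) <= res.fun + 1e-10:
        h2, fun = 0.0, neg_restricted_ll(0.0)
    else:
        fun = res.fun
    d = h2 * lam + (1.0 - h2)
    xdx = float((xt * xt / d).sum())
    beta = float((xt * yt / d).sum()) / xdx
    r = yt - xt * beta
    sigma2 = float((r * r / d).sum()) / (n - p)
    return h2, sigma2, -float(fun)


def _he_h2(y: np.ndarray, K: np.ndarray) -> float:
    """Haseman-Elston regression of off-diagonal cross-products on K."""
    z = (y - y.mean())
    sd = z.std()
    if sd == 0:
        return 0.0
    z /= sd
    iu = np.triu_indices_from(K, k=1)
    cp = z[iu[0]] * z[iu[1]]
    k = K[iu]
    vk = np.var(k)
    if vk == 0:
        return 0.0
    slope = np.cov(k, cp, ddof=0)[0, 1] / vk
    return float(np.clip(slope, 0.0, 1.0))


def estimate_pve(y: np.ndarray, grm: np.ndarray, estimator: str = REML,
                 gene_id: str = "", stratum: str = "", m_variants: int = 0
                 ) -> PveEstimate:
    """Estimate the variance fraction attributable to the GRM component."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if grm.shape != (n, n):
        raise ValueError("GRM and phenotype dimensions disagree")
    if estimator == REML:
        h2, sigma2, ll = _reml_h2(y, grm)
        sg2, se2 = h2 * sigma2, (1 - h2) * sigma2
    elif estimator == HE:
        h2 = _he_h2(y, grm)
        vt = float(np.var(y, ddof=1))
        sg2, se2, ll = h2 * vt, (1 - h2) * vt, np.nan
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return PveEstimate(gene_id, stratum, float(h2), sg2, se2, n,
                       m_variants, estimator, ll)


def pve_scan(expression: ExpressionMatrix, genotypes: GenotypeMatrix,
             annotation: GeneAnnotation, window: float = 1e6,
             maf_min: float = 0.05, estimator: str = REML,
             match_seed: int = 0, genes: list[str] | None = None
             ) -> pd.DataFrame:
    """Per-gene, per-sex PVE with matched sample sizes.

    The majority sex is subsampled (seeded) to the minority-sex count so the
    two strata estimate PVE from equal information.  Variants enter the GRM
    if their sex-aware MAF within the stratum is >= ``maf_min``.  Genes with
    no passing cis variant are skipped with a log entry.
    """
    sex = genotypes.samples.sex
    idx = match_subsample(sex, match_seed)
    rows = []
    w = int(window)
    gene_set = set(genes) if genes is not None else None
    gene_index = {g: i for i, g in enumerate(expression.gene_ids)}
    for g in annotation.table.itertuples(index=False):
        if gene_set is not None and g.gene_id not in gene_set:
            continue
        if g.gene_id not in gene_index:
            continue
        on_chrom = genotypes.chrom == g.chrom
        hit = on_chrom & (genotypes.pos >= g.tss - w) & (genotypes.pos <= g.tes + w)
        if not hit.any():
            logger.info("gene %s: no cis variants; skipped", g.gene_id)
            continue
        on_x = bool(dataio.is_x(g.chrom))
        for stratum, code in (("male", MALE), ("female", FEMALE)):
            take = idx[sex[idx] == code]
            D = genotypes.dosage[np.ix_(hit, take)]
            s_lab = sex[take]
            mafs = []
            for r in D:
                try:
                    mafs.append(dataio.sex_aware_maf(r, s_lab, on_x,
                                                     genotypes.x_coding))
                except ValueError:
                    mafs.append(0.0)
            D = D[np.asarray(mafs) >= maf_min]
            if D.shape[0] == 0 or (D.std(axis=1) > 0).sum() == 0:
                logger.info("gene %s (%s): no variants pass MAF; skipped",
                            g.gene_id, stratum)
                continue
            K = cis_grm(D)
            y = expression.values[gene_index[g.gene_id]][take]
            est = estimate_pve(y, K, estimator, g.gene_id, stratum, D.shape[0])
            rows.append(vars(est))
    return pd.DataFrame(rows)


def compare_pve(pve_m: np.ndarray, pve_f: np.ndarray) -> dict:
    """Wilcoxon rank-sum comparison of male vs female per-gene PVE.

    Reports both means and the male/female fold of means.
    """
    pm = np.asarray(pve_m, dtype=float)
    pf = np.asarray(pve_f, dtype=float)
    if pm.size < 10 or pf.size < 10:
        raise ValueError("need at least 10 genes per stratum to compare PVE")
    res = stats.wilcoxon_rank_sum(pm, pf, stats.TWO_SIDED)
    mean_m, mean_f = float(pm.mean()), float(pf.mean())
    fold = mean_m / mean_f if mean_f > 0 else np.inf
    return {"mean_male": mean_m, "mean_female": mean_f,
            "fold_m_over_f": float(fold), "p": res.p_value,
            "statistic": res.statistic}
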