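"""Negative-binomial differential chromatin accessibility between sexes,
and its integration with sex-specific expression and interaction eQTLs.

Counts are normalized by median-of-ratios size factors, per-peak dispersion
is estimated by method-of-moments within groups, and the two-group test is
the classic exact negative-binomial test: condition on the total count of a
peak and sum the joint probabilities of all splits no more likely than the
observed one.  All pmf arithmetic is in log space.

Downstream, peaks are linked to genes whose (strand-oriented) upstream
window they intersect, and enrichment of sex-specific accessibility in
sex-specific expression / interaction-eQTL genes is tested with Fisher's
exact test, including the directional variant (elevated expression in one
sex pairing with depressed accessibility in the same sex).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from . import dataio, stats
from .dataio import FEMALE, MALE, GeneAnnotation, PeakCountMatrix

logger = logging.getLogger(__name__)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (peak x sample count matrix).

    The reference is the per-peak geometric mean over samples, computed from
    peaks where every sample has a positive count; each sample's factor is
    the median ratio of its counts to the reference.  If no peak is
    all-positive, falls back to total-count factors scaled to geometric
    mean 1, with a warning.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim == 1:
        c = c[None, :]
    if c.shape[1] == 1:
        return np.array([1.0])
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        logger.warning("no peak with all-positive counts; "
                       "using library-size factors")
        tot = np.maximum(c.sum(axis=0), 1.0)  # zero-total sample guard
        return tot / np.exp(np.mean(np.log(tot)))
    logc = np.log(c[allpos])
    ref = logc.mean(axis=1)
    return np.exp(np.median(logc - ref[:, None], axis=0))


def estimate_dispersion(counts: np.ndarray, groups: np.ndarray,
                        sf: np.ndarray, mode: str = "trend") -> np.ndarray:
    """Per-peak NB dispersion alpha by method-of-moments within groups.

    On size-factor-normalized counts, each group contributes
    (var - mean)/mean^2; the raw per-peak estimate is the df-weighted
    average across groups, clipped at zero.  A hyperbolic mean-dispersion
    trend a0/mean + a1 is then fit across peaks and applied per ``mode``:

    * ``"trend"`` (default) — each peak takes its fitted trend value,
      borrowing strength across peaks; with the few samples typical of
      accessibility studies this keeps the exact test's type-I error at
      its nominal level, where the noisy raw estimates run liberal;
    * ``"per_peak"`` — raw method-of-moments estimates;
    * ``"max"`` — max(raw, trend), a deliberately conservative choice.

    When too few peaks have positive raw estimates to fit the trend, raw
    values are returned.  Zero-mean peaks get NaN.
    """
    c = np.asarray(counts, dtype=float)
    one_dim = c.ndim == 1
    if one_dim:
        c = c[None, :]
    groups = np.asarray(groups)
    q = c / np.asarray(sf, dtype=float)[None, :]
    labels = np.unique(groups)
    num = np.zeros(c.shape[0])
    den = 0.0
    means = np.zeros(c.shape[0])
    wsum = 0
    for g in labels:
        m = groups == g
        n_g = int(m.sum())
        if n_g < 2:
            raise ValueError("need >= 2 samples per group")
        mean_g = q[:, m].mean(axis=1)
        var_g = q[:, m].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            num += (n_g - 1) * (var_g - mean_g) / mean_g**2
        den += n_g - 1
        means += n_g * mean_g
        wsum += n_g
    alpha = np.maximum(num / den, 0.0)
    means /= wsum
    alpha[means == 0] = np.nan
    if mode not in ("per_peak", "trend", "max"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    if mode != "per_peak":
        ok = np.isfinite(alpha) & (alpha > 0) & (means > 0)
        if ok.sum() >= 10:
            A = np.column_stack([1.0 / means[ok], np.ones(ok.sum())])
            coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
            trend = np.maximum(coef[0] / np.maximum(means, 1e-12) + coef[1], 0.0)
            fitted = np.fmax(alpha, trend) if mode == "max" else trend
            fitted = np.where(np.isfinite(alpha), fitted, alpha)
            alpha = fitted
        else:
            logger.info("too few positive dispersions for a trend fit; "
                        "using per-peak estimates")
    return alpha


def _nb_logpmf_sum(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of a count with the given mean/variance (NB, or Poisson when
    var <= mean within rounding)."""
    if var <= mean * (1 + 1e-12):
        return sps.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return sps.nbinom.logpmf(k, r, p)


def nb_test(peak_counts: np.ndarray, sex: np.ndarray, sf: np.ndarray,
            alpha: float) -> dict:
    """Exact two-group NB test for one peak, conditioning on the total.

    The group sums are modelled as NB with mean s_g * mu_hat (mu_hat the
    pooled normalized mean) and variance sum_j (sf_j mu + alpha sf_j^2 mu^2);
    the p-value sums P(a, T - a) over all splits of the total T whose joint
    probability does not exceed the observed one, normalized by the total.
    Computation is in log space throughout.
    """
    k = np.asarray(peak_counts, dtype=float)
    sex = np.asarray(sex)
    sf = np.asarray(sf, dtype=float)
    m_mask, f_mask = sex == MALE, sex == FEMALE
    if m_mask.sum() < 2 or f_mask.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    kM, kF = k[m_mask].sum(), k[f_mask].sum()
    sM, sF = sf[m_mask].sum(), sf[f_mask].sum()
    T = int(kM + kF)
    if not np.isfinite(alpha):
        alpha = 0.0
    qM, qF = kM / sM, kF / sF
    l2fc = float(np.log2(qF / qM)) if qM > 0 and qF > 0 else (
        np.inf if qF > 0 else (-np.inf if qM > 0 else 0.0))
    if T == 0:
        return {"p": 1.0, "l2fc_fm": 0.0, "direction": "none",
                "mean_m": 0.0, "mean_f": 0.0, "alpha": alpha}
    mu = (kM + kF) / (sM + sF)
    meanM, meanF = sM * mu, sF * mu
    varM = meanM + alpha * mu**2 * float((sf[m_mask]**2).sum())
    varF = meanF + alpha * mu**2 * float((sf[f_mask]**2).sum())
    a = np.arange(T + 1)
    la = _nb_logpmf_sum(a, meanM, varM)
    lb = _nb_logpmf_sum(T - a, meanF, varF)
    joint = la + lb
    obs = joint[int(kM)]
    keep = joint <= obs + 1e-10
    p = float(np.exp(logsumexp(joint[keep]) - logsumexp(joint)))
    return {"p": min(p, 1.0), "l2fc_fm": l2fc,
            "direction": "female" if l2fc > 0 else ("male" if l2fc < 0 else "none"),
            "mean_m": qM, "mean_f": qF, "alpha": float(alpha)}


def diff_accessibility(peaks: PeakCountMatrix, dispersion_mode: str = "trend",
                       fdr: float = 0.10) -> pd.DataFrame:
    """Per-peak differential accessibility table with BH q-values.

    The default significance threshold is FDR 10%; peaks are ranked by
    nominal p ascending with ties broken by |log2 fold| descending.
    """
    sex = peaks.samples.sex
    counts = peaks.counts
    sf = size_factors(counts)
    alpha = estimate_dispersion(counts, sex, sf, mode=dispersion_mode)
    rows = []
    for i in range(peaks.n_peaks):
        r = nb_test(counts[i], sex, sf, alpha[i])
        r["peak_id"] = peaks.peaks["peak_id"].iloc[i]
        r["chrom"] = peaks.peaks["chrom"].iloc[i]
        rows.append(r)
    out = pd.DataFrame(rows)
    out["q"] = stats.bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    out["rank"] = np.lexsort((-np.abs(out["l2fc_fm"].replace(
        [np.inf, -np.inf], np.nan).fillna(0.0)), out["p"])).argsort()
    return out[["peak_id", "chrom", "p", "q", "significant", "l2fc_fm",
                "direction", "mean_m", "mean_f", "alpha", "rank"]]


def peak_gene_link(peaks: PeakCountMatrix, annotation: GeneAnnotation,
                   upstream_bp: int = 40_000, strand_oriented: bool = True
                   ) -> pd.DataFrame:
    """Link peaks to genes whose upstream promoter window they intersect.

    The window spans ``upstream_bp`` bases upstream of the TSS; upstream is
    strand-oriented by default (higher coordinates for minus-strand genes),
    or genomic-left when ``strand_oriented=False``.  Multi-links allowed.
    """
    rows = []
    ann = annotation.table
    stss = annotation.strand_tss()
    for pi, pk in peaks.peaks.iterrows():
        same = ann["chrom"] == pk["chrom"]
        for gi in np.flatnonzero(same.to_numpy()):
            tss = int(stss.iloc[gi])
            minus = ann["strand"].iloc[gi] == "-"
            if strand_oriented and minus:
                lo, hi = tss, tss + upstream_bp
            else:
                lo, hi = tss - upstream_bp, tss
            # peak is 0-based half-open; gene window 1-based inclusive
            if pk["start"] + 1 <= hi and pk["end"] >= lo:
                rows.append((pk["peak_id"], ann["gene_id"].iloc[gi]))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id"])


def integration_enrichment(peak_diff: pd.DataFrame, gene_flags: pd.Series,
                           link_map: pd.DataFrame,
                           thresholds: tuple[float, ...] = (0.2, 0.1, 0.05),
                           gene_direction: pd.Series | None = None) -> dict:
    """Enrichment of sex-specific accessibility among flagged genes.

    Per q-threshold, a 2x2 Fisher test of (gene linked to a sex-specific
    peak) x (gene flag, e.g. differential expression or interaction-eQTL
    p < 0.1).  With ``gene_direction`` ("female"/"male" per gene), also runs
    the one-sided directional test that elevated expression in a sex pairs
    with depressed accessibility in that sex (opposing signs).
    """
    if link_map.empty:
        raise ValueError("empty peak-gene link map")
    pd_idx = peak_diff.set_index("peak_id")
    genes = gene_flags.index.to_numpy()
    per_thr = []
    for thr in thresholds:
        sig_peaks = set(pd_idx.index[pd_idx["q"] < thr])
        linked = link_map[link_map["peak_id"].isin(sig_peaks)]
        linked_genes = set(linked["gene_id"])
        has_peak = pd.Series([g in linked_genes for g in genes], index=genes)
        table = [[int((has_peak & gene_flags).sum()), int((has_peak & ~gene_flags).sum())],
                 [int((~has_peak & gene_flags).sum()), int((~has_peak & ~gene_flags).sum())]]
        if min(sum(t) for t in table) == 0 or table[0][0] + table[1][0] == 0:
            per_thr.append({"threshold": thr, "odds_ratio": np.nan, "p": np.nan,
                            "n_sig_peaks": len(sig_peaks)})
            logger.info("degenerate integration table at q < %.3g", thr)
            continue
        res = stats.fisher_exact(table, stats.TWO_SIDED)
        per_thr.append({"threshold": thr, "odds_ratio": res.effect,
                        "p": res.p_value, "ci_low": res.ci_low,
                        "ci_high": res.ci_high, "n_sig_peaks": len(sig_peaks)})
    out = {"per_threshold": pd.DataFrame(per_thr)}
    if gene_direction is not None:
        # sign concordance among flagged genes linked to sex-specific peaks:
        # rows = expression direction, cols = chromatin direction; opposing
        # directions load the off-diagonal, so test OR < 1 one-sided
        sig = pd_idx[pd_idx["q"] < max(thresholds)]
        merged = link_map.merge(sig[["direction"]], left_on="peak_id",
                                right_index=True)
        merged = merged[merged["gene_id"].isin(gene_direction.index)]
        merged = merged[gene_flags.reindex(merged["gene_id"]).fillna(False).to_numpy()]
        if len(merged):
            expr_dir = gene_direction.reindex(merged["gene_id"]).to_numpy()
            chrom_dir = merged["direction"].to_numpy()
            table = [[int(((expr_dir == "female") & (chrom_dir == "female")).sum()),
                      int(((expr_dir == "female") & (chrom_dir == "male")).sum())],
                     [int(((expr_dir == "male") & (chrom_dir == "female")).sum()),
                      int(((expr_dir == "male") & (chrom_dir == "male")).sum())]]
            res = stats.fisher_exact(table, stats.LESS)
            opposing = expr_dir != chrom_dir
            out["directional"] = {"n_pairs": int(len(merged)),
                                  "frac_opposing": float(opposing.mean()),
                                  "p": res.p_value, "odds_ratio": res.effect,
                                  "table": table}
        else:
            out["directional"] = {"n_pairs": 0, "frac_opposing": np.nan,
                                  "p": np.nan, "odds_ratio": np.nan}
    return out


def escape_enrichment(peak_diff: pd.DataFrame, escape_genes: set[str],
                      link_map: pd.DataFrame, top_fraction: float = 0.10
                      ) -> dict:
    """Fisher test: X-inactivation-escape status of linked genes x membership
    in the top decile of X-chromosome sex-specific peaks.

    Peaks are ranked by nominal p ascending (ties: |log2 fold| descending);
    the top set holds floor(top_fraction * n_x_peaks) peaks.
    """
    if not escape_genes:
        raise ValueError("empty escape gene list")
    x_peaks = peak_diff[dataio.is_x(peak_diff["chrom"].to_numpy())].copy()
    if x_peaks.empty:
        raise ValueError("no X-chromosome peaks")
    order = np.lexsort((-np.abs(x_peaks["l2fc_fm"].replace(
        [np.inf, -np.inf], np.nan).fillna(0.0).to_numpy()),
        x_peaks["p"].to_numpy()))
    n_top = int(np.floor(top_fraction * len(x_peaks)))
    top_ids = set(x_peaks["peak_id"].to_numpy()[order[:n_top]])
    linked = link_map[link_map["peak_id"].isin(set(x_peaks["peak_id"]))]
    rows = []
    for r in linked.itertuples(index=False):
        rows.append((r.gene_id in escape_genes, r.peak_id in top_ids))
    if not rows:
        raise ValueError("no genes linked to X peaks")
    esc = np.array([r[0] for r in rows])
    top = np.array([r[1] for r in rows])
    table = [[int((esc & top).sum()), int((esc & ~top).sum())],
             [int((~esc & top).sum()), int((~esc & ~top).sum())]]
    res = stats.fisher_exact(table, stats.GREATER)
    return {"n_top_peaks": n_top, "odds_ratio": res.effect, "p": res.p_value,
            "table": table,
            "prop_escape_top": table[0][0] / max(table[0][0] + table[1][0], 1),
            "prop_escape_shared": table[0][1] / max(table[0][1] + table[1][1], 1)}
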