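"""Sex-specific differential expression mean and variance (DV) testing.

Three DV strategies are provided, mirroring a three-pronged robustness
design:

* ``A_F``        — variance-ratio F test on every gene, no gating;
* ``B_gated``    — Shapiro-Wilk normality gate (on pooled values mean-centred
                   within sex by default), then F test if normality is not
                   rejected, Brown-Forsythe otherwise;
* ``C_residual`` — values are quantile-normalized to N(0,1), sex is regressed
                   out, and the gate-and-test of strategy B is applied to the
                   regression residuals.  Removing the mean effect of sex
                   distinguishes genuine differential variance from
                   differential expression leaking into the variance.

Mean differences are tested per gene with Welch's t on residual-scale values
or a negative-binomial exact test on counts (sharing the chromatin-module
machinery).  Sample sizes are matched between sexes by seeded random
subsampling of the majority sex before any variance comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import dataio, stats
from .dataio import FEMALE, MALE, ExpressionMatrix

logger = logging.getLogger(__name__)

STRATEGY_A = "A_F"
STRATEGY_B = "B_gated"
STRATEGY_C = "C_residual"

GATE_POOLED = "pooled"
GATE_PER_SEX = "per_sex"


def match_subsample(sex: np.ndarray, seed: int) -> np.ndarray:
    """Indices of all minority-sex samples plus an equally sized seeded
    uniform subsample of the majority sex; identity when already balanced."""
    sex = np.asarray(sex)
    males = np.flatnonzero(sex == MALE)
    females = np.flatnonzero(sex == FEMALE)
    if males.size == 0 or females.size == 0:
        raise ValueError("both sexes must be present")
    if males.size == females.size:
        return np.arange(sex.size)
    minority, majority = (males, females) if males.size < females.size else (females, males)
    rng = np.random.default_rng(seed)
    picked = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, picked]))


def quantile_normalize_to_normal(values: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles by rank: Phi^-1((r - 0.5)/n).

    Midranks are used for ties (tied inputs share the averaged quantile).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("constant vector cannot be quantile-normalized")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.5) / x.size)


@dataclass
class DvResult:
    gene_id: str
    strategy: str
    branch: str           # "F" or "BF"
    statistic: float
    p: float
    direction: str        # higher-variance sex: "female"/"male"
    shapiro_p: float = np.nan
    q: float = np.nan


def _center_within_sex(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    out = y.astype(float).copy()
    for grp in (MALE, FEMALE):
        m = s == grp
        out[m] -= out[m].mean()
    return out


def _gate(y: np.ndarray, s: np.ndarray, gate_scope: str, alpha: float
          ) -> tuple[bool, float]:
    """True when normality is NOT rejected (-> F branch)."""
    if gate_scope == GATE_PER_SEX:
        pm = stats.shapiro_wilk(y[s == MALE]).p_value
        pf = stats.shapiro_wilk(y[s == FEMALE]).p_value
        p = min(pm, pf)
    else:
        p = stats.shapiro_wilk(_center_within_sex(y, s)).p_value
    return p >= alpha, p


def test_dv(expr: ExpressionMatrix, sex: np.ndarray | None = None,
            strategy: str = STRATEGY_B, alpha_normality: float = 0.05,
            gate_scope: str = GATE_POOLED, matched: bool = True,
            seed: int = 0) -> pd.DataFrame:
    """Per-gene differential-variance test; returns one row per gene with
    branch taken, p, BH q and the higher-variance sex.

    ``matched=True`` subsamples the majority sex (seeded) before testing so
    the two variance estimates carry equal sample information.
    """
    if expr.kind != dataio.RESIDUALS:
        raise ValueError("DV testing expects residual-scale expression")
    s = expr.samples.sex if sex is None else np.asarray(sex)
    if matched:
        idx = match_subsample(s, seed)
    else:
        logger.info("DV testing on unmatched sample sizes")
        idx = np.arange(s.size)
    s_use = s[idx]
    if min((s_use == MALE).sum(), (s_use == FEMALE).sum()) < 3:
        raise ValueError("need at least 3 samples per sex")
    rows = []
    for gi, gene in enumerate(expr.gene_ids):
        y = expr.values[gi, idx]
        if strategy == STRATEGY_C:
            z = quantile_normalize_to_normal(y)
            X = np.column_stack([np.ones_like(z), s_use.astype(float)])
            beta, *_ = np.linalg.lstsq(X, z, rcond=None)
            y_test = z - X @ beta
        else:
            y_test = y
        ym, yf = y_test[s_use == MALE], y_test[s_use == FEMALE]
        shapiro_p = np.nan
        if strategy == STRATEGY_A:
            branch = "F"
        else:
            use_f, shapiro_p = _gate(y_test, s_use, gate_scope, alpha_normality)
            branch = "F" if use_f else "BF"
        res = stats.f_var_test(yf, ym) if branch == "F" else stats.brown_forsythe(yf, ym)
        direction = "female" if np.var(yf, ddof=1) >= np.var(ym, ddof=1) else "male"
        rows.append(DvResult(gene, strategy, branch, res.statistic, res.p_value,
                             direction, shapiro_p))
    out = pd.DataFrame([vars(r) for r in rows])
    out["q"] = stats.bh_fdr(out["p"].to_numpy())
    return out


@dataclass
class DeResult:
    gene_id: str
    test: str
    effect: float         # mean difference (welch, F-M) or log2 fold (nb, F/M)
    p: float
    direction: str
    q: float = np.nan


def test_de(expr: ExpressionMatrix, sex: np.ndarray | None = None,
            method: str = "welch", matched: bool = True, seed: int = 0
            ) -> pd.DataFrame:
    """Per-gene differential mean expression between sexes.

    ``welch`` runs Welch's t on residual-scale values; ``nb`` runs the
    negative-binomial exact test on raw counts with median-of-ratios size
    factors (delegating to the chromatin-accessibility machinery).
    """
    s = expr.samples.sex if sex is None else np.asarray(sex)
    idx = match_subsample(s, seed) if matched else np.arange(s.size)
    s_use = s[idx]
    rows: list[DeResult] = []
    if method == "welch":
        if expr.kind != dataio.RESIDUALS:
            raise ValueError("welch DE expects residual-scale expression")
        for gi, gene in enumerate(expr.gene_ids):
            y = expr.values[gi, idx]
            yf, ym = y[s_use == FEMALE], y[s_use == MALE]
            res = stats.welch_t(yf, ym)
            rows.append(DeResult(gene, "welch", res.effect, res.p_value,
                                 "female" if res.effect >= 0 else "male"))
    elif method == "nb":
        if expr.kind != dataio.COUNTS:
            raise ValueError("nb DE expects raw counts")
        from . import atac
        counts = expr.values[:, idx].astype(np.int64)
        sf = atac.size_factors(counts)
        alpha = atac.estimate_dispersion(counts, s_use, sf)
        for gi, gene in enumerate(expr.gene_ids):
            r = atac.nb_test(counts[gi], s_use, sf, alpha[gi])
            rows.append(DeResult(gene, "nb", r["l2fc_fm"], r["p"], r["direction"]))
    else:
        raise ValueError(f"unknown DE method {method!r}")
    out = pd.DataFrame([vars(r) for r in rows])
    out["q"] = stats.bh_fdr(out["p"].to_numpy())
    return out


def xa_proportion_test(significant: np.ndarray, chrom: np.ndarray,
                       sided: str = stats.GREATER) -> dict:
    """One-sided Fisher test that the significant-gene proportion is higher
    on X than on autosomes; reports both proportions."""
    sig = np.asarray(significant, dtype=bool)
    on_x = dataio.is_x(np.asarray(chrom))
    if on_x.all() or (~on_x).all():
        raise ValueError("need genes on both X and autosomes")
    table = [[int((sig & on_x).sum()), int((~sig & on_x).sum())],
             [int((sig & ~on_x).sum()), int((~sig & ~on_x).sum())]]
    res = stats.fisher_exact(table, sided)
    return {"prop_x": table[0][0] / on_x.sum(),
            "prop_auto": table[1][0] / (~on_x).sum(),
            "odds_ratio": res.effect, "p": res.p_value, "table": table}


def dv_de_overlap_test(dv_flags: np.ndarray, de_flags: np.ndarray) -> stats.TestResult:
    """Chi-squared test of association between DV and DE gene sets."""
    dv = np.asarray(dv_flags, dtype=bool)
    de = np.asarray(de_flags, dtype=bool)
    if dv.size == 0 or dv.size != de.size:
        raise ValueError("need aligned, nonempty flag vectors")
    table = [[int((dv & de).sum()), int((dv & ~de).sum())],
             [int((~dv & de).sum()), int((~dv & ~de).sum())]]
    return stats.chisq_2xk(table)
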