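"""Sex-interacting allele-specific expression (ASE) QTLs.

For each gene, haplotype-resolved allelic read counts are aggregated across
transcribed heterozygous sites within each individual and modelled with a
binomial generalized linear mixed model:

    alt_i ~ Binomial(n_i, logistic(alpha + gamma*h_i + delta*h_i*s_i + u_i))
    u_i ~ N(0, tau^2)

where h_i in {-1, 0, +1} is the phased regulatory-genotype contrast (sign =
which haplotype carries the regulatory alt allele; 0 = regulatory
homozygote, informing the baseline only), s_i is sex (male 0 / female 1),
and u_i an individual random intercept absorbing individual-level allelic
imbalance.  The sex-interacting aseQTL test is a likelihood-ratio test of
delta = 0 against chi-squared(1).

The random intercept is integrated out by adaptive Gauss-Hermite quadrature
centred at each individual's posterior mode with curvature-based scaling
(posterior modes found by a vectorized Newton iteration; the integrand is
strictly log-concave).  With tau fixed at 0 the model reduces exactly to a
logistic regression.  An optional beta-binomial kernel (``family``)
replaces the binomial when allelic ratios are overdispersed beyond the
random intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .dataio import AseTable

logger = logging.getLogger(__name__)

TAU_MAX = 5.0
N_NODES = 15


def aggregate_sites(ase: AseTable, min_total: int = 10) -> pd.DataFrame:
    """Sum ref/alt counts across sites per (individual, gene).

    Units with total reads below ``min_total`` are dropped (counts logged).
    ``h`` and ``sex`` must be constant within a unit.
    """
    t = ase.table
    if t.empty:
        return pd.DataFrame(columns=["individual", "gene_id", "ref_count",
                                     "alt_count", "total", "h", "sex"])
    grouped = t.groupby(["individual", "gene_id"], sort=True).agg(
        ref_count=("ref_count", "sum"), alt_count=("alt_count", "sum"),
        h=("h", "first"), h_n=("h", "nunique"),
        sex=("sex", "first"), sex_n=("sex", "nunique")).reset_index()
    if (grouped["h_n"] > 1).any() or (grouped["sex_n"] > 1).any():
        raise ValueError("h/sex inconsistent within an (individual, gene) unit")
    grouped["total"] = grouped["ref_count"] + grouped["alt_count"]
    kept = grouped[grouped["total"] >= min_total].drop(columns=["h_n", "sex_n"])
    n_drop = len(grouped) - len(kept)
    if n_drop:
        logger.info("aggregate_sites: dropped %d units below %d reads",
                    n_drop, min_total)
    return kept.reset_index(drop=True)


@dataclass
class AseFit:
    gene_id: str
    alpha: float
    gamma: float
    delta: float
    tau: float
    loglik: float
    lrt: float
    p: float
    n_units: int
    converged: bool
    family: str = "binomial"
    note: str = ""


def _binom_kernel(k, n, eta):
    """Binomial log-likelihood (with constant) at logit mean eta; stable."""
    # log sigma(eta) = -logaddexp(0, -eta); log(1 - sigma) = -logaddexp(0, eta)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return const - k * np.logaddexp(0.0, -eta) - (n - k) * np.logaddexp(0.0, eta)


def _marginal_loglik(k: np.ndarray, n: np.ndarray, eta0: np.ndarray,
                     tau: float, nodes: int = N_NODES) -> float:
    """Sum over individuals of log int Binom(k|n, sigma(eta0+u)) N(u;0,tau) du
    by adaptive Gauss-Hermite quadrature (vectorized Newton for the modes)."""
    if tau <= 1e-8:
        return float(_binom_kernel(k, n, eta0).sum())
    x, w = np.polynomial.hermite.hermgauss(nodes)
    inv_t2 = 1.0 / tau**2
    u = np.zeros_like(eta0, dtype=float)
    for _ in range(25):  # strictly concave => plain Newton converges
        sig = expit(eta0 + u)
        grad = (k - n * sig) - u * inv_t2
        hess = -(n * sig * (1 - sig) + inv_t2)
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    sig = expit(eta0 + u)
    s = 1.0 / np.sqrt(n * sig * (1 - sig) + inv_t2)
    uk = u[:, None] + np.sqrt(2.0) * s[:, None] * x[None, :]
    logg = (_binom_kernel(k[:, None], n[:, None], eta0[:, None] + uk)
            - 0.5 * uk**2 * inv_t2 - np.log(tau) - 0.5 * np.log(2 * np.pi))
    per_ind = logsumexp(np.log(w)[None, :] + x[None, :]**2 + logg, axis=1) \
        + 0.5 * np.log(2.0) + np.log(s)
    return float(per_ind.sum())


def _betabinom_loglik(k: np.ndarray, n: np.ndarray, eta0: np.ndarray,
                      log_phi: float) -> float:
    """Beta-binomial log-likelihood with mean logistic(eta0), precision
    phi = exp(log_phi) (no random intercept; phi absorbs overdispersion)."""
    mu = expit(eta0)
    phi = np.exp(log_phi)
    a = np.maximum(mu * phi, 1e-8)
    b = np.maximum((1 - mu) * phi, 1e-8)
    return float(sps.betabinom.logpmf(k.astype(int), n.astype(int), a, b).sum())


def _fit(k, n, h, s, with_delta: bool, family: str, tau_fixed: float | None,
         nodes: int) -> tuple[np.ndarray, float, bool]:
    hs = h * s

    def unpack(theta):
        alpha, gamma = theta[0], theta[1]
        j = 2
        delta = theta[j] if with_delta else 0.0
        j += int(with_delta)
        extra = theta[j] if j < len(theta) else None
        return alpha, gamma, delta, extra

    def nll(theta):
        alpha, gamma, delta, extra = unpack(theta)
        eta0 = alpha + gamma * h + delta * hs
        if family == "betabinom":
            return -_betabinom_loglik(k, n, eta0, extra)
        tau = tau_fixed if tau_fixed is not None else extra
        return -_marginal_loglik(k, n, eta0, tau, nodes)

    n_base = 2 + int(with_delta)
    if family == "betabinom":
        extra0, extra_bounds = [np.log(20.0)], [(-2.0, 12.0)]
    elif tau_fixed is None:
        extra0, extra_bounds = [0.3], [(1e-6, TAU_MAX)]
    else:
        extra0, extra_bounds = [], []
    bounds = [(-10, 10)] * n_base + extra_bounds
    best = None
    for start_scale in (1.0, 0.25):
        x0 = np.array([0.0] * n_base + [e * start_scale for e in extra0])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    theta = best.x
    return theta, -float(best.fun), bool(best.success)


def fit_ase_glmm(gene_table: pd.DataFrame, gene_id: str = "",
                 family: str = "binomial", tau: float | None = None,
                 nodes: int = N_NODES, min_per_sex: int = 5) -> AseFit:
    """Fit the sex-interacting ASE GLMM for one gene and LRT-test delta = 0.

    ``gene_table`` is the aggregated output of :func:`aggregate_sites` for
    one gene.  Requires at least ``min_per_sex`` individuals per sex with a
    nonzero phased contrast.  ``tau`` fixes the random-intercept SD (0 gives
    a plain logistic regression); None estimates it.  Returns a flagged
    non-converged fit (NaN estimates) rather than a silent bad optimum.
    """
    t = gene_table
    k = t["alt_count"].to_numpy(dtype=float)
    n = t["total"].to_numpy(dtype=float) if "total" in t else \
        (t["alt_count"] + t["ref_count"]).to_numpy(dtype=float)
    h = t["h"].to_numpy(dtype=float)
    s = t["sex"].to_numpy(dtype=float)
    informative = h != 0
    for code in (0.0, 1.0):
        if (informative & (s == code)).sum() < min_per_sex:
            raise ValueError(
                f"need >= {min_per_sex} informative individuals per sex")
    theta_f, ll_f, ok_f = _fit(k, n, h, s, True, family, tau, nodes)
    theta_r, ll_r, ok_r = _fit(k, n, h, s, False, family, tau, nodes)
    if not (ok_f and ok_r):
        logger.warning("gene %s: GLMM did not converge; returning NA fit", gene_id)
        return AseFit(gene_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                      np.nan, np.nan, len(t), False, family, "non-convergence")
    lrt = max(0.0, 2.0 * (ll_f - ll_r))
    p = float(sps.chi2.sf(lrt, 1))
    if family == "betabinom":
        tau_hat = 0.0
    elif tau is not None:
        tau_hat = float(tau)
    else:
        tau_hat = float(theta_f[3])
    return AseFit(gene_id, float(theta_f[0]), float(theta_f[1]),
                  float(theta_f[2]), tau_hat, ll_f, lrt, max(p, 1e-300),
                  len(t), True, family)


def ase_scan(ase: AseTable, min_total: int = 10, family: str = "binomial",
             min_per_sex: int = 5) -> pd.DataFrame:
    """Aggregate and fit every gene in an AseTable; one row per gene.

    Genes failing the informative-individual requirement are skipped with a
    log entry; non-converged fits appear with NaN estimates and a note.
    """
    agg = aggregate_sites(ase, min_total)
    rows = []
    for gene_id, sub in agg.groupby("gene_id", sort=True):
        try:
            fit = fit_ase_glmm(sub, gene_id, family=family,
                               min_per_sex=min_per_sex)
        except ValueError as exc:
            logger.info("gene %s skipped: %s", gene_id, exc)
            continue
        rows.append(vars(fit))
    return pd.DataFrame(rows)
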