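"""Brute-force enumeration oracles, independent of the package internals."""

import numpy as np
from math import comb

from scipy import stats as sps


def fisher_oracle_two_sided(a, b, c, d):
    """Sum hypergeometric table probabilities <= observed, by enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def fisher_oracle_greater(a, b, c, d):
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    hi = min(r1, c1)
    return sum(comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
               for x in range(a, hi + 1))


def binom_oracle_two_sided(k, n, p0=0.5):
    probs = [comb(n, x) * p0**x * (1 - p0)**(n - x) for x in range(n + 1)]
    return sum(p for p in probs if p <= probs[k] * (1 + 1e-12))


def nb_oracle(kM, kF, meanM, varM, meanF, varF):
    """Linear-space enumeration of the conditional exact NB test."""
    def pmf(k, mean, var):
        if var <= mean * (1 + 1e-12):
            return sps.poisson.pmf(k, mean)
        r = mean**2 / (var - mean)
        return sps.nbinom.pmf(k, r, r / (r + mean))

    T = kM + kF
    joint = np.array([pmf(a, meanM, varM) * pmf(T - a, meanF, varF)
                      for a in range(T + 1)])
    obs = joint[kM]
    return joint[joint <= obs * (1 + 1e-10)].sum() / joint.sum()
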