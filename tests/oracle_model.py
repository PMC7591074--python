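"""Independent brute-force re-implementation of the observer model.

Used only as a test oracle: everything is recomputed from scratch with
plain scipy/numpy and explicit loops, sharing no code with the package.
"""

import numpy as np
from scipy.stats import binom

N = 9
P_INIT = 0.05
U_INIT = 2.5
DELTA_P = (1 - 2 * P_INIT) / (N - 1)
XI = 0.02 / N**2


def power_binom(p, u, n=8):
    pmf = np.array([binom.pmf(k, n, p) for k in range(n + 1)])
    w = pmf**u
    return w / w.sum()


def oracle_policy(u_pi):
    """pi(r; HI, SI) as an 81 x 9 array, cell = HI * 9 + SI."""
    pol = np.zeros((81, 9))
    for hi_ in range(9):
        fh = power_binom(1 - P_INIT - DELTA_P * hi_, U_INIT - 2 * DELTA_P * (hi_ + 1))
        for si_ in range(9):
            fs = power_binom(1 - P_INIT - DELTA_P * si_, U_INIT - 2 * DELTA_P * (si_ + 1))
            row = fh * fs
            row = row / row.sum()
            row = row ** (1.0 / u_pi) + XI
            pol[hi_ * 9 + si_] = row / row.sum()
    return pol


def oracle_prior(pHI0, uHI0, pSI0, uSI0):
    h = power_binom(pHI0, 1.0 / uHI0)
    s = power_binom(pSI0, 1.0 / uSI0)
    prior = np.zeros(81)
    for a in range(9):
        for b in range(9):
            prior[a * 9 + b] = h[a] * s[b]
    return prior / prior.sum()


def oracle_bayes_update(belief81, r, pol):
    post = np.zeros(81)
    for c in range(81):
        post[c] = belief81[c] * pol[c, r - 1]
    return post / post.sum()


def oracle_rating_to_bin(rating):
    return min(8, rating * 9 // 100)


def oracle_session_loglik(pdict, returns, hi_ratings, si_ratings, pre_update=False):
    """Per-trial log-likelihoods, re-deriving every belief from scratch."""
    pol = oracle_policy(pdict["u_pi"])
    prior = oracle_prior(pdict["pHI0"], pdict["uHI0"], pdict["pSI0"], pdict["uSI0"])
    eta = pdict["eta"]
    out = np.zeros(18)
    block_prior = prior
    for b in range(3):
        belief = block_prior.copy()
        for t in range(6):
            i = b * 6 + t
            cell = oracle_rating_to_bin(hi_ratings[i]) * 9 + oracle_rating_to_bin(si_ratings[i])
            if pre_update:
                out[i] = np.log(max(belief[cell], 1e-30))
            belief = oracle_bayes_update(belief, returns[i], pol)
            if not pre_update:
                out[i] = np.log(max(belief[cell], 1e-30))
        if b < 2:
            block_prior = (1 - eta) * block_prior + eta * belief
            block_prior = block_prior / block_prior.sum()
    return out
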