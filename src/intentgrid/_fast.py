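"""Numba kernels for the hot loops of model fitting.

These mirror :mod:`intentgrid.core_model` exactly -- same belief recursion,
same scoring -- but operate on flat arrays so that per-participant MAP
fitting (thousands of likelihood evaluations) and the coarse grid search
stay fast on a single core.  ``tests/test_fitting.py`` asserts bitwise-level
agreement between this path and the reference implementation.

Layout conventions: beliefs are flat length-81 vectors with cell
``hi * 9 + si``; the policy template is passed as an (81, 9) row-stochastic
array ``template[cell, r - 1]``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N = 9
N_CELLS = 81
PROB_FLOOR = 1e-30

# log C(8, k) for k = 0..8
_LOG_C8 = np.log(np.array([1, 8, 28, 56, 70, 56, 28, 8, 1], dtype=float))


@njit(cache=True)
def _pmf9(p, u):
    """Sharpened binomial Bin(k; p, 8)**u over k = 0..8, normalised."""
    logw = np.empty(N)
    m = -1e300
    lp = math.log(p)
    lq = math.log1p(-p)
    for k in range(N):
        v = u * (_LOG_C8[k] + k * lp + (8 - k) * lq)
        logw[k] = v
        if v > m:
            m = v
    s = 0.0
    for k in range(N):
        logw[k] = math.exp(logw[k] - m)
        s += logw[k]
    for k in range(N):
        logw[k] /= s
    return logw


@njit(cache=True)
def _apply_uncertainty(template, inv_u_pi, xi, out):
    """out[c, r] = normalised template[c, r]**inv_u_pi + xi."""
    for c in range(N_CELLS):
        s = 0.0
        for r in range(N):
            v = template[c, r] ** inv_u_pi + xi
            out[c, r] = v
            s += v
        for r in range(N):
            out[c, r] /= s


@njit(cache=True)
def _run_session(prior, pol, eta, returns, hi, si, pre_update, out):
    """Belief recursion over 3 blocks x 6 trials; per-trial logliks into out."""
    belief = np.empty(N_CELLS)
    block_prior = prior.copy()
    for b in range(3):
        for c in range(N_CELLS):
            belief[c] = block_prior[c]
        for t in range(6):
            i = b * 6 + t
            cell = hi[i] * N + si[i]
            if pre_update:
                p = belief[cell]
                out[i] = math.log(p if p > PROB_FLOOR else PROB_FLOOR)
            r = returns[i] - 1
            z = 0.0
            for c in range(N_CELLS):
                belief[c] *= pol[c, r]
                z += belief[c]
            for c in range(N_CELLS):
                belief[c] /= z
            if not pre_update:
                p = belief[cell]
                out[i] = math.log(p if p > PROB_FLOOR else PROB_FLOOR)
        if b < 2:
            z = 0.0
            for c in range(N_CELLS):
                block_prior[c] = (1.0 - eta) * block_prior[c] + eta * belief[c]
                z += block_prior[c]
            for c in range(N_CELLS):
                block_prior[c] /= z


@njit(cache=True)
def session_per_trial(theta, returns, hi, si, template, xi, pre_update):
    """Per-trial log-likelihood vector (length 18) for one parameter vector.

    ``theta`` holds (pHI0, uHI0, pSI0, uSI0, u_pi, eta) on the natural
    scale; ``template`` is the (81, 9) raw policy template.
    """
    pol = np.empty((N_CELLS, N))
    _apply_uncertainty(template, 1.0 / theta[4], xi, pol)
    hi_m = _pmf9(theta[0], 1.0 / theta[1])
    si_m = _pmf9(theta[2], 1.0 / theta[3])
    prior = np.empty(N_CELLS)
    s = 0.0
    for a in range(N):
        for b in range(N):
            prior[a * N + b] = hi_m[a] * si_m[b]
            s += prior[a * N + b]
    for c in range(N_CELLS):
        prior[c] /= s
    out = np.empty(18)
    _run_session(prior, pol, theta[5], returns, hi, si, pre_update, out)
    return out


@njit(cache=True)
def grid_loglik(
    phi_vals,
    uhi_vals,
    psi_vals,
    usi_vals,
    upi_vals,
    eta_vals,
    returns,
    hi,
    si,
    template,
    xi,
    pre_update,
):
    """Data log-likelihood on the full Cartesian parameter grid.

    Returns an array indexed (pHI0, uHI0, pSI0, uSI0, u_pi, eta) so that
    ``.ravel()`` enumerates grid points in lexicographic parameter order.
    The policy (which depends only on u_pi) and the prior marginals are
    hoisted out of the inner loops.
    """
    n_ph, n_uh = phi_vals.size, uhi_vals.size
    n_ps, n_us = psi_vals.size, usi_vals.size
    n_up, n_et = upi_vals.size, eta_vals.size

    hi_margs = np.empty((n_ph, n_uh, N))
    for i in range(n_ph):
        for j in range(n_uh):
            hi_margs[i, j] = _pmf9(phi_vals[i], 1.0 / uhi_vals[j])
    si_margs = np.empty((n_ps, n_us, N))
    for i in range(n_ps):
        for j in range(n_us):
            si_margs[i, j] = _pmf9(psi_vals[i], 1.0 / usi_vals[j])

    out = np.empty((n_ph, n_uh, n_ps, n_us, n_up, n_et))
    pol = np.empty((N_CELLS, N))
    prior = np.empty(N_CELLS)
    per_trial = np.empty(18)
    for iu in range(n_up):
        _apply_uncertainty(template, 1.0 / upi_vals[iu], xi, pol)
        for ip in range(n_ph):
            for ih in range(n_uh):
                for js in range(n_ps):
                    for ju in range(n_us):
                        s = 0.0
                        for a in range(N):
                            for b in range(N):
                                v = hi_margs[ip, ih, a] * si_margs[js, ju, b]
                                prior[a * N + b] = v
                                s += v
                        for c in range(N_CELLS):
                            prior[c] /= s
                        for ie in range(n_et):
                            _run_session(
                                prior,
                                pol,
                                eta_vals[ie],
                                returns,
                                hi,
                                si,
                                pre_update,
                                per_trial,
                            )
                            tot = 0.0
                            for t in range(18):
                                tot += per_trial[t]
                            out[ip, ih, js, ju, iu, ie] = tot
    return out
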