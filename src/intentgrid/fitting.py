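"""Per-participant MAP estimation of the six observer parameters.

Fitting maximises the log-posterior ``lp = loglik + log_prior``: the
18-trial session likelihood of :func:`intentgrid.core_model.session_loglik`
penalised by a weak regularising prior that keeps parameters in their
psychologically meaningful ranges (uniform on the bounded parameters,
log-normal with unit median on the scale parameters).

The optimisation is a coarse Cartesian grid search followed by local ascent
(L-BFGS-B with numerical gradients) from the best few grid seeds, run on an
unconstrained transformed scale -- scaled logit for the probabilities and
the learning rate, scaled logit of the logarithm for the uncertainty
scales -- so the optimiser never leaves the feasible box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _fast
from .core_model import (
    DEFAULT_CONSTANTS,
    PARAM_NAMES,
    ParticipantParams,
    PolicyConstants,
    SessionData,
    build_policy_template,
)

__all__ = ["FitConfig", "FitResult", "log_prior", "grid_search", "map_fit", "fit_population"]

_SCALE_PARAMS = ("uHI0", "uSI0", "u_pi")
_LOGNORM_SIGMA = 1.5


@dataclass(frozen=True)
class FitConfig:
    """Grid resolution, bounds and optimiser settings for MAP fitting.

    ``n_grid`` gives the number of coarse-grid values per parameter
    (probabilities and ``eta`` spaced linearly, scales geometrically);
    ``n_restarts`` is the number of top grid seeds polished by local
    ascent.  ``seed`` is recorded for provenance; the fit itself is
    deterministic.
    """

    n_grid: int = 5
    bounds: dict = field(
        default_factory=lambda: {
            "pHI0": (0.01, 0.99),
            "uHI0": (0.05, 20.0),
            "pSI0": (0.01, 0.99),
            "uSI0": (0.05, 20.0),
            "u_pi": (0.05, 20.0),
            "eta": (0.0, 1.0),
        }
    )
    n_restarts: int = 3
    maxiter: int = 200
    tol: float = 1e-6
    seed: int = 0
    score_pre_update: bool = False

    def __post_init__(self) -> None:
        if self.n_grid < 1:
            raise ValueError("n_grid must be at least 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")
        if set(self.bounds) != set(PARAM_NAMES):
            raise ValueError("bounds must cover exactly the six parameters")

    @classmethod
    def fast(cls) -> "FitConfig":
        """Cheaper preset (coarser grid, fewer restarts) for large batches."""
        return cls(n_grid=4, n_restarts=2, maxiter=120)

    def grid_values(self, name: str) -> np.ndarray:
        lo, hi = self.bounds[name]
        if name in _SCALE_PARAMS:
            return np.geomspace(lo, hi, self.n_grid)
        return np.linspace(lo, hi, self.n_grid)


@dataclass
class FitResult:
    """MAP fit for one session: parameters, objective values, diagnostics."""

    participant_id: str
    params: ParticipantParams
    lp: float
    loglik: float
    per_trial: np.ndarray
    converged: bool
    n_eval: int
    gpts: int | None = None

    def __post_init__(self) -> None:
        self.per_trial = np.asarray(self.per_trial, dtype=float)
        if self.per_trial.shape != (18,):
            raise ValueError("per_trial must have length 18")
        if abs(self.per_trial.sum() - self.loglik) > 1e-8:
            raise ValueError("per-trial log-likelihoods must sum to loglik")


def log_prior(params: ParticipantParams, config: FitConfig | None = None) -> float:
    """Weak regularising log-prior density.

    Uniform (constant 0) on the bounded parameters pHI0, pSI0 and eta;
    log-normal(mu=0, sigma=1.5) on the scales uHI0, uSI0, u_pi, softly
    pulling them towards order 1.  Returns ``-inf`` outside the bounds.
    """
    config = config or DEFAULT_FIT_CONFIG
    lp = 0.0
    for name in PARAM_NAMES:
        lo, hi = config.bounds[name]
        x = getattr(params, name)
        if not lo <= x <= hi:
            return -math.inf
        if name in _SCALE_PARAMS:
            s = _LOGNORM_SIGMA
            lp += -math.log(x) - math.log(s * math.sqrt(2 * math.pi)) - math.log(x) ** 2 / (
                2 * s**2
            )
    return lp


DEFAULT_FIT_CONFIG = FitConfig()


def _log_prior_array(theta: np.ndarray, config: FitConfig) -> float:
    """log_prior on a raw parameter vector, without dataclass validation."""
    lp = 0.0
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = config.bounds[name]
        if not lo <= theta[i] <= hi:
            return -math.inf
        if name in _SCALE_PARAMS:
            s = _LOGNORM_SIGMA
            lx = math.log(theta[i])
            lp += -lx - math.log(s * math.sqrt(2 * math.pi)) - lx**2 / (2 * s**2)
    return lp


# ---------------------------------------------------------------------------
# transformed (unconstrained) scale

_EPS = 1e-9


def _to_unconstrained(theta: np.ndarray, config: FitConfig) -> np.ndarray:
    z = np.empty(6)
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = config.bounds[name]
        x = theta[i]
        if name in _SCALE_PARAMS:
            lo, hi, x = math.log(lo), math.log(hi), math.log(x)
        frac = np.clip((x - lo) / (hi - lo), _EPS, 1.0 - _EPS)
        z[i] = logit(frac)
    return z


def _to_natural(z: np.ndarray, config: FitConfig) -> np.ndarray:
    theta = np.empty(6)
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = config.bounds[name]
        if name in _SCALE_PARAMS:
            y = math.log(lo) + (math.log(hi) - math.log(lo)) * expit(z[i])
            theta[i] = math.exp(y)
        else:
            theta[i] = lo + (hi - lo) * expit(z[i])
    return theta


# ---------------------------------------------------------------------------
# session packing


def _pack(session: SessionData):
    return (
        session.returns.astype(np.int64),
        session.hi_bins.astype(np.int64),
        session.si_bins.astype(np.int64),
    )


def _template81(constants: PolicyConstants) -> np.ndarray:
    return np.ascontiguousarray(
        build_policy_template(constants).probs.reshape(_fast.N_CELLS, _fast.N)
    )


def session_loglik_fast(
    theta: np.ndarray,
    session: SessionData,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
    score_pre_update: bool = False,
) -> np.ndarray:
    """Per-trial log-likelihoods via the compiled kernel (reference-equal)."""
    returns, hi, si = _pack(session)
    return _fast.session_per_trial(
        np.asarray(theta, dtype=float),
        returns,
        hi,
        si,
        _template81(constants),
        constants.xi,
        score_pre_update,
    )


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    session: SessionData,
    config: FitConfig | None = None,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
    top_k: int | None = None,
):
    """Evaluate the log-posterior on the coarse Cartesian grid.

    Returns ``(seeds, lps)``: the ``top_k`` best parameter vectors (rows in
    PARAM_NAMES order) and their log-posteriors, sorted best-first with
    ties broken by lexicographic grid order.
    """
    config = config or DEFAULT_FIT_CONFIG
    top_k = top_k if top_k is not None else config.n_restarts
    grids = [config.grid_values(name) for name in PARAM_NAMES]
    returns, hi, si = _pack(session)
    ll = _fast.grid_loglik(
        *grids,
        returns,
        hi,
        si,
        _template81(constants),
        constants.xi,
        config.score_pre_update,
    ).ravel()

    # add the log-prior (separable across parameters) by broadcasting
    prior_terms = []
    for name, g in zip(PARAM_NAMES, grids):
        if name in _SCALE_PARAMS:
            s = _LOGNORM_SIGMA
            lg = np.log(g)
            prior_terms.append(-lg - math.log(s * math.sqrt(2 * math.pi)) - lg**2 / (2 * s**2))
        else:
            prior_terms.append(np.zeros_like(g))
    shape = tuple(len(g) for g in grids)
    lp = ll.reshape(shape).copy()
    for axis, term in enumerate(prior_terms):
        sl = [None] * 6
        sl[axis] = slice(None)
        lp += term[tuple(sl)]
    lp = lp.ravel()

    order = np.argsort(-lp, kind="stable")[: min(top_k, lp.size)]
    mesh = np.stack(
        [m.ravel() for m in np.meshgrid(*grids, indexing="ij")], axis=1
    )
    return mesh[order], lp[order]


# ---------------------------------------------------------------------------
# MAP fit


def map_fit(
    session: SessionData,
    config: FitConfig | None = None,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
) -> FitResult:
    """MAP estimate for one session: grid seeds, then bounded local ascent.

    The returned ``lp`` is never below the best grid seed's ``lp`` (the
    seed itself is kept if no ascent improves on it).  ``converged`` is
    False only when every restart reports optimiser failure.
    """
    config = config or DEFAULT_FIT_CONFIG
    returns, hi, si = _pack(session)
    template = _template81(constants)
    xi = constants.xi
    pre = config.score_pre_update
    n_eval = 0

    def neg_lp(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        theta = _to_natural(z, config)
        ll = _fast.session_per_trial(theta, returns, hi, si, template, xi, pre).sum()
        return -(ll + _log_prior_array(theta, config))

    seeds, seed_lps = grid_search(session, config, constants)
    n_eval += config.n_grid ** 6
    best_theta, best_lp = seeds[0], seed_lps[0]
    any_converged = False
    for seed in seeds:
        z0 = _to_unconstrained(seed, config)
        res = minimize(
            neg_lp,
            z0,
            method="L-BFGS-B",
            options={"maxiter": config.maxiter, "ftol": config.tol},
        )
        any_converged = any_converged or bool(res.success)
        if -res.fun > best_lp:
            best_lp = -res.fun
            best_theta = _to_natural(res.x, config)

    per_trial = _fast.session_per_trial(
        np.asarray(best_theta, dtype=float), returns, hi, si, template, xi, pre
    )
    loglik = float(per_trial.sum())
    params = ParticipantParams.from_array(best_theta)
    return FitResult(
        participant_id=session.participant_id,
        params=params,
        lp=float(best_lp),
        loglik=loglik,
        per_trial=per_trial,
        converged=any_converged,
        n_eval=n_eval,
        gpts=int(session.gpts),
    )


def fit_population(
    sessions,
    config: FitConfig | None = None,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
    progress: bool = False,
) -> list:
    """MAP-fit every session; returns a list of :class:`FitResult`."""
    config = config or DEFAULT_FIT_CONFIG
    results = []
    iterator = sessions
    if progress:
        from tqdm import tqdm

        iterator = tqdm(sessions, desc="fitting")
    for session in iterator:
        results.append(map_fit(session, config, constants))
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Parameter table: one row per participant with fit diagnostics."""
    rows = []
    for r in results:
        row = {"participant_id": r.participant_id}
        row.update({k: getattr(r.params, k) for k in PARAM_NAMES})
        row.update(
            {
                "lp": r.lp,
                "loglik": r.loglik,
                "converged": r.converged,
                "gpts": r.gpts,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
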