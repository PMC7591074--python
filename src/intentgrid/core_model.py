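"""Generative belief model for intent attribution in a serial dictator game.

A participant watches three dictators in turn, each making six splits of a
small endowment, and after every split rates the dictator's harmful intent
(HI) and self-interest (SI) on 1-100 scales.  The model treats the
participant as a Bayesian observer holding a joint belief distribution over
the dictator's latent attributes, discretised on a 9 x 9 lattice
(index 0 = totally altruistic end, index 8 = totally antisocial end).

The moving parts:

* a *sharpened binomial* family ``NB(k; p, u, n) ~ Bin(k; p, n)**u`` used
  both for the participant's priors and for the attribute-to-behaviour
  policy template -- the exponent ``u`` sharpens (u > 1) or blunts (u < 1)
  the distribution while preserving its mode;
* a fixed *policy template* mapping every (HI, SI) cell to a distribution
  over nine possible return bins (r = 1: dictator keeps everything,
  r = 9: returns everything, r = 5: returns half);
* an idiosyncratic *policy uncertainty* ``u_pi`` that flattens the template
  (exponent ``1/u_pi``) plus a small lapse rate for numerical stability;
* exact grid-based Bayesian updates of the belief after each observed
  return, and a learning-rate ``eta`` mixing the posterior about one
  dictator into the prior for the next;
* a response model in which the two ratings are a joint draw from the
  81-cell belief, so that a maximally uncertain observer scores
  ``ln(1/81) = -4.394`` per trial -- the chance floor used in diagnostics.

Each participant is characterised by six parameters (``ParticipantParams``):
prior modes ``pHI0, pSI0``, prior uncertainties ``uHI0, uSI0`` (entering as
exponent ``1/u``, so larger means flatter), policy uncertainty ``u_pi`` and
learning rate ``eta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom

__all__ = [
    "N_LEVELS",
    "N_CELLS",
    "CHANCE_LOGLIK",
    "LOG_FLOOR",
    "PARAM_NAMES",
    "PolicyConstants",
    "ParticipantParams",
    "BeliefGrid",
    "PolicyMatrix",
    "SessionData",
    "sharpened_binomial",
    "build_prior",
    "build_policy_template",
    "apply_policy_uncertainty",
    "bayes_update",
    "carry_over_prior",
    "rating_to_bin",
    "bin_to_rating",
    "trial_loglik",
    "session_loglik",
]

#: Number of discrete levels per attribute dimension (and of return bins).
N_LEVELS = 9
#: Number of cells in the joint (HI, SI) belief lattice.
N_CELLS = N_LEVELS * N_LEVELS
#: Per-trial log-likelihood of an observer hedging uniformly over all 81
#: possible joint responses: ln(1/81).
CHANCE_LOGLIK = -math.log(N_CELLS)
#: Probability floor applied before taking logs.
PROB_FLOOR = 1e-30
LOG_FLOOR = math.log(PROB_FLOOR)

#: Canonical parameter order used by array round-trips and CSV tables.
PARAM_NAMES = ("pHI0", "uHI0", "pSI0", "uSI0", "u_pi", "eta")

DICTATOR_TYPES = ("fair", "partially_fair", "unfair")
N_BLOCKS = 3
TRIALS_PER_BLOCK = 6
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class PolicyConstants:
    """Fixed constants of the attribute-to-behaviour policy template.

    ``delta_p`` spaces the binomial success probability linearly from
    ``1 - p_init`` (most generous cell) down to ``p_init`` (least generous)
    across the 9 attribute levels; with the default constants it equals
    0.1125 exactly.  ``xi = 0.02 / n_pi**2`` is the small fixed lapse rate
    added to each policy row for numerical stability.
    """

    n_pi: int = N_LEVELS
    p_init: float = 0.05
    u_init: float = 2.5

    def __post_init__(self) -> None:
        if self.n_pi < 2:
            raise ValueError("n_pi must be at least 2")
        if not 0.0 < self.p_init < 0.5:
            raise ValueError("p_init must lie in (0, 0.5)")
        if self.u_init <= 0.0:
            raise ValueError("u_init must be positive")

    @property
    def delta_p(self) -> float:
        return (1.0 - 2.0 * self.p_init) / (self.n_pi - 1)

    @property
    def xi(self) -> float:
        return 0.02 / self.n_pi**2


DEFAULT_CONSTANTS = PolicyConstants()


@dataclass(frozen=True)
class ParticipantParams:
    """The six fitted per-participant quantities.

    pHI0, pSI0
        Modes of the prior beliefs over harmful intent / self-interest,
        on (0, 1); 0 maps to the altruistic end of the lattice.
    uHI0, uSI0
        Prior uncertainties (> 0).  They enter as exponent ``1/u`` on the
        prior binomial, so larger values mean flatter priors, i.e. reduced
        initial confidence.
    u_pi
        Policy uncertainty (> 0): exponent ``1/u_pi`` flattening the policy
        template, making every observed return less informative.
    eta
        Learning rate in [0, 1] carrying the posterior about one dictator
        over into the prior for the next.
    """

    pHI0: float
    uHI0: float
    pSI0: float
    uSI0: float
    u_pi: float
    eta: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")
        if not (0.0 < self.pHI0 < 1.0 and 0.0 < self.pSI0 < 1.0):
            raise ValueError("pHI0 and pSI0 must lie in (0, 1)")
        if self.uHI0 <= 0.0 or self.uSI0 <= 0.0 or self.u_pi <= 0.0:
            raise ValueError("uHI0, uSI0 and u_pi must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "ParticipantParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values")
        return cls(**dict(zip(PARAM_NAMES, values)))


@dataclass
class BeliefGrid:
    """Joint probability over the 9 x 9 (HI, SI) lattice; axis 0 is HI."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_LEVELS, N_LEVELS):
            raise ValueError(f"belief grid must be {N_LEVELS}x{N_LEVELS}")
        if np.any(self.probs < 0.0):
            raise ValueError("belief probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError("belief grid must sum to 1")

    @classmethod
    def uniform(cls) -> "BeliefGrid":
        return cls(np.full((N_LEVELS, N_LEVELS), 1.0 / N_CELLS))

    @property
    def hi_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    @property
    def si_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    def mean_hi(self) -> float:
        return float(self.hi_marginal @ np.arange(N_LEVELS))

    def mean_si(self) -> float:
        return float(self.si_marginal @ np.arange(N_LEVELS))

    def entropy(self) -> float:
        p = self.probs[self.probs > 0.0]
        return float(-(p * np.log(p)).sum())


@dataclass
class PolicyMatrix:
    """Distribution over 9 return bins for each (HI, SI) attribute cell.

    ``probs[hi, si, r - 1]`` is the probability that a dictator with
    attributes (hi, si) returns bin ``r``.  ``uncertainty_applied``
    distinguishes the raw template from its ``1/u_pi``-flattened,
    lapse-stabilised form; only the latter may enter Bayesian updates.
    """

    probs: np.ndarray
    uncertainty_applied: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_LEVELS, N_LEVELS, N_LEVELS):
            raise ValueError("policy matrix must be 9x9x9")
        if np.any(self.probs < 0.0):
            raise ValueError("policy probabilities must be non-negative")
        rowsums = self.probs.sum(axis=2)
        if np.any(np.abs(rowsums - 1.0) > _NORM_TOL):
            raise ValueError("each (HI, SI) policy row must sum to 1")

    def row(self, hi: int, si: int) -> np.ndarray:
        return self.probs[hi, si]

    def return_slice(self, observed: int) -> np.ndarray:
        """9 x 9 likelihood slice ``pi(r = observed; HI, SI)``."""
        if not 1 <= int(observed) <= N_LEVELS:
            raise ValueError("return bin must lie in 1..9")
        return self.probs[:, :, int(observed) - 1]


@dataclass
class SessionData:
    """One participant's 18-trial session: 3 dictator blocks x 6 trials.

    Trials are stored flat in encounter order; block ``b`` occupies trials
    ``6 b .. 6 b + 5``.  Ratings are on the raw 1-100 scale; returns are
    bins 1-9 (1 = nothing returned, 5 = half, 9 = everything).
    """

    participant_id: str
    gpts: int
    dictator_types: tuple
    returns: np.ndarray
    hi_ratings: np.ndarray
    si_ratings: np.ndarray
    order_label: str = ""

    def __post_init__(self) -> None:
        self.returns = np.asarray(self.returns, dtype=int)
        self.hi_ratings = np.asarray(self.hi_ratings, dtype=int)
        self.si_ratings = np.asarray(self.si_ratings, dtype=int)
        self.dictator_types = tuple(self.dictator_types)
        if len(self.dictator_types) != N_BLOCKS:
            raise ValueError("exactly 3 dictator blocks are required")
        for d in self.dictator_types:
            if d not in DICTATOR_TYPES:
                raise ValueError(f"unknown dictator type {d!r}")
        for name, arr in (
            ("returns", self.returns),
            ("hi_ratings", self.hi_ratings),
            ("si_ratings", self.si_ratings),
        ):
            if arr.shape != (N_TRIALS,):
                raise ValueError(f"{name} must have exactly {N_TRIALS} entries")
        if np.any((self.returns < 1) | (self.returns > N_LEVELS)):
            raise ValueError("return bins must lie in 1..9")
        for name, arr in (("hi_ratings", self.hi_ratings), ("si_ratings", self.si_ratings)):
            if np.any((arr < 1) | (arr > 100)):
                raise ValueError(f"{name} must lie in 1..100")
        if not 32 <= int(self.gpts) <= 160:
            raise ValueError("GPTS total must lie in 32..160")
        if not self.order_label:
            self.order_label = "-".join(self.dictator_types)

    @property
    def hi_bins(self) -> np.ndarray:
        return np.array([rating_to_bin(r) for r in self.hi_ratings])

    @property
    def si_bins(self) -> np.ndarray:
        return np.array([rating_to_bin(r) for r in self.si_ratings])

    def block_returns(self, block: int) -> np.ndarray:
        return self.returns[block * TRIALS_PER_BLOCK : (block + 1) * TRIALS_PER_BLOCK]


# ---------------------------------------------------------------------------
# distributions


def sharpened_binomial(p: float, u: float, n: int) -> np.ndarray:
    """Binomial pmf over {0..n} raised to the power ``u`` and renormalised.

    ``u = 1`` recovers the plain binomial; ``u > 1`` sharpens the
    distribution around its (unchanged) mode, ``u < 1`` blunts it, and
    ``u = 0`` flattens it to uniform.  Computed in log space so extreme
    exponents stay stable.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    if u < 0.0:
        raise ValueError("exponent u must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    logpmf = binom.logpmf(np.arange(n + 1), n, p)
    logw = u * logpmf
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def build_prior(
    params: ParticipantParams, constants: PolicyConstants = DEFAULT_CONSTANTS
) -> BeliefGrid:
    """Initial joint belief: outer product of sharpened-binomial marginals.

    The HI marginal is ``NB(k; pHI0, 1/uHI0, 8)`` and the SI marginal the
    analogue with (pSI0, uSI0); the uncertainties enter as the *inverse*
    exponent so that larger ``u`` means a flatter marginal.  The joint is
    the product of the two independent marginals.
    """
    n = constants.n_pi - 1
    hi = sharpened_binomial(params.pHI0, 1.0 / params.uHI0, n)
    si = sharpened_binomial(params.pSI0, 1.0 / params.uSI0, n)
    joint = np.outer(hi, si)
    return BeliefGrid(joint / joint.sum())


# ---------------------------------------------------------------------------
# policy map


def build_policy_template(
    constants: PolicyConstants = DEFAULT_CONSTANTS,
) -> PolicyMatrix:
    """Shared attribute-to-behaviour template ``pi_gen(r; HI, SI)``.

    Per attribute dimension the return distribution over ``r - 1`` in
    {0..8} is a sharpened binomial with success probability
    ``1 - p_init - delta_p * a`` and exponent ``u_init - 2 delta_p (a + 1)``
    for level ``a``; the joint row is the normalised product of the HI and
    SI factors.  At (HI=0, SI=0) the row peaks at r = 9 (return everything),
    at (HI=8, SI=8) at r = 1 (return nothing).
    """
    n = constants.n_pi - 1
    factors = np.empty((N_LEVELS, N_LEVELS))
    for a in range(N_LEVELS):
        p = 1.0 - constants.p_init - constants.delta_p * a
        u = constants.u_init - 2.0 * constants.delta_p * (a + 1)
        if u <= 0.0:
            raise ValueError(f"policy exponent non-positive at level {a}")
        factors[a] = sharpened_binomial(p, u, n)
    probs = factors[:, None, None, :] * factors[None, :, None, :]
    probs = probs.reshape(N_LEVELS, N_LEVELS, N_LEVELS)
    probs /= probs.sum(axis=2, keepdims=True)
    return PolicyMatrix(probs, uncertainty_applied=False)


def apply_policy_uncertainty(
    template: PolicyMatrix,
    u_pi: float,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
) -> PolicyMatrix:
    """Flatten the template by ``1/u_pi`` and add the lapse rate ``xi``.

    ``pi(r; HI, SI) ~ pi_gen(r; HI, SI)**(1/u_pi) + xi``, renormalised per
    (HI, SI) row.  Larger ``u_pi`` pushes every row towards uniform; the
    lapse keeps all entries strictly positive so Bayesian updates can never
    hit a zero normaliser.
    """
    if template.uncertainty_applied:
        raise ValueError("policy uncertainty has already been applied")
    if u_pi <= 0.0:
        raise ValueError("u_pi must be positive")
    probs = template.probs ** (1.0 / u_pi) + constants.xi
    probs /= probs.sum(axis=2, keepdims=True)
    return PolicyMatrix(probs, uncertainty_applied=True)


# ---------------------------------------------------------------------------
# updating


def bayes_update(
    belief: BeliefGrid, observed: int, policy: PolicyMatrix
) -> BeliefGrid:
    """Exact grid Bayes rule after observing return bin ``observed``.

    ``p_t(HI, SI) = pi(r; HI, SI) p_{t-1}(HI, SI) / Z`` with ``Z`` the sum
    of the numerator over all 81 cells.
    """
    if not policy.uncertainty_applied:
        raise ValueError("bayes_update requires an uncertainty-applied policy")
    post = policy.return_slice(observed) * belief.probs
    z = post.sum()
    if z <= 0.0 or not np.isfinite(z):
        raise FloatingPointError("degenerate normaliser in Bayesian update")
    return BeliefGrid(post / z)


def carry_over_prior(
    prior_d: BeliefGrid, posterior_d: BeliefGrid, eta: float
) -> BeliefGrid:
    """Prior for the next dictator: convex mixture ``(1-eta) prior + eta posterior``."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    mixed = (1.0 - eta) * prior_d.probs + eta * posterior_d.probs
    return BeliefGrid(mixed / mixed.sum())


# ---------------------------------------------------------------------------
# response model


def rating_to_bin(rating: int) -> int:
    """Map a 1-100 rating onto lattice index 0..8: ``min(8, floor(r*9/100))``."""
    rating = int(rating)
    if not 1 <= rating <= 100:
        raise ValueError("rating must lie in 1..100")
    return min(N_LEVELS - 1, rating * N_LEVELS // 100)


def bin_to_rating(index: int) -> int:
    """Inverse of :func:`rating_to_bin` using bin centres."""
    index = int(index)
    if not 0 <= index < N_LEVELS:
        raise ValueError("index must lie in 0..8")
    return int(round((index + 0.5) * 100 / N_LEVELS))


def trial_loglik(belief: BeliefGrid, hi: int, si: int) -> float:
    """Log-probability of reporting the joint cell (hi, si).

    Ratings are modelled as one joint draw from the 81-cell belief, so a
    uniform belief yields ``ln(1/81) = -4.394`` and a point mass at the
    reported cell yields 0.  The cell mass is floored at 1e-30 before the
    log.
    """
    for idx in (hi, si):
        if not 0 <= int(idx) < N_LEVELS:
            raise ValueError("attribute indices must lie in 0..8")
    return float(np.log(max(belief.probs[hi, si], PROB_FLOOR)))


def session_loglik(
    params: ParticipantParams,
    session: SessionData,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
    score_pre_update: bool = False,
):
    """Total and per-trial log-likelihood of one 18-trial session.

    For each dictator block the prior is built (block 1) or carried over
    (blocks 2-3 via ``eta``); within a block each observed return triggers a
    Bayesian update and the trial's reported (HI, SI) bins are then scored
    against the updated belief (participants rate after seeing the split).
    Set ``score_pre_update=True`` to score against the pre-update belief
    instead.

    Returns ``(total, per_trial)`` with ``per_trial`` of length 18.
    """
    template = build_policy_template(constants)
    policy = apply_policy_uncertainty(template, params.u_pi, constants)
    hi_bins = session.hi_bins
    si_bins = session.si_bins
    per_trial = np.empty(N_TRIALS)

    block_prior = build_prior(params, constants)
    for b in range(N_BLOCKS):
        belief = block_prior
        for t in range(TRIALS_PER_BLOCK):
            i = b * TRIALS_PER_BLOCK + t
            if score_pre_update:
                per_trial[i] = trial_loglik(belief, hi_bins[i], si_bins[i])
                belief = bayes_update(belief, int(session.returns[i]), policy)
            else:
                belief = bayes_update(belief, int(session.returns[i]), policy)
                per_trial[i] = trial_loglik(belief, hi_bins[i], si_bins[i])
        if b < N_BLOCKS - 1:
            block_prior = carry_over_prior(block_prior, belief, params.eta)
    return float(per_trial.sum()), per_trial
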