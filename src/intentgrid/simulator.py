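"""Forward simulation: dictator behaviour and participant attributions.

Given a participant's six parameters, the simulator runs the same belief
recursion as the likelihood and, at each trial, samples one joint (HI, SI)
cell from the post-update belief and reports the corresponding bin-centre
ratings.  Dictators are of three kinds -- fair (always return half),
partially fair (50:50 chance of returning half or nothing) and unfair
(always return nothing) -- seen in counterbalanced order, six trials each.

All randomness flows from one master seed through per-participant
substreams (:class:`numpy.random.SeedSequence` spawning), so populations
are reproducible participant-by-participant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_CONSTANTS,
    DICTATOR_TYPES,
    N_BLOCKS,
    N_TRIALS,
    TRIALS_PER_BLOCK,
    ParticipantParams,
    PolicyConstants,
    SessionData,
    apply_policy_uncertainty,
    bin_to_rating,
    build_policy_template,
    build_prior,
)

__all__ = [
    "DICTATOR_ORDERS",
    "simulate_dictator_returns",
    "simulate_participant",
    "simulate_population",
    "sessions_to_frame",
]

#: The three counterbalanced block orders (cyclic rotations of the types).
DICTATOR_ORDERS = (
    ("fair", "partially_fair", "unfair"),
    ("partially_fair", "unfair", "fair"),
    ("unfair", "fair", "partially_fair"),
)

#: Return bin meaning per dictator action: half of the endowment -> bin 5,
#: nothing -> bin 1 (r = round(f * 8) + 1 for returned fraction f).
_RETURN_HALF = 5
_RETURN_NONE = 1


def simulate_dictator_returns(
    dictator_type: str,
    n_trials: int = TRIALS_PER_BLOCK,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Realised return-bin sequence for one dictator block."""
    if dictator_type == "fair":
        return np.full(n_trials, _RETURN_HALF, dtype=int)
    if dictator_type == "unfair":
        return np.full(n_trials, _RETURN_NONE, dtype=int)
    if dictator_type == "partially_fair":
        if rng is None:
            raise ValueError("partially_fair requires an rng")
        return np.where(
            rng.random(n_trials) < 0.5, _RETURN_HALF, _RETURN_NONE
        ).astype(int)
    raise ValueError(f"unknown dictator type {dictator_type!r}")


def _sample_cell(belief_flat: np.ndarray, rng: np.random.Generator) -> int:
    c = np.cumsum(belief_flat)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right").clip(0, 80))


def simulate_participant(
    params: ParticipantParams,
    order,
    rng: np.random.Generator,
    participant_id: str = "sim",
    gpts: int = 32,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
    replay_returns: np.ndarray | None = None,
) -> SessionData:
    """Generate one 18-trial session from known parameters.

    ``order`` is a permutation of the three dictator types.  If
    ``replay_returns`` (length 18) is given, those observed returns are
    replayed instead of freshly simulated dictator behaviour -- useful when
    regenerating attributions for sessions that were actually observed.
    """
    order = tuple(order)
    if sorted(order) != sorted(DICTATOR_TYPES):
        raise ValueError("order must be a permutation of the three dictator types")
    template = build_policy_template(constants)
    policy = apply_policy_uncertainty(template, params.u_pi, constants)

    returns = np.empty(N_TRIALS, dtype=int)
    hi_ratings = np.empty(N_TRIALS, dtype=int)
    si_ratings = np.empty(N_TRIALS, dtype=int)

    block_prior = build_prior(params, constants).probs
    for b, dtype_ in enumerate(order):
        if replay_returns is not None:
            block_returns = np.asarray(replay_returns, dtype=int)[
                b * TRIALS_PER_BLOCK : (b + 1) * TRIALS_PER_BLOCK
            ]
        else:
            block_returns = simulate_dictator_returns(dtype_, TRIALS_PER_BLOCK, rng)
        belief = block_prior.copy()
        for t in range(TRIALS_PER_BLOCK):
            i = b * TRIALS_PER_BLOCK + t
            r = int(block_returns[t])
            belief = policy.return_slice(r) * belief
            belief /= belief.sum()
            cell = _sample_cell(belief.ravel(), rng)
            hi_ratings[i] = bin_to_rating(cell // 9)
            si_ratings[i] = bin_to_rating(cell % 9)
            returns[i] = r
        if b < N_BLOCKS - 1:
            block_prior = (1.0 - params.eta) * block_prior + params.eta * belief
            block_prior /= block_prior.sum()

    return SessionData(
        participant_id=participant_id,
        gpts=int(gpts),
        dictator_types=order,
        returns=returns,
        hi_ratings=hi_ratings,
        si_ratings=si_ratings,
        order_label="-".join(order),
    )


def simulate_population(
    param_table: pd.DataFrame,
    seed: int,
    constants: PolicyConstants = DEFAULT_CONSTANTS,
    replay: dict | None = None,
) -> list:
    """Simulate one session per row of a parameter table.

    The table needs columns ``participant_id``, ``gpts`` and the six
    parameters; block orders are assigned round-robin over the three
    counterbalanced orders.  ``replay`` may map participant id to an
    observed length-18 return sequence.  Each participant gets an
    independent child stream of the master ``seed``.
    """
    if len(param_table) == 0:
        raise ValueError("parameter table is empty")
    streams = np.random.SeedSequence(seed).spawn(len(param_table))
    sessions = []
    for k, (_, row) in enumerate(param_table.iterrows()):
        params = ParticipantParams(
            **{name: float(row[name]) for name in
               ("pHI0", "uHI0", "pSI0", "uSI0", "u_pi", "eta")}
        )
        pid = str(row["participant_id"])
        sessions.append(
            simulate_participant(
                params,
                DICTATOR_ORDERS[k % len(DICTATOR_ORDERS)],
                np.random.default_rng(streams[k]),
                participant_id=pid,
                gpts=int(row["gpts"]),
                constants=constants,
                replay_returns=None if replay is None else replay.get(pid),
            )
        )
    return sessions


def sessions_to_frame(sessions) -> pd.DataFrame:
    """Long-format trial table (18 rows per participant)."""
    rows = []
    for s in sessions:
        for b in range(N_BLOCKS):
            for t in range(TRIALS_PER_BLOCK):
                i = b * TRIALS_PER_BLOCK + t
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "gpts": s.gpts,
                        "block_index": b + 1,
                        "dictator_type": s.dictator_types[b],
                        "trial": t + 1,
                        "return_bin": int(s.returns[i]),
                        "hi_rating": int(s.hi_ratings[i]),
                        "si_rating": int(s.si_ratings[i]),
                        "order_label": s.order_label,
                    }
                )
    return pd.DataFrame(rows)
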