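"""Validation workflow: fit diagnostics, behavioural summaries, parameter
recovery, and a partial-correlation network over fitted parameters.

The stages mirror how grid-based observer models are usually validated:

1. *Diagnostics* -- per-trial log-likelihoods aggregated by trial index,
   dictator type and paranoia (GPTS) quantile, each stratum compared with
   the chance floor ``ln(1/81) = -4.394`` of an observer hedging uniformly
   over all joint responses.
2. *Behavioural summaries* -- mean attribution ratings by dictator type,
   GPTS group and trial, plus rank correlations between paranoia and the
   attributions.
3. *Parameter recovery* -- simulate from known parameters, refit, and
   report Spearman rho, bias and RMSE per parameter.
4. *Network* -- unregularised partial correlations between the fitted
   parameters and GPTS (precision-matrix inversion with a ridge fallback),
   bootstrap percentile intervals for the edges, and nodewise moderated
   regressions testing whether edges change with GPTS.
5. *Cluster control* -- networks refitted on populations whose prior modes
   were drawn from disconnected density clusters with all other parameters
   independent; edges reappearing there with the same sign as in the
   reference network are flagged as possible fitting artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .core_model import CHANCE_LOGLIK, PARAM_NAMES, TRIALS_PER_BLOCK
from .fitting import FitConfig, fit_population, results_to_frame
from .simulator import simulate_population
from .synthetic_data import (
    PopulationSpec,
    generate_cluster_population,
    generate_population,
)

__all__ = [
    "DiagnosticsReport",
    "RecoveryReport",
    "NetworkResult",
    "run_diagnostics",
    "summarize_attributions",
    "run_recovery",
    "parameter_network",
    "network_sign_table",
    "cluster_control",
]


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DiagnosticsReport:
    by_trial: pd.DataFrame
    by_dictator: pd.DataFrame
    by_gpts_quantile: pd.DataFrame
    overall: dict
    chance_floor: float = CHANCE_LOGLIK
    below_chance_strata: list = field(default_factory=list)

    def summary_text(self) -> str:
        lines = [
            "Model-fit diagnostics",
            f"  chance floor (uniform belief): {self.chance_floor:.4f}",
            "  overall per-trial log-likelihood: "
            f"mean {self.overall['mean']:.3f}, median {self.overall['median']:.3f}, "
            f"range [{self.overall['min']:.3f}, {self.overall['max']:.3f}]",
            f"  strata below chance: {self.below_chance_strata or 'none'}",
        ]
        return "\n".join(lines)


def _per_trial_frame(fits, sessions) -> pd.DataFrame:
    by_id = {s.participant_id: s for s in sessions}
    if set(f.participant_id for f in fits) - set(by_id):
        missing = sorted(set(f.participant_id for f in fits) - set(by_id))
        raise ValueError(f"fits without matching sessions: {missing[:5]}")
    rows = []
    for f in fits:
        s = by_id[f.participant_id]
        for i, ll in enumerate(f.per_trial):
            rows.append(
                {
                    "participant_id": f.participant_id,
                    "gpts": s.gpts,
                    "trial_overall": i + 1,
                    "dictator_type": s.dictator_types[i // TRIALS_PER_BLOCK],
                    "loglik": float(ll),
                }
            )
    return pd.DataFrame(rows)


def run_diagnostics(fits, sessions, n_quantiles: int = 4) -> DiagnosticsReport:
    """Aggregate per-trial log-likelihoods by trial, dictator and GPTS quantile.

    Any stratum whose mean falls below the chance floor is flagged; with an
    adequately fitting model all strata should sit well above it.
    """
    frame = _per_trial_frame(fits, sessions)
    by_trial = (
        frame.groupby("trial_overall")["loglik"].agg(["mean", "count"]).reset_index()
    )
    by_dictator = (
        frame.groupby("dictator_type")["loglik"].agg(["mean", "count"]).reset_index()
    )
    q = pd.qcut(frame["gpts"], q=n_quantiles, duplicates="drop")
    by_q = (
        frame.assign(gpts_quantile=q)
        .groupby("gpts_quantile", observed=True)["loglik"]
        .agg(["mean", "count"])
        .reset_index()
    )
    overall = {
        "mean": float(frame["loglik"].mean()),
        "median": float(frame["loglik"].median()),
        "min": float(frame["loglik"].min()),
        "max": float(frame["loglik"].max()),
    }
    below = []
    for name, table, key in (
        ("trial", by_trial, "trial_overall"),
        ("dictator", by_dictator, "dictator_type"),
        ("gpts_quantile", by_q, "gpts_quantile"),
    ):
        for _, row in table.iterrows():
            if row["mean"] < CHANCE_LOGLIK:
                below.append(f"{name}={row[key]}")
    return DiagnosticsReport(
        by_trial=by_trial,
        by_dictator=by_dictator,
        by_gpts_quantile=by_q,
        overall=overall,
        below_chance_strata=below,
    )


# ---------------------------------------------------------------------------
# behavioural summaries


def summarize_attributions(trials: pd.DataFrame, n_gpts_groups: int = 4) -> dict:
    """Descriptive summary of attribution ratings in a long trial table.

    Returns mean HI/SI by dictator type, GPTS group and trial index, the
    Spearman correlations between GPTS and each participant's mean HI/SI,
    and the overall HI-SI correlation.  Rank correlations over constant
    columns are reported as missing (NaN).
    """
    by_dictator = (
        trials.groupby("dictator_type")[["hi_rating", "si_rating"]]
        .mean()
        .reset_index()
    )
    per_part = (
        trials.groupby("participant_id")
        .agg(gpts=("gpts", "first"), hi=("hi_rating", "mean"), si=("si_rating", "mean"))
        .reset_index()
    )
    try:
        groups = pd.qcut(per_part["gpts"], q=n_gpts_groups, duplicates="drop")
        by_gpts = (
            per_part.assign(gpts_group=groups)
            .groupby("gpts_group", observed=True)[["hi", "si"]]
            .mean()
            .reset_index()
        )
    except ValueError:  # all-identical GPTS
        by_gpts = pd.DataFrame(columns=["gpts_group", "hi", "si"])
    by_trial = (
        trials.groupby(["dictator_type", "trial"])[["hi_rating", "si_rating"]]
        .mean()
        .reset_index()
    )

    def _rho(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(spearmanr(x, y).statistic)

    return {
        "by_dictator": by_dictator,
        "by_gpts_group": by_gpts,
        "by_trial": by_trial,
        "rho_gpts_hi": _rho(per_part["gpts"], per_part["hi"]),
        "rho_gpts_si": _rho(per_part["gpts"], per_part["si"]),
        "rho_hi_si": _rho(trials["hi_rating"], trials["si_rating"]),
        "per_participant": per_part,
    }


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryReport:
    table: pd.DataFrame  # one row per parameter: rho, bias, rmse
    n: int
    seed: int
    n_failed: int = 0
    merged: pd.DataFrame | None = None


def recovery_table(true_table: pd.DataFrame, fitted_table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter Spearman rho, bias and RMSE of recovered vs true values."""
    merged = true_table.merge(
        fitted_table, on="participant_id", suffixes=("_true", "_fit")
    )
    rows = []
    for name in PARAM_NAMES:
        t = merged[f"{name}_true"].to_numpy(float)
        f = merged[f"{name}_fit"].to_numpy(float)
        rho = float(spearmanr(t, f).statistic) if np.std(t) > 0 and np.std(f) > 0 else float("nan")
        rows.append(
            {
                "param": name,
                "rho": rho,
                "bias": float(np.mean(f - t)),
                "rmse": float(np.sqrt(np.mean((f - t) ** 2))),
            }
        )
    return pd.DataFrame(rows)


def run_recovery(
    spec: PopulationSpec,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    progress: bool = False,
) -> RecoveryReport:
    """Simulate a population from known parameters, refit, and compare."""
    fit_config = fit_config or FitConfig.fast()
    true_table = generate_population(spec, seed)
    sessions = simulate_population(true_table, seed=seed + 1)
    fits = fit_population(sessions, fit_config, progress=progress)
    fitted = results_to_frame(fits).drop(columns=["gpts"])
    table = recovery_table(true_table, fitted)
    merged = true_table.merge(fitted, on="participant_id", suffixes=("_true", "_fit"))
    return RecoveryReport(table=table, n=spec.n, seed=seed, merged=merged)


# ---------------------------------------------------------------------------
# partial-correlation network


@dataclass
class NetworkResult:
    variables: list
    pcorr: pd.DataFrame
    edges: pd.DataFrame  # long edge table with bootstrap CIs
    moderation: pd.DataFrame | None = None
    ridge_used: float = 0.0


def _partial_corr(X: np.ndarray, ridge: float = 0.0):
    """Partial correlations from the inverse covariance of z-scored columns."""
    S = np.cov(X, rowvar=False)
    used = 0.0
    if ridge > 0.0 or np.linalg.cond(S) > 1e10:
        used = max(ridge, 1e-6)
        S = S + used * np.eye(S.shape[0])
    P = np.linalg.inv(S)
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc, used


def parameter_network(
    param_table: pd.DataFrame,
    moderator: str = "gpts",
    n_boot: int = 1000,
    seed: int = 0,
    include_moderation: bool = True,
    ridge: float = 0.0,
) -> NetworkResult:
    """Partial-correlation network over the six parameters plus a moderator.

    All variables are z-scored; edges are partial correlations from the
    inverted covariance matrix, with percentile intervals from ``n_boot``
    row resamples.  If ``include_moderation``, each parameter is also
    regressed on all other parameters, the moderator, and
    moderator-by-parameter interactions; the symmetrised interaction
    coefficients estimate how each edge changes with the moderator.
    """
    variables = [*PARAM_NAMES, moderator]
    if len(param_table) < len(variables) + 1:
        raise ValueError("need at least 8 complete rows for the network")
    X = param_table[variables].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pc, used = _partial_corr(X, ridge)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = X.shape[0]
    boots = np.empty((n_boot, len(variables), len(variables)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], _ = _partial_corr(X[idx], ridge=max(used, 1e-6))
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)

    edge_rows = []
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            edge_rows.append(
                {
                    "var_a": variables[i],
                    "var_b": variables[j],
                    "pcorr": pc[i, j],
                    "ci_lo": lo[i, j],
                    "ci_hi": hi[i, j],
                    "sign": int(np.sign(pc[i, j])),
                    "excludes_zero": bool(lo[i, j] > 0 or hi[i, j] < 0),
                }
            )
    edges = pd.DataFrame(edge_rows)

    moderation = None
    if include_moderation:
        moderation = _moderated_edges(X, variables, moderator)

    return NetworkResult(
        variables=variables,
        pcorr=pd.DataFrame(pc, index=variables, columns=variables),
        edges=edges,
        moderation=moderation,
        ridge_used=used,
    )


def _moderated_edges(X: np.ndarray, variables, moderator: str) -> pd.DataFrame:
    """Nodewise regressions with moderator interactions, symmetrised."""
    m_idx = variables.index(moderator)
    g = X[:, m_idx]
    params = [v for k, v in enumerate(variables) if k != m_idx]
    idx = [k for k in range(len(variables)) if k != m_idx]
    inter = {}
    for a_pos, a in zip(idx, params):
        others = [(k, v) for k, v in zip(idx, params) if k != a_pos]
        cols = [X[:, k] for k, _ in others]
        cols.append(g)
        cols.extend(X[:, k] * g for k, _ in others)
        design = sm.add_constant(np.column_stack(cols))
        fitres = sm.OLS(X[:, a_pos], design).fit()
        base = 1 + len(others) + 1
        for off, (_, b) in enumerate(others):
            inter[(a, b)] = float(fitres.params[base + off])
    rows = []
    for i, a in enumerate(params):
        for b in params[i + 1 :]:
            coef = 0.5 * (inter[(a, b)] + inter[(b, a)])
            rows.append(
                {"var_a": a, "var_b": b, "interaction": coef, "sign": int(np.sign(coef))}
            )
    return pd.DataFrame(rows)


def network_sign_table(result: NetworkResult) -> pd.DataFrame:
    """Compact edge-sign table (sign 0 when the bootstrap CI covers zero)."""
    t = result.edges.copy()
    t["sign"] = np.where(t["excludes_zero"], t["sign"], 0)
    return t[["var_a", "var_b", "sign", "pcorr"]]


def cluster_control(
    n_per_cluster: int = 200,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    n_boot: int = 200,
    reference: NetworkResult | None = None,
    progress: bool = False,
) -> dict:
    """Network-artefact control on cluster-generated pseudo-populations.

    For each density cluster (low, medium, high) a population is generated
    with independent parameters, simulated, refitted, and its
    partial-correlation network estimated.  Edges significant in a cluster
    network *and* matching the reference network's sign are candidate
    fitting artefacts.  Returns per-cluster sign tables and, if a
    reference network is given, an edge-by-edge sign comparison.
    """
    fit_config = fit_config or FitConfig.fast()
    out = {"clusters": {}, "sign_tables": {}, "comparison": None}
    base = np.random.SeedSequence(seed)
    for k, cluster in enumerate(("low", "medium", "high")):
        table = generate_cluster_population(cluster, n_per_cluster, seed + 101 * (k + 1))
        sessions = simulate_population(table, seed=seed + 211 * (k + 1))
        fits = fit_population(sessions, fit_config, progress=progress)
        fitted = results_to_frame(fits)
        net = parameter_network(
            fitted, n_boot=n_boot, seed=seed + 307 * (k + 1), include_moderation=False
        )
        out["clusters"][cluster] = {"true": table, "fitted": fitted, "network": net}
        out["sign_tables"][cluster] = network_sign_table(net)
    if reference is not None:
        ref_signs = network_sign_table(reference).set_index(["var_a", "var_b"])["sign"]
        rows = []
        for cluster, tab in out["sign_tables"].items():
            t = tab.set_index(["var_a", "var_b"])
            for key, ref_sign in ref_signs.items():
                if key not in t.index:
                    continue
                c_sign = int(t.loc[key, "sign"])
                rows.append(
                    {
                        "cluster": cluster,
                        "var_a": key[0],
                        "var_b": key[1],
                        "reference_sign": int(ref_sign),
                        "cluster_sign": c_sign,
                        "artefact_candidate": bool(
                            c_sign != 0 and c_sign == ref_sign
                        ),
                    }
                )
        out["comparison"] = pd.DataFrame(rows)
    return out
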