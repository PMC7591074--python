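"""Pseudo-population generator with paranoia-coupled observer parameters.

This module creates parameter tables with the statistical structure the
downstream analysis assumes, so the whole pipeline (simulate, fit,
summarise, network) is exercisable without any real participant data.
Pre-existing paranoia is an integer GPTS total on 32-160 with a
right-skewed marginal (most of the general population scores low); each
observer parameter is a linear function of the z-scored GPTS on its link
scale (logit for the bounded parameters, log for the scales) plus Gaussian
noise.  The default coupling directions and magnitudes mirror the
parameter-paranoia associations the model is meant to exhibit: paranoia
raises policy uncertainty most strongly, raises the prior uncertainties
mildly, raises the harmful-intent prior mode, and leaves the learning rate
uncoupled.  These are generator settings that define a study condition,
not estimates.

A second generator draws the cluster populations used as the
network-artefact control: prior modes confined to low-, medium- or
high-density boxes with the remaining parameters from one shared dense
range, so that any parameter correlations recovered after refitting such
data must be artefacts of the fitting procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_model import PARAM_NAMES

__all__ = ["PopulationSpec", "generate_gpts", "generate_population", "generate_cluster_population"]

_LOGIT_PARAMS = ("pHI0", "pSI0", "eta")
_PARAM_CLIP = {
    "pHI0": (0.01, 0.99),
    "pSI0": (0.01, 0.99),
    "uHI0": (0.05, 20.0),
    "uSI0": (0.05, 20.0),
    "u_pi": (0.05, 20.0),
    "eta": (0.0, 1.0),
}

#: pHI0 / pSI0 sampling boxes for the three density clusters of the
#: artefact control.
CLUSTER_RANGES = {
    "high": {"pHI0": (0.01, 0.98), "pSI0": (0.80, 0.98)},
    "medium": {"pHI0": (0.25, 0.50), "pSI0": (0.50, 0.75)},
    "low": {"pHI0": (0.01, 0.20), "pSI0": (0.01, 0.20)},
}

#: Shared dense ranges for the four non-clustered parameters.
_SHARED_DENSE = {
    "uHI0": (0.3, 3.0),
    "uSI0": (0.3, 3.0),
    "u_pi": (0.5, 4.0),
    "eta": (0.1, 0.9),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Study-condition settings for one synthetic population.

    ``intercepts``, ``couplings`` and ``noise_sd`` are all on each
    parameter's link scale; couplings multiply the z-scored GPTS total.
    """

    n: int = 200
    gpts_beta: tuple = (1.2, 4.0)
    intercepts: dict = field(
        default_factory=lambda: {
            "pHI0": logit(0.30),
            "uHI0": np.log(1.0),
            "pSI0": logit(0.60),
            "uSI0": np.log(1.0),
            "u_pi": np.log(1.5),
            "eta": logit(0.30),
        }
    )
    couplings: dict = field(
        default_factory=lambda: {
            "pHI0": 0.11,
            "uHI0": 0.04,
            "pSI0": 0.0,
            "uSI0": 0.03,
            "u_pi": 0.09,
            "eta": 0.0,
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "pHI0": 0.40,
            "uHI0": 0.30,
            "pSI0": 0.40,
            "uSI0": 0.30,
            "u_pi": 0.30,
            "eta": 0.60,
        }
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be at least 1")
        for d in (self.intercepts, self.couplings, self.noise_sd):
            if set(d) != set(PARAM_NAMES):
                raise ValueError("spec dicts must cover exactly the six parameters")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError("noise scales must be non-negative")


def generate_gpts(n: int, rng: np.random.Generator, beta=(1.2, 4.0)) -> np.ndarray:
    """Right-skewed integer GPTS totals on 32..160: ``32 + 128 Beta(a, b)``."""
    raw = 32 + np.round(128 * rng.beta(beta[0], beta[1], size=n))
    return np.clip(raw, 32, 160).astype(int)


def generate_population(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Draw GPTS scores and the coupled six-parameter table.

    Returns a frame with ``participant_id``, ``gpts`` and the six
    parameters, clipped to the fitting bounds.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gpts = generate_gpts(spec.n, rng, spec.gpts_beta)
    sd = gpts.std()
    z = (gpts - gpts.mean()) / (sd if sd > 0 else 1.0)

    table = {"participant_id": [f"P{i:04d}" for i in range(spec.n)], "gpts": gpts}
    for name in PARAM_NAMES:
        link = (
            spec.intercepts[name]
            + spec.couplings[name] * z
            + spec.noise_sd[name] * rng.standard_normal(spec.n)
        )
        nat = expit(link) if name in _LOGIT_PARAMS else np.exp(link)
        lo, hi = _PARAM_CLIP[name]
        if spec.noise_sd[name] == 0.0 and spec.couplings[name] == 0.0:
            mid = nat if np.isscalar(nat) else nat[0]
            if mid <= lo or mid >= hi:
                import warnings

                warnings.warn(f"degenerate spec pins {name} at a bound")
        table[name] = np.clip(nat, lo, hi)
    return pd.DataFrame(table)


def generate_cluster_population(cluster: str, n: int, seed: int) -> pd.DataFrame:
    """Parameter table for one density cluster of the artefact control.

    ``pHI0`` and ``pSI0`` are uniform within the cluster's box; the other
    four parameters come from a single shared dense range (log-uniform for
    the scales, uniform for ``eta``), identical across clusters.
    """
    if cluster not in CLUSTER_RANGES:
        raise ValueError(f"unknown cluster {cluster!r}; expected one of {sorted(CLUSTER_RANGES)}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    box = CLUSTER_RANGES[cluster]
    table = {
        "participant_id": [f"{cluster[0].upper()}{i:04d}" for i in range(n)],
        "gpts": generate_gpts(n, rng),
    }
    for name in ("pHI0", "pSI0"):
        lo, hi = box[name]
        table[name] = rng.uniform(lo, hi, size=n)
    for name in ("uHI0", "uSI0", "u_pi"):
        lo, hi = _SHARED_DENSE[name]
        table[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lo, hi = _SHARED_DENSE["eta"]
    table["eta"] = rng.uniform(lo, hi, size=n)
    cols = ["participant_id", "gpts", *PARAM_NAMES]
    return pd.DataFrame(table)[cols]
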