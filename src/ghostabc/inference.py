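"""Rejection ABC on deep-network summary statistics.

Reference simulations carry an SS-DL vector (model-membership
probabilities, or a scalar parameter prediction) and a label or parameter
value. Observation and references are compared by Euclidean distance;
acceptance is by an absolute threshold epsilon or by a distance quantile.
Accepted labels give model posterior probabilities; accepted parameter
values give posterior means and equal-tailed 95% credible intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ABCConfig",
    "PosteriorResult",
    "abc_reject",
    "model_posterior",
    "parameter_posterior",
    "bayes_factor",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ABCConfig:
    """Acceptance rule: absolute ``epsilon`` or acceptance quantile ``q``."""

    epsilon: float | None = None
    q: float | None = 0.005

    def __post_init__(self) -> None:
        if (self.epsilon is None) == (self.q is None):
            raise ValueError("set exactly one of epsilon or q")
        if self.q is not None and not 0 < self.q <= 1:
            raise ValueError("acceptance quantile q must be in (0, 1]")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class PosteriorResult:
    """Posterior summary of accepted parameter draws."""

    parameter: str
    accepted: np.ndarray
    mean: float
    ci_low: float
    ci_high: float


def abc_reject(
    ss_obs: np.ndarray, reference_ss: np.ndarray, cfg: ABCConfig
) -> np.ndarray:
    """Indices of reference rows accepted for an observed SS-DL.

    Quantile mode accepts the ceil(q*N) nearest rows; rows tied with the
    boundary distance are all included. Epsilon mode accepts distances
    <= epsilon and errors if that set is empty.
    """
    obs = np.asarray(ss_obs, dtype=float).ravel()
    ref = np.atleast_2d(np.asarray(reference_ss, dtype=float))
    if ref.shape[0] == 0:
        raise ValueError("reference table is empty")
    if ref.shape[1] != obs.size:
        raise ValueError(
            f"SS-DL dimension mismatch: observation {obs.size}, reference {ref.shape[1]}"
        )
    dist = np.sqrt(((ref - obs) ** 2).sum(axis=1))
    if cfg.epsilon is not None:
        idx = np.flatnonzero(dist <= cfg.epsilon)
        if idx.size == 0:
            raise ValueError(
                "no reference simulation within epsilon; consider quantile mode"
            )
        return idx
    k = math.ceil(cfg.q * ref.shape[0])
    threshold = np.partition(dist, k - 1)[k - 1]
    return np.flatnonzero(dist <= threshold)


def model_posterior(
    accepted_labels: np.ndarray, model_ids: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Posterior probability of each model: its accepted fraction."""
    labels = np.asarray(accepted_labels)
    if labels.size == 0:
        raise ValueError("no accepted simulations")
    if model_ids is None:
        model_ids = tuple(sorted(np.unique(labels)))
    return {m: float((labels == m).sum() / labels.size) for m in model_ids}


def parameter_posterior(
    accepted_values: np.ndarray, parameter: str = ""
) -> PosteriorResult:
    """Mean and equal-tailed 95% CI of the accepted parameter values.

    Percentiles use linear interpolation between order statistics so the
    interval is bit-reproducible. A single accepted value yields a
    degenerate interval (logged as a warning).
    """
    vals = np.asarray(accepted_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no accepted simulations")
    if vals.size == 1:
        log.warning("single accepted value; credible interval is degenerate")
    lo, hi = np.percentile(vals, [2.5, 97.5], method="linear")
    return PosteriorResult(
        parameter=parameter,
        accepted=vals,
        mean=float(vals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def bayes_factor(
    posterior: dict[str, float], prior: dict[str, float] | None = None
) -> dict[tuple[str, str], float]:
    """Pairwise Bayes factors K(i, j) = [P(i)/P(j)] * [pi(j)/pi(i)].

    Equal model priors by default. A zero denominator yields ``inf``.
    """
    models = list(posterior)
    if prior is None:
        prior = {m: 1.0 / len(models) for m in models}
    out: dict[tuple[str, str], float] = {}
    for i in models:
        for j in models:
            if i == j:
                continue
            num = posterior[i] * prior[j]
            den = posterior[j] * prior[i]
            out[(i, j)] = float("inf") if den == 0 else num / den
    return out
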