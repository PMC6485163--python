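"""Self-consistency checks: model-choice confusion matrix and factor-2.

Both procedures treat simulated data with known truth as observed data and
push it through the full inference stack. The confusion matrix reports, per
generating model, the posterior support each candidate model receives; the
factor-2 statistic reports how often a posterior-mean estimate falls within
50%-200% of the true parameter value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .inference import ABCConfig, abc_reject, model_posterior

__all__ = [
    "ConfusionMatrix",
    "Factor2Report",
    "confusion_matrix",
    "factor2",
    "parameter_recovery_study",
]


@dataclass
class ConfusionMatrix:
    """Row i: data generated under model i; column j: support for model j."""

    matrix: np.ndarray
    model_ids: tuple[str, ...]
    n_pseudo: int
    mode: str  # "mean_posterior" | "assignment"

    def diagonal(self) -> dict[str, float]:
        return {m: float(self.matrix[i, i]) for i, m in enumerate(self.model_ids)}

    def row(self, model_id: str) -> dict[str, float]:
        i = self.model_ids.index(model_id)
        return {m: float(self.matrix[i, j]) for j, m in enumerate(self.model_ids)}


def confusion_matrix(
    simulate_ss: Callable[[str, int], np.ndarray],
    reference_ss: np.ndarray,
    reference_labels: np.ndarray,
    cfg: ABCConfig,
    *,
    model_ids: tuple[str, ...] = ("A", "B", "C", "D", "E", "F"),
    n_pseudo: int = 100,
    rng_seed: int = 0,
    mode: str = "mean_posterior",
) -> ConfusionMatrix:
    """Confusion matrix of the model-choice ABC.

    ``simulate_ss(model_id, seed)`` must produce the SS-DL of one fresh
    pseudo-observed dataset generated under ``model_id`` (simulation, noise
    injection and network prediction included). For each generating model,
    ``n_pseudo`` pseudo-observations are pushed through rejection ABC
    against the reference table. ``mode="mean_posterior"`` averages the
    posterior probability vectors; ``mode="assignment"`` tallies the
    frequency with which each model attains the maximum posterior.
    """
    if mode not in ("mean_posterior", "assignment"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(1, 2**31 - 1, size=(len(model_ids), n_pseudo))
    mat = np.zeros((len(model_ids), len(model_ids)))
    for i, true_model in enumerate(model_ids):
        for r in range(n_pseudo):
            ss = simulate_ss(true_model, int(seeds[i, r]))
            acc = abc_reject(ss, reference_ss, cfg)
            post = model_posterior(reference_labels[acc], model_ids)
            vec = np.array([post[m] for m in model_ids])
            if mode == "mean_posterior":
                mat[i] += vec
            else:
                mat[i, int(np.argmax(vec))] += 1
        mat[i] /= n_pseudo
    return ConfusionMatrix(mat, tuple(model_ids), n_pseudo, mode)


@dataclass
class Factor2Report:
    """Fraction of replicates whose estimate is within [0.5, 2] x truth."""

    parameter: str
    n_replicates: int
    n_within: int
    n_excluded_zero_truth: int

    @property
    def fraction(self) -> float:
        if self.n_replicates == 0:
            raise ValueError("no usable replicates")
        return self.n_within / self.n_replicates


def factor2(
    truths: np.ndarray, estimates: np.ndarray, parameter: str = ""
) -> Factor2Report:
    """The factor-2 recovery statistic, boundaries inclusive.

    A pair counts as recovered when the estimate lies in
    ``[0.5 * |truth|, 2 * |truth|]`` on the truth's side of zero (signed
    rule; published parameters are all positive). Pairs with truth exactly
    zero are excluded and counted separately, the interval being undefined
    there.
    """
    t = np.asarray(truths, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape:
        raise ValueError("truths and estimates must have equal length")
    nonzero = t != 0
    t_nz, e_nz = t[nonzero], e[nonzero]
    signed = e_nz * np.sign(t_nz)
    within = (signed >= 0.5 * np.abs(t_nz)) & (signed <= 2.0 * np.abs(t_nz))
    return Factor2Report(
        parameter=parameter,
        n_replicates=int(nonzero.sum()),
        n_within=int(within.sum()),
        n_excluded_zero_truth=int((~nonzero).sum()),
    )


def parameter_recovery_study(
    parameter: str,
    draw_truth_and_ss: Callable[[int], tuple[float, np.ndarray]],
    reference_ss: np.ndarray,
    reference_values: np.ndarray,
    cfg: ABCConfig,
    *,
    n_replicates: int = 100,
    rng_seed: int = 0,
) -> Factor2Report:
    """Factor-2 study of a parameter estimator over fresh replicates.

    ``draw_truth_and_ss(seed)`` must draw a parameter value from its prior,
    simulate a pseudo-observed dataset under it, and return
    ``(truth, ss_dl)``. Each replicate's posterior mean over the accepted
    reference values is compared with its truth.
    """
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(1, 2**31 - 1, size=n_replicates)
    truths = np.empty(n_replicates)
    means = np.empty(n_replicates)
    for r in range(n_replicates):
        truth, ss = draw_truth_and_ss(int(seeds[r]))
        acc = abc_reject(np.atleast_1d(ss), reference_ss, cfg)
        truths[r] = truth
        means[r] = float(np.asarray(reference_values)[acc].mean())
    return factor2(truths, means, parameter)
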