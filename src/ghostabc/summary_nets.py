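"""Deep-network summary statistics (SS-DL) for ABC.

An ensemble of 10 independently initialised feed-forward networks with four
hidden layers maps a flattened, normalised jSFS either to the vector of
model-membership probabilities (classification) or to a scalar parameter
value (regression). The ensemble average of the member predictions is the
summary statistic consumed by rejection ABC. For parameter estimation a
single member is selected per parameter by the Spearman correlation between
its predictions and the truth on held-out validation simulations.

Networks are scikit-learn multilayer perceptrons; inputs are standardised
per cell with training-set statistics, regression targets are standardised
internally and predictions returned on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.stats import spearmanr
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SummaryEnsemble",
    "train_classifier",
    "train_parameter_regressors",
    "predict_ss",
    "select_network_by_spearman",
]

#: Full-scale training-set sizes, echoed by configuration helpers.
FULL_SCALE = {
    "classifier_sims_per_model": 15_000,
    "classifier_sims_total": 90_000,
    "reference_sims_per_model": 150_000,
    "regressor_sims_per_parameter": 20_000,
}

DEFAULT_HIDDEN = (64, 32, 16, 8)


@dataclass
class SummaryEnsemble:
    """A trained ensemble whose averaged prediction is the SS-DL."""

    members: list[Pipeline]
    task: str  # "classify" | "regress"
    input_dim: int
    classes: np.ndarray | None = None
    target_mean: float = 0.0
    target_scale: float = 1.0
    training_log: list[dict] = field(default_factory=list)
    selected_member: int | None = None

    @property
    def n_networks(self) -> int:
        return len(self.members)

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """Per-member predictions, shape (n_networks, n_rows, n_out)."""
        X = self._check(X)
        if self.task == "classify":
            return np.stack([m.predict_proba(X) for m in self.members])
        preds = np.stack([m.predict(X) for m in self.members])
        return (preds * self.target_scale + self.target_mean)[..., None]

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {X.shape[1]} != training dimension {self.input_dim}"
            )
        return X

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "SummaryEnsemble":
        return joblib.load(path)


def _make_member(task: str, hidden: tuple[int, ...], seed: int, max_iter: int) -> Pipeline:
    kw = dict(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        random_state=seed,
        max_iter=max_iter,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=10,
    )
    net = MLPClassifier(**kw) if task == "classify" else MLPRegressor(**kw)
    return Pipeline([("scale", StandardScaler()), ("net", net)])


def train_classifier(
    X: np.ndarray,
    labels: np.ndarray,
    *,
    n_networks: int = 10,
    hidden: tuple[int, ...] = DEFAULT_HIDDEN,
    rng_seed: int = 0,
    max_iter: int = 200,
) -> SummaryEnsemble:
    """Train the model-choice ensemble on labelled jSFS vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[1] == 0:
        raise ValueError("input dimension is 0")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to train a classifier")
    seeds = np.random.default_rng(rng_seed).integers(0, 2**31 - 1, size=n_networks)
    members, logrows = [], []
    for i, s in enumerate(seeds):
        m = _make_member("classify", hidden, int(s), max_iter)
        m.fit(X, labels)
        net = m.named_steps["net"]
        logrows.append(
            {"member": i, "seed": int(s), "n_iter": net.n_iter_,
             "train_score": float(m.score(X, labels))}
        )
        members.append(m)
    return SummaryEnsemble(
        members=members,
        task="classify",
        input_dim=X.shape[1],
        classes=members[0].named_steps["net"].classes_,
        training_log=logrows,
    )


def train_parameter_regressors(
    X: np.ndarray,
    target: np.ndarray,
    *,
    n_networks: int = 10,
    hidden: tuple[int, ...] = DEFAULT_HIDDEN,
    rng_seed: int = 0,
    max_iter: int = 200,
) -> SummaryEnsemble:
    """Train the per-parameter regression ensemble on jSFS vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    target = np.asarray(target, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("input dimension is 0")
    mu = float(target.mean())
    sd = float(target.std())
    # A constant target has zero variance: the regression function is the
    # constant itself, so the stored scale of 0 pins predictions to mu.
    scale = sd
    z = (target - mu) / (sd if sd > 0 else 1.0)
    seeds = np.random.default_rng(rng_seed).integers(0, 2**31 - 1, size=n_networks)
    members, logrows = [], []
    for i, s in enumerate(seeds):
        m = _make_member("regress", hidden, int(s), max_iter)
        m.fit(X, z)
        net = m.named_steps["net"]
        logrows.append({"member": i, "seed": int(s), "n_iter": net.n_iter_})
        members.append(m)
    return SummaryEnsemble(
        members=members,
        task="regress",
        input_dim=X.shape[1],
        target_mean=mu,
        target_scale=scale,
        training_log=logrows,
    )


def predict_ss(ens: SummaryEnsemble, X: np.ndarray) -> np.ndarray:
    """The SS-DL: averaged member predictions (or the selected member's).

    Classification returns one probability vector per row (rows sum to 1);
    regression returns one scalar per row. If ``ens.selected_member`` is
    set (Spearman-selected parameter network), only that member is used.
    """
    preds = ens.member_predictions(X)
    if ens.selected_member is not None:
        out = preds[ens.selected_member]
    else:
        out = preds.mean(axis=0)
    if ens.task == "regress":
        return out[:, 0]
    return out


def select_network_by_spearman(
    ens: SummaryEnsemble, X_val: np.ndarray, truth: np.ndarray
) -> int:
    """Pick the member whose predictions best rank-correlate with the truth.

    Returns the argmax of Spearman's rho over members (ties broken by
    lowest index) and records it on the ensemble so that subsequent
    ``predict_ss`` calls use that member alone.
    """
    if ens.task != "regress":
        raise ValueError("network selection applies to parameter regressors")
    truth = np.asarray(truth, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("validation truths must take at least two distinct values")
    preds = ens.member_predictions(X_val)[..., 0]
    rhos = np.empty(ens.n_networks)
    for i in range(ens.n_networks):
        if np.allclose(preds[i], preds[i][0]):
            rhos[i] = np.nan
        else:
            rhos[i] = spearmanr(preds[i], truth).statistic
    if np.isnan(rhos).all():
        raise ValueError("all members produce constant predictions; rho undefined")
    best = int(np.nanargmax(rhos))
    ens.selected_member = best
    return best
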