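"""End-to-end ABC-DL studies at configurable problem sizes.

Ties the stages together: prior draws -> fragmented coalescent simulation
-> jSFS -> noise injection -> network ensemble -> rejection ABC -> model
posteriors / parameter posteriors, plus the two self-consistency studies
(confusion matrix, factor-2 parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import ABCConfig
from .models import MODEL_IDS, default_priors, draw_parameters
from .sfs import JointSFS, inject_noise
from .simulate import FragmentSet, desk_fragments
from .summary_nets import (
    SummaryEnsemble,
    predict_ss,
    select_network_by_spearman,
    train_classifier,
    train_parameter_regressors,
)
from .synthetic import make_jsfs_bank, noise_spectrum, simulate_jsfs
from .validation import (
    ConfusionMatrix,
    Factor2Report,
    confusion_matrix,
    parameter_recovery_study,
)

__all__ = [
    "StudyConfig",
    "DESK",
    "MINI",
    "ModelChoiceStack",
    "build_model_choice_stack",
    "run_confusion_study",
    "ParameterStack",
    "build_parameter_stack",
    "run_factor2_study",
]


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and inference settings of one ABC-DL study."""

    fragments: FragmentSet = field(default_factory=desk_fragments)
    model_ids: tuple[str, ...] = MODEL_IDS
    n_train_per_model: int = 500
    n_reference_per_model: int = 500
    n_pseudo_per_model: int = 20
    n_regressor_train: int = 500
    n_regressor_reference: int = 500
    n_spearman_validation: int = 60
    n_networks: int = 10
    hidden: tuple[int, ...] = (64, 32, 16, 8)
    max_iter: int = 200
    lam: float = 0.5
    abc: ABCConfig = field(default_factory=lambda: ABCConfig(q=0.05))


#: Desk preset: 300 fragments x 20 kbp, ~500 training sims per model.
DESK = StudyConfig()

#: Reduced preset used by the shipped acceptance runs (see docs/methods.md).
MINI = StudyConfig(
    fragments=desk_fragments(100, 20_000),
    n_train_per_model=150,
    n_reference_per_model=150,
    n_pseudo_per_model=20,
    n_regressor_train=300,
    n_regressor_reference=300,
    n_spearman_validation=50,
    max_iter=120,
)


@dataclass
class ModelChoiceStack:
    """Trained classifier ensemble plus its SS-DL reference table."""

    cfg: StudyConfig
    noise: JointSFS
    ensemble: SummaryEnsemble
    reference_ss: np.ndarray
    reference_labels: np.ndarray

    def pseudo_observed_ss(self, model_id: str, rng_seed: int) -> np.ndarray:
        """Simulate one noise-injected pseudo-observation and predict its SS-DL."""
        rng = np.random.default_rng(rng_seed)
        s_draw, s_sim, s_noise = rng.integers(1, 2**31 - 1, size=3)
        params = draw_parameters(default_priors(model_id), model_id, int(s_draw))
        sim = simulate_jsfs(model_id, params, self.cfg.fragments, int(s_sim))
        noisy = inject_noise(sim, self.noise, lam=self.cfg.lam, rng_seed=int(s_noise))
        return predict_ss(self.ensemble, noisy.normalize().flatten())[0]


def build_model_choice_stack(cfg: StudyConfig, rng_seed: int) -> ModelChoiceStack:
    """Simulate training + reference banks and train the classifier ensemble."""
    rng = np.random.default_rng(rng_seed)
    s_noise, s_bank, s_train = rng.integers(1, 2**31 - 1, size=3)
    noise = noise_spectrum(cfg.fragments, int(s_noise))
    n = cfg.n_train_per_model + cfg.n_reference_per_model
    bank = make_jsfs_bank(
        cfg.model_ids,
        n,
        cfg.fragments,
        int(s_bank),
        noise=noise,
        lam=cfg.lam,
        partition_counts={
            "train": cfg.n_train_per_model,
            "reference": cfg.n_reference_per_model,
        },
    )
    tr = bank.rows("train")
    ens = train_classifier(
        bank.X[tr],
        bank.labels[tr],
        n_networks=cfg.n_networks,
        hidden=cfg.hidden,
        rng_seed=int(s_train),
        max_iter=cfg.max_iter,
    )
    ref = bank.rows("reference")
    return ModelChoiceStack(
        cfg=cfg,
        noise=noise,
        ensemble=ens,
        reference_ss=predict_ss(ens, bank.X[ref]),
        reference_labels=bank.labels[ref],
    )


def run_confusion_study(
    stack: ModelChoiceStack, rng_seed: int, mode: str = "mean_posterior"
) -> ConfusionMatrix:
    """The confusion-matrix self-consistency check on a trained stack."""
    return confusion_matrix(
        stack.pseudo_observed_ss,
        stack.reference_ss,
        stack.reference_labels,
        stack.cfg.abc,
        model_ids=stack.cfg.model_ids,
        n_pseudo=stack.cfg.n_pseudo_per_model,
        rng_seed=rng_seed,
        mode=mode,
    )


@dataclass
class ParameterStack:
    """Spearman-selected regressor plus its SS-DL reference table."""

    cfg: StudyConfig
    model_id: str
    parameter: str
    noise: JointSFS
    ensemble: SummaryEnsemble
    selected_network: int
    reference_ss: np.ndarray
    reference_values: np.ndarray

    def pseudo_observed(self, rng_seed: int) -> tuple[float, np.ndarray]:
        rng = np.random.default_rng(rng_seed)
        s_draw, s_sim, s_noise = rng.integers(1, 2**31 - 1, size=3)
        params = draw_parameters(
            default_priors(self.model_id), self.model_id, int(s_draw)
        )
        sim = simulate_jsfs(self.model_id, params, self.cfg.fragments, int(s_sim))
        noisy = inject_noise(sim, self.noise, lam=self.cfg.lam, rng_seed=int(s_noise))
        ss = predict_ss(self.ensemble, noisy.normalize().flatten())
        return float(params[self.parameter]), ss


def build_parameter_stack(
    cfg: StudyConfig, parameter: str, rng_seed: int, model_id: str = "B"
) -> ParameterStack:
    """Train the per-parameter regression ensemble under one model.

    Trains on ``n_regressor_train`` simulations, selects the member with
    the highest Spearman correlation on ``n_spearman_validation`` held-out
    simulations, and predicts SS-DL for ``n_regressor_reference`` fresh
    reference simulations.
    """
    rng = np.random.default_rng(rng_seed)
    s_noise, s_bank, s_train = rng.integers(1, 2**31 - 1, size=3)
    noise = noise_spectrum(cfg.fragments, int(s_noise))
    n = cfg.n_regressor_train + cfg.n_spearman_validation + cfg.n_regressor_reference
    bank = make_jsfs_bank(
        (model_id,),
        n,
        cfg.fragments,
        int(s_bank),
        noise=noise,
        lam=cfg.lam,
        partition_counts={
            "train": cfg.n_regressor_train,
            "validation": cfg.n_spearman_validation,
            "reference": cfg.n_regressor_reference,
        },
    )
    target = bank.param_column(parameter)
    tr, va, ref = bank.rows("train"), bank.rows("validation"), bank.rows("reference")
    ens = train_parameter_regressors(
        bank.X[tr],
        target[tr],
        n_networks=cfg.n_networks,
        hidden=cfg.hidden,
        rng_seed=int(s_train),
        max_iter=cfg.max_iter,
    )
    best = select_network_by_spearman(ens, bank.X[va], target[va])
    return ParameterStack(
        cfg=cfg,
        model_id=model_id,
        parameter=parameter,
        noise=noise,
        ensemble=ens,
        selected_network=best,
        reference_ss=predict_ss(ens, bank.X[ref])[:, None],
        reference_values=target[ref],
    )


def run_factor2_study(
    stack: ParameterStack, n_replicates: int, rng_seed: int
) -> Factor2Report:
    """Factor-2 recovery of a parameter's posterior mean over fresh replicates."""
    return parameter_recovery_study(
        stack.parameter,
        stack.pseudo_observed,
        stack.reference_ss,
        stack.reference_values,
        stack.cfg.abc,
        n_replicates=n_replicates,
        rng_seed=rng_seed,
    )
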