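"""Tiny end-to-end model choice: simulate, train networks, run rejection ABC.

A toy-sized run (minutes): banks of noise-injected jSFS simulations for the
six models, an ensemble of networks whose averaged class probabilities are
the summary statistic (SS-DL), and rejection ABC of one pseudo-observed
dataset. At this problem size the posterior is diffuse — see
docs/methods.md for why model discrimination needs genome-scale data.
"""

from ghostabc.inference import ABCConfig, abc_reject, bayes_factor, model_posterior
from ghostabc.pipeline import StudyConfig, build_model_choice_stack
from ghostabc.simulate import desk_fragments

cfg = StudyConfig(
    fragments=desk_fragments(30, 10_000),
    n_train_per_model=30,
    n_reference_per_model=30,
    n_networks=3,
    max_iter=60,
    abc=ABCConfig(q=0.2),
)
stack = build_model_choice_stack(cfg, rng_seed=5)
ss_obs = stack.pseudo_observed_ss("B", rng_seed=6)  # truth: model B
accepted = abc_reject(ss_obs, stack.reference_ss, cfg.abc)
post = model_posterior(stack.reference_labels[accepted], cfg.model_ids)
print("posterior over models for a pseudo-observation from model B:")
for m, p in post.items():
    print(f"  P(model={m} | data) = {p:.3f}")
best = max(post, key=post.get)
second = max((m for m in post if m != best), key=post.get)
print(f"Bayes factor {best} vs {second}: "
      f"{bayes_factor(post)[(best, second)]:.1f}")
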