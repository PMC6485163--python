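"""Factor-2 self-consistency check of a parameter estimator (toy scale).

Trains a small regression ensemble for the XAf-AMH split time under model
B, selects the best member by Spearman correlation on held-out simulations,
and measures how often the ABC posterior mean lands within 50%-200% of the
true value over fresh pseudo-observed replicates.
"""

from ghostabc.inference import ABCConfig
from ghostabc.pipeline import StudyConfig, build_parameter_stack, run_factor2_study
from ghostabc.simulate import desk_fragments

cfg = StudyConfig(
    fragments=desk_fragments(30, 10_000),
    n_regressor_train=60,
    n_regressor_reference=60,
    n_spearman_validation=20,
    n_networks=3,
    max_iter=60,
    abc=ABCConfig(q=0.1),
)
stack = build_parameter_stack(cfg, "tAMH_XAf", rng_seed=3)
print(f"Spearman-selected network: member {stack.selected_network}")
report = run_factor2_study(stack, n_replicates=30, rng_seed=4)
print(f"factor-2 fraction over {report.n_replicates} replicates: "
      f"{100*report.fraction:.0f}%")
# Full-scale analyses report ~96% for this split time; a wide-prior
# posterior mean alone already covers much of the factor-2 band.
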