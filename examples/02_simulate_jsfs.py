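"""Simulate the seven-genome panel and tally its joint SFS.

Simulates 100 independent 20-kbp fragments under model B, tallies the
7-dimensional unfolded joint site frequency spectrum (3 dosage states per
diploid genome) and blends in a noise spectrum the way training simulations
are prepared for the networks.
"""

from ghostabc import build_model, compute_jsfs, default_priors, draw_parameters, \
    desk_fragments, inject_noise, simulate_fragments
from ghostabc.synthetic import noise_spectrum

fragments = desk_fragments(100, 20_000)
params = draw_parameters(default_priors("B"), "B", rng_seed=7)
geno = simulate_fragments(build_model("B", params), fragments, rng_seed=8)
print(f"simulated {geno.n_sites} segregating sites on "
      f"{fragments.n_fragments} fragments ({fragments.total_length/1e6:.0f} Mbp)")

jsfs = compute_jsfs(geno)
print(f"jSFS: {jsfs.counts.shape} tensor, {jsfs.n_sites:.0f} tallied sites")
noise = noise_spectrum(fragments, rng_seed=99)
noisy = inject_noise(jsfs, noise, lam=0.5, rng_seed=9)
print(f"after 50/50 noise injection: {noisy.n_sites:.0f} resampled sites")
# The normalised, flattened tensor (2187 cells) is the network input.
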