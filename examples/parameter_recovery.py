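"""Validating the simulator against its own analytic probabilities.

With every node infected, each edge is an independent Bernoulli trial per
single-step replicate, so the empirical event frequency on each edge must
recover the analytic p_ij within binomial error.
"""

from seednet import estimate_rate, recovery_experiment
from seednet.synthetic import generate_network, SyntheticNetworkSpec
from seednet import build_network, resolve_duplicates

spec = SyntheticNetworkSpec(n_countries=20, n_hubs=3, density=0.15,
                            frac_import_only=0.3, rng_seed=9)
syn = generate_network(spec)
rate = estimate_rate(3, 199.0, 5)

report = recovery_experiment(syn.truth, rate, n_reps=3000, rng_seed=0)
print(f"{report.n_edges} edges, {report.n_reps} single-step replicates")
print(f"max |empirical - analytic| edge probability: "
      f"{report.max_abs_deviation:.4f}")
print(f"edges within 3 binomial SE: "
      f"{report.n_edges_within_3se}/{report.n_edges} "
      f"(all: {report.all_within_3se})")
print("  the simulator's edge-level law matches the probability model "
      "it was built from")
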