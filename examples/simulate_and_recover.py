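"""Simulate rallies and recover the generating transition matrix.

Generates a synthetic tournament from the packaged matrix defaults,
re-derives every rally's state sequence from its six-criteria record,
pools the transition counts and checks how closely the estimate
recovers the generating probabilities.
"""

from efos import SimulationConfig, recover_parameters, simulate_dataset

config = SimulationConfig(n_matches=50, rallies_per_match=200, seed=42)
dataset = simulate_dataset(config)
print(f"simulated {len(dataset.records)} rallies in {config.n_matches} matches")

estimate, max_dev = recover_parameters(dataset)
print("\nEstimated serve row (probabilities):")
print(estimate.row("SER").dropna().round(4).to_string())
print(f"\nmax |estimated - generating| over defined cells: {max_dev:.4f}")

# Reading: at 10,000 rallies the pooled estimate agrees with the
# generating matrix to about the binomial standard error of the rarest
# row; deviations shrink as 1/sqrt(n).
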