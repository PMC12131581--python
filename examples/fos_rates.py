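"""FOS winning and usage rates by category.

Simulates rallies from the packaged defaults and computes the rate
battery: direct winning rate of the FOS, overall winning rate across
the FOS..FOS+3 window (credited to the FOS player), usage rates, and
the two-consecutive-attacks connection rate (FOS and FOS+2 pooled).
"""

from efos import SimulationConfig, rate_table, simulate_dataset
from efos.model import derive_state_sequence

dataset = simulate_dataset(SimulationConfig(n_matches=30, rallies_per_match=150, seed=3))
sequences = [derive_state_sequence(r) for r in dataset.records]

table = rate_table(sequences)
pick = table[table["scope"].isin(["fos_direct_win", "fos_overall_win", "fos_usage",
                                  "connection_win"])]
print(pick.round(4).to_string(index=False))

# Reading: the direct winning rate of each category equals the matrix
# cell P(FOS#i -> P) by construction; the overall window rate is always
# at least as large because opponent errors on FOS+1/FOS+3 also score
# for the FOS player.  Usage rates divide by the full rally sample.
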