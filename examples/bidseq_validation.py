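"""Validate sites and estimate stoichiometry with targeted bisulfite data.

Bisulfite chemistry converts a pseudouridine into a 1-2 nt deletion whose
frequency is roughly proportional to the modification stoichiometry.  This
example simulates pileups for a wild-type and a knockout strain over three
sites of different stoichiometry, computes per-position deletion-rate
traces, and summarizes each site as the maximum rate within +/-2 nt.
"""

import psistop as ps

sites = [30, 90, 150]
stoichiometry = {30: 0.95, 90: 0.5, 150: 0.15}
depth = 10_000

wt = ps.deletion_trace(ps.simulate_bidseq_pileup(
    sites, stoichiometry, depth, seed=7, length=200))
ko = ps.deletion_trace(ps.simulate_bidseq_pileup(
    sites, {s: 0.0 for s in sites}, depth, seed=8, length=200))

table = ps.compare_conditions({"WT": wt, "knockout": ko}, sites)
print(table.to_string(index=False))

print("\nWT deletion rates track the planted stoichiometries (x the "
      "simulator's proportionality constant, 0.9); the knockout shows only "
      "the background error rate, confirming enzyme-dependent modification.")
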