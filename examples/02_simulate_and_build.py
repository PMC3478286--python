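"""Simulate an annotated proteome and build balanced training replicates.

The generator plants short kinase-style motifs (SP, S×S, R××S) around
annotated serine sites; the builder extracts 27-residue windows and pairs
all positives with equal-size negative draws taken >50 residues from any
annotated site.
"""

from phoskit import SimulationSpec, build_balanced_sets, simulate

proteins, truth = simulate(SimulationSpec(n_proteins=100, seed=42))
n_sites = sum(len(p.sites) for p in proteins)
print(f"simulated {len(proteins)} proteins with {n_sites} annotated S sites")
print(f"planted motif instances: {len(truth)} (e.g. {truth.iloc[0].to_dict()})")

sets = build_balanced_sets(proteins, "S", replicates=10, seed=42)
bset = sets[0]
print(f"{len(sets)} balanced replicates, each "
      f"{len(bset.positives)} positives + {len(bset.negatives)} negatives")
print("replicate seeds:", [s.seed for s in sets])
print("an example positive window:", bset.positives[0].window)

# Every replicate shares the same positives; the recorded per-replicate
# seeds let any negative draw be reproduced exactly.
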