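"""Cosine-similarity QC: flagging co-eluting interference.

A 1:1 mix is simulated where 40% of peptides receive a co-eluting
contaminant landing on the heavy monoisotopic peak. The CS score compares
each channel's observed (M, M+1, M+2) pattern to the enrichment-aware
theoretical one: contaminated heavy clusters score visibly below clean ones,
and excluding the flagged peptides pulls protein medians back to the truth.
"""

import numpy as np

from n15quant import QuantConfig, SimConfig, aggregate_proteins, generate_experiment, quantify_table

sim = SimConfig(n_proteins=20, peptides_per_protein=5, default_ratio=1.0,
                enrichment=0.97, noise_cv=0.02, seed=6,
                interference_fraction=0.4, interference_magnitude=4.0)
exp = generate_experiment(sim)
quants = quantify_table(exp.id_records, exp.scans,
                        QuantConfig(efficiency=0.97, cs_threshold=0.98))

hit = {(t["sequence"], t["charge"]): bool(t["interfered"]) for t in exp.truth}
cs_bad = [q.cs_heavy for q in quants if hit[(q.id_record.sequence, q.id_record.charge)]]
cs_ok = [q.cs_heavy for q in quants if not hit[(q.id_record.sequence, q.id_record.charge)]]
print(f"clean peptides:        mean CS(heavy) = {np.mean(cs_ok):.4f}")
print(f"contaminated peptides: mean CS(heavy) = {np.mean(cs_bad):.4f}")
print(f"flagged below CS 0.98: {sum(1 for q in quants if 'low_cs_heavy' in q.flags)} "
      f"of {len(quants)} peptides")

for label, kwargs in [("all peptides", {}), ("flagged excluded", {"exclude_low_cs": True})]:
    prots = aggregate_proteins(quants, **kwargs)
    err = np.mean([abs(np.log10(p.median)) for p in prots if p.median])
    print(f"mean |log10 median error| ({label}): {err:.4f}")
print("\nLow-CS peptides are flagged, never deleted — exclusion is the")
print("consumer's choice, and it restores the protein medians here.")
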