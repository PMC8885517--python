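"""Theoretical isotope envelopes of a heavy peptide at three enrichments.

The peptide VALEAC*VQAR (carbamidomethyl cysteine, [M+H]+) carries 14
labelable nitrogens. At complete labeling its cluster starts at the all-¹⁵N
monoisotopic peak M; at 95–99% enrichment, molecules with residual ¹⁴N form
the M−1, M−2 … satellites whose size is the readout of labeling efficiency.
"""

from n15quant import PeptideIon, build_composition, envelope, m1_over_m, parse_modifications

ion = PeptideIon("VALEACVQAR", parse_modifications("Carbamidomethyl@6"),
                 charge=1, channel="heavy")
comp = build_composition(ion)
print(f"{ion.sequence} [M+H]+ heavy: {comp.hill_formula()} "
      f"({comp.n_labeled_N} labeled N, {comp.n_unlabeled_N} unlabeled N)\n")

for p in (0.95, 0.97, 0.99):
    env = envelope(comp, p, "heavy")
    print(f"enrichment p = {p:.2f}   M-1/M = {m1_over_m(comp, p):.3f}")
    print("  offset   m/z         % of largest peak")
    pct = env.normalized("max")
    for off, mz, v in zip(env.offsets, env.centroid_mz, pct):
        if v >= 0.5:
            print(f"  {off:+d}      {mz:10.4f}   {v:6.1f}")
    print()

print("The M-1/M ratio shrinks as labeling approaches completion — it is the")
print("quantity inverted to estimate the experiment's labeling efficiency.")
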