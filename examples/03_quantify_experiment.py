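"""Full workflow on a simulated mixing experiment.

Ten proteins are mixed at known L/H ratios spanning 0.25–4 at 97% enrichment
with 2% peak noise. Every identified peptide (from either search channel) is
quantified from the averaged MS¹ scans around its identification, the
monoisotopic intensities are corrected for incomplete labeling, and peptide
ratios are compiled into per-protein Q1/median/Q3 with top-N normalization.
"""

from n15quant import QuantConfig, SimConfig, aggregate_proteins, generate_experiment, normalize, quantify_table

truth = {0: 0.25, 1: 0.5, 2: 1.0, 3: 2.0, 4: 4.0}
sim = SimConfig(n_proteins=10, peptides_per_protein=5, ratios=truth,
                enrichment=0.97, noise_cv=0.02, seed=42)
exp = generate_experiment(sim)
print(f"simulated {len(exp.scans)} MS1 scans, {len(exp.id_records)} identifications")

quants = quantify_table(exp.id_records, exp.scans, QuantConfig(efficiency=0.97))
proteins = aggregate_proteins(quants)
factor = normalize(proteins, top_n=100)

print(f"normalization factor (median of the most abundant proteins): {factor:.3f}\n")
print("protein       n   Q1      median  Q3      true L/H")
for i, p in enumerate(proteins):
    t = truth.get(i, sim.default_ratio)
    print(f"{p.accession}  {p.n_peptide_quants}   {p.q1:.3f}   {p.median:.3f}   "
          f"{p.q3:.3f}   {t}")
print("\nMedians recover the simulated mixing ratios; a tight Q1-Q3 range")
print("indicates a reliable protein quantification.")
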