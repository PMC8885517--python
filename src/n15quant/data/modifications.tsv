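# Modification formula deltas. d_labeled_N is the part of dN drawn from the
# metabolically labeled (residue-derived) nitrogen pool: carbamidomethyl adds
# a reagent nitrogen that is always 14N even in heavy samples (d_labeled_N=0),
# while pyro-Glu formation and Met-loss remove residue nitrogens
# (d_labeled_N=-1). Combined names ("Met-loss+Acetyl") are resolved by
# splitting on "+" and summing deltas.
# columns: name, dC, dH, dN, dO, dS, d_labeled_N
name	dC	dH	dN	dO	dS	d_labeled_N
Carbamidomethyl	2	3	1	1	0	0
Acetyl	2	2	0	1	0	0
Oxidation	0	0	0	1	0	0
Gln->pyro-Glu	0	-3	-1	0	0	-1
Met-loss	-5	-9	-1	-1	-1	-1
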