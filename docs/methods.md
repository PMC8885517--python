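# Methods

## The quantification model

A ¹⁵N metabolic-labeling experiment mixes a light (natural abundance) and a
heavy (¹⁵N-grown) sample before processing. Chemically identical peptides
from the two samples co-elute; the mass spectrometer separates them by the
mass shift n·Δ, where n is the peptide's count of labelable nitrogens and
Δ = m(¹⁵N) − m(¹⁴N) ≈ 0.99703 Da. Quantification is performed on MS¹
survey scans: for each identified peptide the counterpart ion is derived,
both isotope clusters are measured from the same averaged spectrum, and the
ratio of efficiency-corrected monoisotopic abundances is reported as L/H.

### Compositions and the nitrogen split

Peptide compositions are built from bundled residue/modification formula
tables (`src/n15quant/data/*.tsv`, standard monoisotopic values; isotope
masses and abundances from CODATA/IUPAC-CIAAW). Every residue-derived
nitrogen belongs to the *labeled* pool; nitrogen introduced chemically after
extraction — the carbamidomethyl reagent nitrogen — is always ¹⁴N and sits
in the *unlabeled* pool. Modifications may move nitrogens out of the labeled
pool (pyro-Glu formation, Met-loss). Charge-carrier protons are included in
the printed hydrogen count (so the [M+H]⁺ formula of carbamidomethylated
VALEACVQAR reads C46 H82 N15 O15 S1) but weigh m(¹H) − m(e) and carry no
isotope distribution.

### Envelopes at enrichment p

The observable cluster at Orbitrap resolution is the *aggregated* envelope:
isotopologues binned by nominal mass, fine structure unresolved. For the
heavy channel each labeled nitrogen is ¹⁵N with probability p
independently, so the labeled pool contributes Binomial(n, 1−p) residual
¹⁴N atoms — the M−1, M−2 … satellites below the fully-labeled monoisotopic
peak M, which anchors offset 0. All other atoms contribute the usual
natural-abundance shoulder at M+1, M+2 …

Implementation: per-bin abundance and mass-moment arrays, convolved per
element by binary powering with per-step truncation of edge bins below
1e−12; final envelopes keep bins in descending-abundance order until they
cover 1 − 1e−6 of the total, then renormalize to exactly 1. Centroid m/z
per bin is the abundance-weighted mean mass. An exact multinomial
enumeration oracle (≤ 12 atoms) validates the engine to 1e−9 in the tests.
One numerical subtlety: at p < 1 the offset-0 bin mixes the pure
monoisotopic species with e.g. {one ¹⁴N + one ¹³C} combinations, so its
centroid sits ~1 mDa above the monoisotopic m/z; the centroid equals the
chemcore mass exactly only where the bin is a single species (light
channel, or heavy at p = 1).

### Labeling efficiency from M−1/M

M−1/M is strictly decreasing in p and nearly linear in (1−p) with slope ~n,
making it the sensitive readout for enrichment. `invert_efficiency` solves
the theoretical curve for p by bisection (Brent) on [0.5, 0.9999] to
|Δp| < 1e−5; observations outside the attainable range clamp to the bracket
edge with a warning. The lower bound reflects the workflow's validity
domain: below ~50% incorporation the heavy satellites overlap the light
cluster, which this workflow deliberately does not deconvolve.
`estimate_experiment_efficiency` averages per-peptide inversions (mean, with
SD reported so non-constant labeling is visible) and by default prefers
peptides with monoisotopic mass < 1500 Da, whose M peak is the cluster
maximum — the filter is overridable and falls back to all clusters with a
warning rather than failing.

### Spectrum averaging and peak matching

MS¹ scans within a window around the identifying MS² retention time
(default −5 s / +15 s — narrower than the ~30 s chromatographic peak on
purpose: it nearly always contains the elution apex while limiting
co-elution interference) are pooled and clustered on the m/z axis with a
FWHM/2 tolerance, FWHM = m/z / R (default R = 240,000). A cluster's
intensity is its summed signal divided by the number of scans in the window
(mean height including scans where the peak is absent); its area is the
trapezoidal integral of per-scan heights over the window. Peak matching
takes the nearest cluster within FWHM/2, ties broken toward the more
intense peak. Absent peaks are *exactly zero* — the zero-noise contract: no
imputation from local noise, so a missing channel is a genuine sentinel
(ratio +inf/0/NaN with a status field), not a fabricated ratio.

### Efficiency correction and CS scoring

Only the monoisotopic peak is measured per channel. Dividing it by the
envelope fraction expected at offset 0 (f_M) scales the measurement to the
whole cluster, adding back the satellite abundance lost to incomplete
labeling; without this the heavy channel is systematically underestimated
(about 2× at p = 0.95 for a 14-nitrogen peptide). The CS score is the
cosine similarity of the observed vs theoretical (M, M+1, M+2) vectors,
computed per channel from the enrichment-aware envelope; it is
scale-invariant and compares shape only. Pairs scoring below the threshold
(default 0.9, configurable) are flagged, never removed. Because inflating M
alone asymptotically bottoms out near cos ≈ 0.88 for typical peptide
shapes, runs that want aggressive interference screening should raise the
threshold (the interference demonstrations use 0.98). CS reliability drops
at very low signal, so each quant carries its summed observed intensity for
downstream down-weighting; no hard intensity floor is applied.

### Protein statistics, normalization, FDR

Per protein, Q1/median/Q3 of the finite peptide ratios are computed on log
ratios (quartiles by linear interpolation between order statistics) and
back-transformed — the result is identical for any log base. The median
resists outliers; proteins with Q3/Q1 > 4 are flagged wide-IQR. One-sided
sentinel ratios are excluded from the log-space statistics by default but
remain in the peptide report. Normalization divides every median by the
median of the top-100 most abundant quantified proteins (abundance =
summed cluster intensity across both channels; peptide count available as
an alternative ranking) or by named housekeeping accessions. FDR is
computed separately per search channel as decoys/targets (in %), since the
¹⁴N and ¹⁵N searches have different random-match behavior.

## The synthetic-data generator

`simulate.generate_experiment` emulates the study conditions of a
well-executed labeling experiment: enrichment 0.97 by default (93–99 is the
realistic range for 14-day plate-grown Arabidopsis), Gaussian elution with
30 s FWHM, one MS¹ scan per second, 1% multiplicative peak noise, lognormal
(σ = 0.3) peptide base intensities around 10⁶, charge 2/3 at 70/30%, and a
peptide pool seeded with real Arabidopsis tryptic sequences (RBCL, TUB2,
PR5 …) extended with random tryptic-like strings. Scenario switches cover
co-eluting interference injected onto a chosen isotope position,
missing-channel proteins (IP-style one-sided cases) and never-labeled
seed-storage-like proteins. The generator writes standard mzML/TSV, emits a
ground-truth table, and is byte-deterministic in its seed.

What it does **not** emulate — and what passing tests therefore do not
show: chemical background and electronic noise floors, centroiding
artifacts from profile data, chromatographic drift or tailing, dynamic-
range compression, isotope clusters of *different* peptides colliding in
m/z, and the low-incorporation regime where light and heavy clusters
overlap (explicitly out of the workflow's validity domain). Recovery
statistics on synthetic data are upper bounds on real-data performance.

## Problem sizes and tolerances in the test suite

The suite exercises end-to-end recovery at deliberately desk-scale sizes:
200 peptide pairs for ratio-recovery RMSE (< 0.05 in log10 at 2% peak
noise), 10 proteins × 4 peptides for reciprocal-labeling symmetry (forward
× reverse medians = 1 within 2%), ≥ 100 interference injections for CS
flagging, and 10 peptides × 4 enrichment levels for efficiency recovery
(±0.005). Envelope correctness is held to 1e−9 against the enumeration
oracle; mass arithmetic to 1e−5 Da against an independent reference
calculator.

## Design choices made where the design was open

- **mzML I/O is implemented in-package on lxml** for the centroided-MS¹
  subset (64/32-bit float arrays, none/zlib compression), with a writer
  producing a minimal valid document; profile data is rejected with
  guidance rather than centroided.
- **Library-first shape**: the importable API plus `examples/` scripts is
  the primary interface; the click CLI is a thin layer over it because the
  workflow is also a shell tool.
- **Averaging uses the mean, not the sum**, over window scans (ratios are
  invariant either way); intensity mode is the default, area mode uses the
  trapezoidal XIC integral.
- **Envelope display** offers both normalizations — largest peak = 100%
  (plot-style) and unit sum (internal) — with unit sum used everywhere in
  computation.
- **Efficiency averaging is unweighted** across peptides; intensity
  weighting is deliberately not applied so a single bright peptide cannot
  dominate the estimate.
- **Deduplication**: one quantification per (sequence, modifications,
  charge, file); when both channels were independently identified the
  higher-score identification anchors the RT window.
- **N-terminal acetyl and related nitrogen-free modifications** are taken
  at face value from the variable-modification list; they alter no nitrogen
  pools.
- Ambiguous residues (B, Z, X, U) are rejected, not guessed.

## Known limitations

No MS² search, decoy-database construction, protein inference or
cross-replicate significance testing (downstream tools' territory); no
deconvolution of overlapping ¹⁴N/¹⁵N clusters at low incorporation, hence
no support for turnover-style studies; only ¹⁵N is wired as a metabolic
label, though the envelope engine itself is element-generic; Thermo RAW
files must be converted to centroided mzML externally.
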