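# Methods

## The chemistry model

A dehydroamino acid (DHAA) is modelled purely by its mass consequence:
formation from Ser/Thr removes one water (−18.010565 Da) and from Cys one
H₂S (−33.987721 Da). Phospho-Ser/Thr precursors eliminate phosphate, but
relative to the unphosphorylated residue the product delta is the same
water loss, so a single delta per donor residue suffices. Dehydrobutyrine
(from Thr) is mass-identical to dehydroalanine formation and is not
distinguished. Michael addition is treated as mass-neutral bond formation:
a conjugate's delta is the eliminylation loss plus the full monoisotopic
mass of the intact nucleophile (glutathione C₁₀H₁₇N₃O₆S, homocysteine
C₄H₉NO₂S, DTT C₄H₁₀O₂S₂, TCEP C₉H₁₅O₆P); stereochemistry is ignored as
mass-identical. A crosslink between two peptides uses the same logic: its
mass is the sum of the two peptide masses plus the (negative) crosslinker
delta, −18.010565 for S/T-derived and −33.987721 for Cys-derived DHAAs.
Donors are restricted to S/T/C, acceptors to the nucleophilic side chains
C/K/H; an alkylated acceptor Cys is chemically blocked and rejected.

Atomic masses are pinned in `dhaaxl.constants` (CODATA/AME-style
monoisotopic values; proton 1.00727646688 Da) so results are reproducible
across platforms. Reference renderings at lower precision (e.g. −18.0105
for the S/T crosslinker delta) are treated as truncations of the
full-precision values; all internal arithmetic is full precision — the
worked-example crosslink m/z of 487.49546 at z = 4 only reproduces at full
precision. The companion standard IG[DHA]TENLK–CGSKDNIK computes to
neutral 1705.866883 Da, m/z 427.47400 at z = 4, by residue-mass summation;
a circulating value of 474.47400 for this species is a digit transposition
and is deliberately not matched.

## ¹⁸O labelling

Tryptic digestion in heavy water exchanges both C-terminal carboxylate
oxygens, so each C-terminus carries two ¹⁸O: a linear peptide shifts
+4.008493 Da and a crosslinked pair of peptides, having two C-termini,
+8.016986 Da. The label is carried compositionally (heavy oxygen is a
distinct element species, assumed isotopically pure), so isotope patterns
and fragment masses of labelled species fall out of the same machinery; in
fragment ladders the label appears in every y ion and no b ion.

## Isotope patterns

Theoretical isotope distributions are computed by convolving per-element
isotopologue polynomials over neutron-shift bins, tracking in each bin both
the probability and the abundance-weighted mass so every reported peak is
the centroid of its isotopologue cluster. Bins with suffix probability
below 1e-12 are pruned during convolution; the final pattern is truncated
to the requested number of peaks and renormalized to sum 1. The
implementation is checked against exhaustive isotopologue enumeration (an
exponential-time oracle used for compositions of ≤ 12 atoms) to 1e-9 in
intensity. The adjacent-peak spacing invariant (≈ 1.0034/z Da) holds for
peptide-like compositions where carbon dominates; it is not asserted for
artificial sulfur-dominated formulas whose shift-2 bin is ³⁴S-driven.

## Searching

Candidates come from in-silico tryptic digestion (cleave after K/R, no
cleavage before proline, 2 missed cleavages, length 6–40 by default —
conventional settings). Decoys are per-protein sequence reversals keeping
the C-terminal residue, preserving the tryptic mass distribution. Scoring
is a transparent greedy matched-ion count plus fraction of fragment
intensity explained (each observed peak explains at most one theoretical
ion, b/y ions only, 10 ppm precursor and 20 ppm fragment tolerances by
default); it is deliberately not a rescoring model, because the package's
validation surface is planted-truth recovery, not engine benchmarking.
q-values are estimated by target-decoy competition: at threshold s the FDR
estimate is #decoys≥s / #targets≥s, and a match's q is the best estimate
over thresholds at or below its score.

Open modification discovery explains the precursor mass gap between an
unidentified spectrum and an unmodified digest peptide with a candidate
modification delta, then localizes the modification to the target residue
whose placement maximizes the fragment score (ties go to the lowest
position and are flagged ambiguous).

The crosslink search enumerates (α, β) peptide pairs whose summed mass plus
the crosslinker delta matches the precursor, with a donor residue on α and
an acceptor on β. Fragment ions spanning the linked site carry the entire
partner-peptide mass plus the crosslinker delta; ions outside it equal the
plain linear fragments. Site localization picks the best-scoring placement
per chain, then the pair is scored jointly on the union of both chains'
ladders. When several donor chemistries are searched (S/T water loss and
Cys H₂S loss), each spectrum competes across the union of the candidate
spaces and q-values are estimated once on the pooled best-per-spectrum
matches. This pooling matters: a spectrum whose true explanation lives in
the other chemistry's space would otherwise meet only decoys in its own
search, and a handful of such decoy hits can dominate the FDR estimate of
a small targeted search.

## Crosslink validation

A candidate crosslink is accepted only if (1) the identical peptide pair
and linked sites are found in both the standard and the heavy-water
preparation with a heavy−light mass difference of one crosslinked-pair
label shift (+8.016986 Da) within tolerance and retention times within a
window; (2) the observed MS1 envelope matches the theoretical isotope
distribution of the species (monoisotopic mass within tolerance and
normalized dot-product similarity above threshold); and (3) both label
forms survive, below the FDR threshold, a full-proteome linear search in
which the crosslink is appended to the database as a site-specific custom
modification whose delta is the partner-peptide mass plus the crosslinker
delta (heavy variant +4.008493 for the partner's labelled C-terminus).
Defaults: 5 min RT window, 10 ppm mass tolerance, 0.95 isotope similarity,
q ≤ 0.01 — strict, configurable values; acceptance is monotone in all four
parameters. Partial ¹⁸O exchange is simulated (see below) but the
validator matches only the fully exchanged +8 species.

## The synthetic-data generator

The generator emulates the study conditions at desk scale, fully
deterministic under its seed at every stage. Defaults: 30 random
tryptic-friendly proteins of 120–240 residues; 8 direct DHAA sites and 4
sites per conjugate kind; 6 intra- and 6 inter-protein crosslinks planted
in both label states plus 4 "light-only" links that must be rejected;
40 unmodified background peptides; 2 ppm Gaussian mass error; 0.3 min RT
jitter; 30 uniform noise peaks per spectrum at 1–10 % of the base peak;
48 disease (AD) and 44 control specimens with log-normal intensity noise
(σ = 0.3 on the natural-log scale) and a 10-fold planted effect on
crosslink features — group sizes and effect size chosen to match the
reported disease-tissue conditions. Heavy runs emit the fully exchanged
species with probability 0.95 (the labelled water's isotopic purity);
otherwise exactly one terminus carries the label, stressing the
validator's +8-only matching. Spectra are generated at the peptidoform
level (one spectrum per species per run, scalar precursor intensity, no
chromatographic peak shapes) since quantification here is aggregation,
not feature detection; technical replicates are modelled as two runs per
label state.

Two constraints keep the planted truth identifiable by construction:
planted sites sit on internal residues of distinct tryptic peptides (so
fragment ladders can localize them), and intra-protein crosslinks are
never planted between sequence-adjacent tryptic peptides — a water-loss
crosslink between adjacent peptides is exactly isobaric with the
missed-cleavage linear peptide and no mass-based method can distinguish
them.

What passing tests on this generator do **not** show: performance under
real chromatographic interference, co-isolation, semi-tryptic background,
incomplete fragmentation, or realistic intensity-dependent noise. The
recovery and FDR numbers characterize the pipeline's logic, not its
behaviour on instrument data.

## Statistics

A site is *confirmed* only when at least one conjugate form (GSH, HC, DTT,
TCEP or a crosslink) is observed there; the bare −18/−34 Da loss can arise
in-instrument and confirms nothing on its own, so direct-only sites are
kept but flagged. Prevalence thresholds are inclusive fractions of the
specimen universe, making counts non-increasing in the threshold.

Label-free quantification sums precursor intensities per peptidoform per
specimen across runs and median-normalizes specimens; missing values stay
missing (no imputation — imputation choices would dominate the results and
none is canonical). Fold changes are ratios of group means on the
intensity scale. The default test is Welch's two-sample t-test: the
analysis design this package targets describes a paired t-test for groups
of 48 and 44 specimens, which cannot be paired as stated, so the unpaired
test is the default and a paired mode exists for genuinely balanced
designs. Zero-variance features get the limiting p (kept strictly
positive) and a flag rather than an error.

Permutation FDR permutes group labels unrestrictedly (SAM-style): for each
observed |t| threshold, q is the permutation-mean count of permuted |t|
values at or above it divided by the observed count, capped at 1, with
each feature assigned the best achievable estimate over thresholds it
survives. An `exhaustive` mode enumerates all label assignments for small
designs and is verified against direct counting at 3 vs 3. Site occupancy
is modified/(modified+unmodified) per specimen, reported as the mean with
the standard error of the per-specimen fractions (checked against a
bootstrap over specimens).

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on the
default 30-protein simulation (two light and two heavy runs, ~160 spectra
per label state), the differential analysis on the 48-vs-44 matrix with
100–500 permutations, and the oracle equivalences on ≤ 12-atom
compositions and 3-vs-3 designs — sizes chosen so the complete suite
exercises every stage in well under a minute each while keeping every
statistical check adequately powered.

## Known limitations

- Scoring is intentionally simple; no intensity prediction, rescoring or
  retention-time modelling.
- Only b/y fragment ions at charges 1–2; no neutral losses or isotope
  peaks in MS2.
- Quantification aggregates identified precursor intensities; there is no
  feature detection or match-between-runs.
- The crosslink search targets small databases (hundreds of proteins), as
  crosslink search spaces grow quadratically.
- Average (non-monoisotopic) masses, isotope fine structure and charge
  deconvolution are out of scope.
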