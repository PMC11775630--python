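# dhaaxl

Discovery and validation of **dehydroamino acids (DHAAs)** and their
protein–protein crosslinks in bottom-up proteomics data.

DHAAs — dehydroalanine (from Ser or Cys) and dehydrobutyrine (from Thr) —
arise by *eliminylation*: β-elimination of water (−18.010565 Da) from
Ser/Thr or of H₂S (−33.987721 Da) from Cys. The resulting electrophilic
alkene reacts by Michael addition with cellular nucleophiles, leaving
diagnostic mass shifts: conjugates with glutathione (GSH), homocysteine
(HC), or the reducing agents DTT and TCEP, and — when the nucleophile is a
Cys/Lys/His side chain of another peptide — covalent protein–protein
crosslinks (DHAA-XL). These species are of particular interest in
aggregated, long-lived proteins such as those found in Alzheimer's disease
brain tissue.

`dhaaxl` is a library for the full discovery workflow:

- **chemistry** (`dhaaxl.chem`): elemental-composition algebra, monoisotopic
  masses, eliminylation/conjugate/crosslinker deltas, ¹⁸O C-terminal label
  shifts, and theoretical isotope patterns by polynomial convolution;
- **I/O** (`dhaaxl.io`): FASTA and MGF via pyteomics, TSV identification
  tables (PSMs, CSMs, sites), peptide→protein coordinate mapping, and
  intra/inter link classification;
- **digestion & planning** (`dhaaxl.digest`): tryptic digestion, targeted
  database construction (curated aggregation panel / DHAA-containing /
  top-N abundant), the 9 × datasets × databases crosslink search grid, and
  crosslink-appended database augmentation;
- **searching** (`dhaaxl.search`): linear PSM search with reversed-decoy
  q-values, open delta-mass modification discovery with site localization,
  and a DHAA crosslink search scoring crosslink-containing fragments of
  both chains;
- **validation** (`dhaaxl.validate`): heavy-water crosslink validation —
  tryptic digestion in H₂¹⁸O labels every C-terminus with two ¹⁸O, so a
  linear peptide shifts +4 Da but a crosslinked pair (two C-termini) shifts
  +8 Da — plus MS1 isotope-envelope verification and the three-criterion
  acceptance rule;
- **statistics** (`dhaaxl.stats`): conjugate-evidence eliminylation-site
  calling, specimen prevalence, label-free intensity aggregation,
  disease/control differential abundance (Welch t) with permutation FDR,
  site occupancy, and aggregate-association fractions;
- **simulation** (`dhaaxl.simulate`): a fully seeded synthetic-data
  generator (proteomes, planted sites/conjugates/crosslinks, paired
  light/heavy spectra with ppm error, intensity matrices with planted
  fold changes) so every stage is testable against known ground truth.

## Worked example

The package reproduces the theoretical m/z of a synthetic crosslinked
peptide standard — dehydroalanine at Ser5 of SPVVSGDTSPR joined to the
cysteine of CGSKDNIK:

```python
>>> from dhaaxl import CrosslinkSpecies, Peptidoform, builtin_modifications
>>> from dhaaxl import crosslink_species_mz
>>> mods = builtin_modifications()
>>> x = CrosslinkSpecies(Peptidoform("SPVVSGDTSPR"), Peptidoform("CGSKDNIK"),
...                      donor_site=5, acceptor_site=1,
...                      crosslinker=mods["XL-ST"])
>>> round(crosslink_species_mz(x, 4), 5)
487.49546
```

The crosslinker delta is the water loss of dehydroalanine formation
(−18.010565 Da), so the crosslinked pair is lighter than the sum of its
two peptides; at charge 4 the species appears at m/z 487.49546.

Running the end-to-end pipeline on synthetic data
(`python examples/simulate_search_validate.py`) prints:

```
planted crosslinks (both labels): 12
planted light-only decoy links:   4
accepted after validation:        12
recovery of planted links:        100.0%
empirical FDR among accepted:     0.0%
light-only links accepted:        0 (must be 0: no heavy +8 Da partner exists for them)
```

All 12 crosslinks planted in both label states survive the
three-criterion validation, no false crosslink is accepted, and the four
links planted only in the light runs — which have no +8 Da heavy partner —
are all rejected, demonstrating the specificity of the ¹⁸O signature.

The `examples/` directory has one short script per capability:
`chemistry_constants.py`, `digest_and_plan.py`,
`simulate_search_validate.py`, `differential_abundance.py`,
`site_calling_prevalence.py`.

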