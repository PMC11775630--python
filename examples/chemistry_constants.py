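"""Mass deltas of the dehydroamino-acid chemistry and a worked crosslink m/z.

Prints the eliminylation and conjugate mass shifts used throughout the
pipeline, the heavy-water label shifts, and the theoretical m/z of a
synthetic crosslinked-peptide standard.
"""

from dhaaxl import (
    CrosslinkSpecies,
    Peptidoform,
    builtin_modifications,
    conjugate_delta,
    crosslink_species_mz,
    eliminylation_delta,
    label_18O_shift,
)

mods = builtin_modifications()

print("Eliminylation deltas (DHAA formation, Da):")
print(f"  Ser/Thr (-H2O): {eliminylation_delta('S'):+.6f}")
print(f"  Cys     (-H2S): {eliminylation_delta('C'):+.6f}")

print("Conjugate deltas vs the unmodified residue (Da):")
for conj in ("GSH", "HC", "DTT", "TCEP"):
    print(f"  {conj:>4}-DHAA on Ser: {conjugate_delta(conj, 'S'):+.6f}")

print("Heavy-water (18O) C-terminal label shifts (Da):")
print(f"  linear peptide (1 terminus):  {label_18O_shift(1):+.6f}")
print(f"  crosslinked pair (2 termini): {label_18O_shift(2):+.6f}")

# the synthetic standard: dehydroalanine at Ser5 of SPVVSGDTSPR joined to
# the cysteine of CGSKDNIK; at charge 4 this is the inclusion-list species
x = CrosslinkSpecies(
    Peptidoform("SPVVSGDTSPR"), Peptidoform("CGSKDNIK"),
    donor_site=5, acceptor_site=1, crosslinker=mods["XL-ST"],
)
print(f"SPVV[DHA]GDTSPR-CGSKDNIK at z=4: m/z {crosslink_species_mz(x, 4):.5f}")
print("(the water-loss crosslinker makes the pair 18.0106 Da lighter than "
      "the sum of its peptides)")
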