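"""In-silico digestion and the crosslink search grid.

Digests a small protein, then enumerates the full factorial crosslink
search plan: 3 DHAA donor chemistries x 3 nucleophilic acceptors x
datasets x targeted databases.
"""

from dhaaxl import DigestParams, ProteinRecord, plan_crosslink_searches, tryptic_digest
from dhaaxl.digest import load_aggregation_panel

prot = ProteinRecord("DEMO", "demo protein", "MKSPVVSGDTSPRLKAAAKCGSKDNIKR")
peps = tryptic_digest(prot, DigestParams(max_missed_cleavages=1, min_length=6))
print("Tryptic peptides (1 missed cleavage, length >= 6):")
for pep, start in peps:
    print(f"  {start:>3}  {pep}")

plan = plan_crosslink_searches(
    dataset_ids=tuple(f"run{i:02d}" for i in range(16)),
    database_ids=("aggregation", "dhaa_containing", "top500"),
)
print(f"\nCrosslink search plan: {len(plan)} jobs "
      "(9 donor-acceptor chemistry combos x 16 datasets x 3 databases)")

panel = load_aggregation_panel()
print(f"Shipped aggregation panel: {len(panel)} proteins, e.g. "
      + ", ".join(panel[:6]))
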