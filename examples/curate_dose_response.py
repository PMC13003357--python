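"""Curate a small dose-response table and band the survivors.

Builds a handful of records that each exercise one exclusion rule, runs
the curation pipeline, and prints the kept compounds with their potency
categories plus the exclusion ledger.
"""

from ahrqsar import DoseResponseRecord, curate_dataset

records = [
    DoseResponseRecord("benzo-like", purity_pct=99.0, ec25_ahr_uM=0.8),
    DoseResponseRecord("weak-agonist", purity_pct=95.0, ec25_ahr_uM=45.0),
    DoseResponseRecord("clean-negative", purity_pct=98.0),
    DoseResponseRecord("impure", purity_pct=80.0, ec25_ahr_uM=2.0),
    DoseResponseRecord("burst-artifact", purity_pct=99.0, ec25_ahr_uM=10.0,
                       ec20_cyto_uM=12.0),
    DoseResponseRecord("gray-zone", purity_pct=99.0, ec25_ahr_uM=300.0),
]

result = curate_dataset(records, scheme="4cat")

print("kept compounds:")
print(result.kept[["compound_id", "ec25_ahr_uM", "activity_category"]].to_string(index=False))
print("\nexclusion ledger:")
print(result.ledger_frame().to_string(index=False))
print(
    "\nEach kept compound carries its EC25-banded potency category; each "
    "excluded record names the single rule that removed it (e.g. the "
    "cytotoxicity factor-3 rule catches reporter activity too close to "
    "cell death to be receptor-specific)."
)
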