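"""Disproportionality analysis on a simulated adverse-event report table.

Simulates 3000 spontaneous reports with drug-niche covariate structure and
a planted 4x reporting enrichment of torsades de pointes for one drug,
curates the table, selects genetic-algorithm-matched background pools,
and computes the averaged proportional reporting ratio (PRR) of the drug's
major cardiotoxicity event (MCE).  PRR >= 2 calls the drug positive.
"""

from cardioscreen.faers import GaParams, classify_faers, curate
from cardioscreen.sim import FaersSimConfig, simulate_faers

table, truth = simulate_faers(FaersSimConfig(
    n_reports=3000, duplicate_rate=0.05,
    planted_associations=(("drugA", "torsades de pointes", 4.0),),
    seed=21,
))
curated, log = curate(table)
print(f"curation: {log['input_rows']} rows -> {log['output_rows']} "
      f"({log['collapsed_duplicates']} near-duplicates collapsed)")

positive, assoc = classify_faers(
    "drugA", curated, n_pools=20, ga=GaParams(generations=20), seed=1,
)
print(f"drugA MCE      : {assoc.event}")
print(f"mean PRR       : {assoc.mean_prr:.2f} over {len(assoc.pool_prrs)} matched pools")
print(f"call           : {'positive' if positive else 'negative'} (threshold 2.0)")
print("\nThe planted 4x enrichment is diluted by concomitant-role mentions, "
      "but the averaged PRR stays well above the positivity threshold.")
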