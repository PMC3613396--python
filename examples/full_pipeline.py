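"""The whole inference end to end on a paralog-pair cohort.

Five genomes, each with a duplicated dpsB: the pipeline recovers ortholog
clusters, structure, promoter calls, chromosome context, synteny and fold
changes, then verifies the duplication dichotomy — one copy arm-located
with a SigB motif and poor synteny (the osmotically inducible paralog),
the other core-located, motif-free, well conserved (the ancestral copy).
"""

import pandas as pd

from dpsevolve.pipeline import run_pipeline, verify_dichotomy
from dpsevolve.simulate import generate_cohort

cohort = generate_cohort(n_genomes=5, length=2_000_000, n_genes=25,
                         arm_threshold=500_000, seed=42)
result = run_pipeline(cohort, params={"arm_threshold": 500_000,
                                      "bootstrap_reps": 100},
                      out_dir="scratch/example_run")

pd.set_option("display.width", 200)
cols = ["gene", "cluster", "tail_category", "position_mb", "compartment",
        "sigb_positive", "synteny_score", "fold_change_mean",
        "predicted_osmo_inducible"]
print(result.report[cols].round(2).to_string(index=False))

table = verify_dichotomy(result)
print(f"\ndichotomous pairs: {int(table['dichotomy'].sum())}/{len(table)}")
counts, agreement = result.concordance
print(f"motif/induction agreement: {agreement:.0f}% {counts}")
print("\nEvery pair splitting cleanly and 100% agreement reproduce the"
      "\nheadline: the SigB-motif-bearing arm paralog is the osmotically"
      "\ninducible one. Artifacts are under scratch/example_run/.")
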