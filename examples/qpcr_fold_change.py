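"""Efficiency-corrected fold changes (Pfaffl) and motif/induction agreement.

Builds a Ct table with a planted 8-fold induction for one gene, summarises
per-replicate Pfaffl ratios normalised to hrdB, and cross-tabulates
induction calls against promoter-motif presence.
"""

from dpsevolve import expression
from dpsevolve.simulate import generate_ct_table

print("pfaffl_ratio(E_t=2, dCt_t=3, E_r=2, dCt_r=0) =",
      expression.pfaffl_ratio(2.0, 3, 2.0, 0))

truth = {"dpsB2_arm": 8.0, "dpsB_core": 1.0}
rows = generate_ct_table(truth, efficiency=2.0, noise_sd=0.2, n_reps=3, seed=1)
folds = expression.summarize(rows, induction_threshold=2.0)
for f in folds:
    print(f"{f.gene}: mean fold change {f.ratio_mean:.2f} "
          f"(SD {f.ratio_sd:.2f}, n={f.n_reps}), induced={f.induced}")

sigb = {"dpsB2_arm": True, "dpsB_core": False}
counts, agreement = expression.induction_concordance(folds, sigb)
print(f"\nmotif vs induction: {counts}, agreement {agreement:.0f}%")
print("The arm copy with the SigB motif is the one induced by osmotic"
      " stress;\nthe reference-normalised ratio recovers the planted 8-fold"
      " change within\nreplicate noise.")
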