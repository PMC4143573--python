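"""The three-stage cross-strain fold-change screen.

Part 1 replays the screen on the published per-strain fold changes of the
three candidate genes (FMP21, YER034W, PRM5).  Part 2 runs the full chain —
percentile-shift normalization, intensity/flag filters, fold changes, three
stages — on a synthetic matrix with one planted thermotolerance-concordant
gene among 499 background genes, and checks it is recovered.
"""

import thermoscreen as ts
from thermoscreen import datasets

# --- published fold-change table ------------------------------------------
result = ts.screen_fold_changes(
    datasets.candidate_fold_changes(), datasets.STRAIN_ROLES
)
print("published fold-change table:")
print(result.audit.to_string(float_format=lambda v: f"{v:.2f}"))
print(f"stage-3 candidates: {sorted(result.stage3_genes)}\n")
# All three genes exceed 1.5-fold in the tolerant and reference strains,
# show a >1.5 fold-change ratio somewhere along the gradient, and decrease
# monotonically with thermotolerance — so all three survive stage 3.

# --- synthetic matrix with planted ground truth ---------------------------
trio = ts.default_strain_trio()
matrix, truth = ts.simulate_expression_matrix(
    trio,
    n_genes=500,
    n_replicates=2,
    planted_induction={"tolerant": 3.68, "reference": 2.18, "sensitive": 1.35},
    noise_sd=0.05,
    seed=7,
)
roles = {"tolerant": "tolerant", "reference": "reference", "sensitive": "sensitive"}
res = ts.run_screen(matrix, roles)
print(f"synthetic screen: {res.n_input_genes} genes in, "
      f"{res.n_filtered_genes} past filters, "
      f"stage sizes = {len(res.stage1_genes)}/{len(res.stage2_genes)}/"
      f"{len(res.stage3_genes)}")
print(f"planted gene {truth.planted_gene!r} recovered: "
      f"{truth.planted_gene in res.stage3_genes}")
# With duplicate arrays and 0.05 log2-scale noise the planted gene is the
# only survivor: background genes have expected fold change 1 and cannot
# clear the 1.5-fold stage-1 bar.
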