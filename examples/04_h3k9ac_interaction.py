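"""Rank genes by the interaction of promoter H3K9ac gain with upregulation.

Simulates a peak landscape with known per-gene summed M-values, assigns peaks
to 10-kb promoter windows, combines the H3K9ac score (X1) with an expression
log2 fold-change (X2) into the interaction effect IE = X1 + X2 + X1*X2,
selects genes with IE z-score > 0, and checks how stable that selection is
when the gamma weights are drawn at random.
"""

import numpy as np

from ordgene import (
    assign_peaks,
    gamma_robustness,
    h3k9ac_scores,
    interaction_effect,
    simulate_peak_landscape,
)

peaks, promoters, truth = simulate_peak_landscape(
    n_genes=40, peaks_per_gene=(1, 3), m_value_loc=0.6, n_decoys=25, seed=4
)
mapping = assign_peaks(peaks, promoters, window=10_000)
x1 = h3k9ac_scores(mapping, peaks)
print(f"{len(x1)}/{len(promoters)} genes have >= 1 peak in the promoter window "
      f"({len(peaks)} peaks incl. 25 decoys outside every window)")

rng = np.random.default_rng(0)
x2 = rng.uniform(0.2, 2.5, size=len(x1))  # upregulated candidates only

table = interaction_effect(x1.to_numpy(), x2, gene_ids=x1.index)
n_sel = int(table["selected"].sum())
print(f"{n_sel}/{len(table)} candidate genes selected (IE_Z > 0)")
print("\ntop 5 by IE_Z:")
print(table.head(5).to_string(float_format=lambda v: f"{v:.3g}"))

frac = gamma_robustness(x1.to_numpy(), x2, n_iter=100, seed=1)
print(f"\nrandom-gamma robustness: identical selected set in {frac:.0%} "
      "of 100 iterations (gammas ~ U(0.5, 2)^3)")
# IE_Z > 0 picks genes whose combined acetylation gain and upregulation is
# above the candidate average; the robustness fraction says how sensitive
# that set is to the arbitrary unit weights.  With diffuse candidates like
# these, genes near the boundary flip; stability emerges when the candidate
# IE values are well separated:
x1_sep = np.concatenate([rng.uniform(0.1, 0.3, 20), rng.uniform(2.5, 4.0, 20)])
x2_sep = np.concatenate([rng.uniform(0.1, 0.3, 20), rng.uniform(2.0, 3.0, 20)])
frac_sep = gamma_robustness(x1_sep, x2_sep, n_iter=100, seed=1)
print(f"with two well-separated candidate classes: identical set in "
      f"{frac_sep:.0%} of iterations")
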