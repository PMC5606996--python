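# ordgene

Screen gene expression against **ordinal clinical severity** instead of a
binary disease/control split.

Clinical metadata often carries more than a case/control label: tumor stages,
dementia ratings, or neuropathological grades such as the Vonsattel scale for
Huntington's disease order patients by severity. `ordgene` fits, for every
gene, a proportional-odds cumulative-link model tying log-scale expression
*x* to the ordered grade *Y* ∈ {0, …, k}:

    P(Y ≤ i | x) = F(αᵢ − βx),   i = 1, …, k

with a probit link *F* = Φ by default (a latent variable z\* = βx + ε,
ε ~ N(0,1), thresholded at α₁ < … < α_k). The single shared slope β is the
rate at which expression rises (β > 0) or falls (β < 0) with severity; each
parameter gets a two-tailed Wald z-test. Genes whose fit passes a stringent
threshold (default p < 10⁻⁶) are called **phenotype-associated genes (PAGs)**,
split by the sign of β, and ranked by |β|. Because one β must describe every
grade boundary, a PAG has to change consistently across the whole severity
range — not merely differ between pooled groups, and not be an artifact of
late-stage shifts in tissue composition.

Around that core the package provides the comparison and integration
machinery such a screen is used with:

- **`diffexp`** — an empirical-Bayes moderated t-test (two-group contrast)
  with BH correction, plus hypergeometric overlap statistics, to contrast the
  severity-aware screen with the conventional binary one;
- **`enrichment`** — hypergeometric gene-set over-representation with the
  enrichment score (k/n)/(K/N) and a Welch t comparison of score
  distributions;
- **`epi`** — integration with differential H3K9ac ChIP-seq: peaks (with
  MAnorm-style M-values) are assigned to 10-kb promoter windows, summed into
  a per-gene H3K9ac score X₁, combined with the expression fold-change X₂
  through the interaction effect IE = γ₀ + γ₁X₁ + γ₂X₂ + γ₃X₁X₂ (defaults
  γ₀ = 0, γ₁ = γ₂ = γ₃ = 1), and selected by IE z-score > 0, with a
  random-gamma robustness check;
- **`preprocess`** — quantile normalization, probe→gene averaging, homolog
  mapping;
- **`synthetic`** — seeded generators for every stage (graded cohorts with
  known per-gene β, two-group designs, peak landscapes), so the whole
  pipeline is testable without any download;
- **`io` / `cli`** — TSV/GMT/GTF/BED-like readers and a thin `ordgene`
  command (`simulate`, `screen`, `deg`, `enrich`, `integrate`, `robustness`).

## Worked example

```python
from ordgene import screen_genes, simulate_ordinal_cohort, split_and_rank

expr, phenotype, truth = simulate_ordinal_cohort(
    n_genes=500, n_samples=70, pag_fraction=0.05, seed=20
)
table = screen_genes(expr, phenotype, p_threshold=1e-6, params="slope")
up, down = split_and_rank(table)
print(table.attrs["summary"])
```

Running `python examples/01_screen_severity_cohort.py` prints:

```
cohort: 500 genes x 70 samples, grade counts [38, 16, 10, 6]
strict all-parameters rule: 0 PAGs (conservative when a latent threshold is near zero)
slope-test rule, p<1e-6: 25 PAGs (14 up, 11 down) out of 500 fitted genes

top 5 upregulated PAGs (expression rises with severity):
         beta  se_beta  p_slope  rank_global
gene_id
g00260   3.53    0.559 2.64e-10            3
g00311   3.43    0.593 7.41e-09            4
g00434   2.83    0.493 9.89e-09            7
g00204   2.62    0.413 2.03e-10            8
g00191   2.56    0.421  1.1e-09            9

recovered 25/25 truly grade-associated genes with 0 false calls
```

The 70-sample cohort mimics a severity-graded brain collection (32 controls +
38 patients over four grades). Each listed gene's `beta` is its slope on the
latent severity scale per unit log-expression; `p_slope` is the two-tailed
Wald test of β = 0; `rank_global` orders all PAGs by |β|. The simulation
plants 25 genes with |β| ≥ 1.5 and the screen recovers all of them with no
false call at p < 10⁻⁶.

The other example scripts show the PAG-vs-DEG contrast
(`02_pags_vs_degs.py`), enrichment scoring (`03_gene_set_enrichment.py`) and
the H3K9ac interaction-effect ranking (`04_h3k9ac_interaction.py`). The same
steps are available from the shell, e.g.:

```bash
ordgene simulate --out-dir demo --n-genes 300 --seed 5
ordgene screen --expression demo/expression.tsv --metadata demo/metadata.tsv \
    --p-threshold 1e-6 --params slope --out demo/pags.tsv
```

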