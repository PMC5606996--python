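# Methods

## The ordinal screening model

For each gene independently, log-scale expression x is tied to an ordered
severity grade Y ∈ {0, …, k} by a cumulative-link model under the
proportional-odds assumption:

    P(Y ≤ i | x) = F(αᵢ − βx),   i = 1, …, k,
    α₁ < α₂ < … < α_k.

The default link is the probit, F = Φ, equivalent to a latent variable
z\* = βx + ε with ε ~ N(0,1) thresholded at the αᵢ; a logit link is
available. The sign convention αᵢ − βx (rather than αᵢ + βx) is the standard
cumulative-link parameterization: it makes β > 0 mean "expression rises with
grade", so upregulated genes have positive slopes. The two forms differ only
by the sign of β and are otherwise the same model.

Assumptions worth stating explicitly:

- **Proportional odds**: one slope β is shared by all k category boundaries.
  This is what forces a called gene to change *consistently* across the whole
  severity range and is the reason the screen is less sensitive than a binary
  contrast to late-stage cell-type composition shifts.
- **Single covariate, no adjustment**: the model is fit per gene on
  expression alone (no age/sex covariates, no survival component).
- **Ordinal, not interval, grades**: only the ordering of the categories is
  used; a grade of 4 is never treated as "twice" a grade of 2.

### Estimation

Parameters are estimated by direct maximum likelihood. The ordering
constraint is enforced by optimizing over (α₁, log gap₂, …, log gap_k, β);
the negative log-likelihood and its analytic gradient are minimized by BFGS
and then polished with damped Newton steps (finite-difference Hessian of the
analytic gradient) until the gradient infinity norm is below `tol` (default
1e-8). Initialization is deterministic: αᵢ⁰ = F⁻¹(cumulative category
frequency), β⁰ = 0; nothing in the fit is randomized. Observed levels are
recoded to a contiguous 0..k (an intercept for an unobserved boundary is not
identifiable).

Standard errors come from the inverse observed information, computed by
central finite differences of the analytic gradient at the MLE in the natural
(α, β) parameterization. Each parameter gets a two-tailed Wald z-test of
zero. Degenerate situations are handled conservatively:

- constant-expression genes are refused (the slope is unidentifiable) and
  skipped by the matrix screen with a logged count — never counted as PAGs;
- an observation with category probability exactly 0 makes the (exact)
  negative log-likelihood +∞ by definition; the optimizer itself works on a
  clipped version (p ≥ 1e-12) so it can move away from such regions;
- (quasi-)separation — a diverging slope (|β̂|·sd(x) > 25) or a
  non-invertible information matrix — flags the fit and sets all p-values to
  the conservative value 1;
- non-converged fits are excluded from calling and counted in the summary.

In tests, the fit is cross-checked against two independent routes it never
uses internally: a dense grid-search oracle on the NLL surface, and
statsmodels' `OrderedModel`/`Probit` (the k = 1 cumulative model *is* binary
probit regression, up to the intercept sign).

### Calling, orientation, ranking

A gene is a phenotype-associated gene (PAG) when its Wald tests pass
`p_threshold` (default 1e-6, deliberately stringent because no
multiple-testing correction is applied at this stage; BH-adjusted slope
p-values are emitted alongside for transparency). Two readings of "all the
fitted parameters" are exposed:

- `params="all"` (default): every intercept **and** the slope must pass.
  Note this rule is conservative in a way that depends on the *grade mix*,
  not on effect size: a latent threshold whose true value is ≈ 0 (i.e. a
  cumulative grade fraction near ½) can never yield a significant Wald test.
  With the default cohort margins (46% controls) the first threshold sits at
  −0.11, so under this rule the screen calls essentially nothing — the
  behavior is demonstrated, not hidden, in `examples/01`.
- `params="slope"`: only β is tested. This is the reading under which the
  screen has the expected power (the slope is also the only parameter with a
  scientific interpretation here), and it is what the power-oriented tests
  and the acceptance recall use.

PAGs are split by sign(β) into up/down lists and ranked by |β| descending;
ties break by smaller slope p, then lexicographic gene id (an arbitrary but
deterministic rule). Screening is permutation-invariant in genes and samples,
invariant under order-preserving relabeling of the grades, and reversing the
grade order exactly negates β̂ and swaps the up/down sets — all asserted as
tests.

The default grade mapping shipped for Huntington's-style metadata collapses
{control, grade 0–4} to four levels {0, 1, 2, 3} with grades 0–1 and 3–4
merged. This is an editable configuration (YAML `order` + `levels`), not a
published table; any order-preserving collapse is accepted and validated.

## The binary comparator

The disease-vs-control contrast uses an empirical-Bayes moderated t-test:
per-gene pooled variance s² (df d = n₁ + n₂ − 2) is shrunk to
s̃² = (d₀s₀² + ds²)/(d₀ + d) and t = Δmean / (s̃·√(1/n₁ + 1/n₂)) is referred
to a t distribution with d₀ + d df. When not supplied, (d₀, s₀²) are
estimated from the ensemble of log-variances by moment matching: under an
inverse-χ² prior, var(log s²) − ψ′(d/2) = ψ′(d₀/2), solved with a Newton
inverse-trigamma, and the mean of log s² fixes s₀². d₀ = 0 recovers the
ordinary pooled t exactly (a test pins this); d₀ → ∞ gives a z-statistic with
fully shared variance. "Corrected" p-values are Benjamini–Hochberg by default
(Bonferroni by flag). No numeric identity with any particular R
implementation is promised; correctness is established against formula and
simulation oracles (type-I error ≈ nominal on null genes).

## Enrichment score

For a term with K members in a background of N genes and k hits in a target
list of n: upper-tail hypergeometric p (`scipy.stats.hypergeom.sf(k−1, N, K,
n)`) and enrichment score (k/n)/(K/N) ≥ 0, the relative frequency of term
genes in the target versus the background. Gene sets are taken as given from
GMT (no ontology propagation); members are intersected with the background
before testing; terms with k = 0 are dropped. The background defaults to the
set of genes actually fitted in the screen and is overridable. Score
distributions are compared by a two-tailed Welch t-test, with means and SDs
reported.

## H3K9ac interaction effect

Coordinates are 0-based half-open throughout. A differential peak [s, e) is
assigned to a gene when it overlaps the promoter window [tss − w, tss + w)
(default w = 10 kb, symmetric; asymmetric windows are strand-oriented via
flags). One peak may serve several genes. The gene's H3K9ac score X₁ is the
sum of assigned M-values (so splitting a peak into adjacent pieces with the
same total M leaves the score unchanged); genes with no assigned peak leave
the candidate set. Strand is recorded but does not affect the default
symmetric window. The M-value sign convention (treated − untreated or the
reverse) is the caller's assertion; the package only sums what it is given.

Candidates (upregulated genes, X₂ > 0, with ≥ 1 promoter peak) get
IE = γ₀ + γ₁X₁ + γ₂X₂ + γ₃X₁X₂ with defaults γ₀ = 0 (an additive shift
cannot change ranks) and γ₁ = γ₂ = γ₃ = 1. IE_Z standardizes IE across the
candidate set using the population SD (ddof = 0; sample SD by flag), and
selection is the *strict* inequality IE_Z > 0 — a gene exactly at the mean is
not selected. IE_Z, and hence the selected set, is invariant under any
positive affine map of IE, in particular under common positive scaling of
(γ₁, γ₂, γ₃) with γ₀ = 0 and under any γ₀.

`gamma_robustness` re-draws (γ₁, γ₂, γ₃) — independent U(0.5, 2) by default,
any sampler injectable, seeded — for 100 iterations and reports the fraction
whose selected set is *identical* to the default-gamma set. This fraction is
meaningful only when the candidate IE values are well separated: with a
diffuse, unimodal IE distribution, genes near the boundary flip and the
fraction is modest by construction. The acceptance scenario therefore encodes
two separated candidate classes (weak vs strong concordant acetylation gain
and upregulation), under which the selection is fully stable.

## Synthetic data

`simulate_ordinal_cohort` emulates a severity-graded postmortem cohort:

- **n = 70 samples** with grade fractions (32, 13, 13, 12)/70 — 32 controls
  plus 38 patients spread over three pooled grade groups;
- **σₓ = 1** log-scale expression SD, zero baseline (an additive baseline is
  available; it only shifts the intercepts);
- **pag_fraction = 0.05** of genes truly associated (of the order of the few
  percent a genome-wide screen calls), with |β| ~ U(1.5, 3) and random sign —
  1.5 is the smallest slope the screen is expected to detect reliably at this
  n and threshold, which the power tests then verify.

One shared grade vector is drawn per cohort (a fixed case-control-style
design); expression for associated genes is then drawn *conditionally on the
grade* by exact rejection sampling from p(x | Y = y) under the latent-probit
joint. To keep a single grade vector exactly consistent across genes with
different slopes, the base thresholds a (with Φ(a) the cumulative grade
fractions) are rescaled per gene to αg = a·√(1 + βg²σₓ²), making the marginal
grade distribution β-invariant. Conditioning on the grade margins does not
change the β estimand, which the recovery and coverage tests confirm
empirically (bias < 2%, Wald coverage ≈ 95%).

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: probe-level noise and normalization artifacts,
correlated genes (every simulated gene is independent), cell-type composition
drift with disease stage, batch effects, and non-monotone expression–severity
relationships. The generators for the other stages are similarly idealized
(Gaussian two-group design with mean shifts; non-overlapping promoter
windows with decoy peaks placed strictly outside every window).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale, chosen
to make the statistical assertions sharp while staying light: 10⁴ null genes
at n = 70 for calibration (binomial SE ≈ 0.002 on a 5% rate), 500 replicate
cohorts at n = 1000 for recovery/coverage, 10³ genes for recall, a
three-stage grid (step 0.02 → 0.001 → 2·10⁻⁵) for the MLE oracle. A full
acceptance run takes roughly a minute on one CPU.

Numerical details fixed by design: gradient tolerance 1e-8 with Newton
polish; likelihood clipping at 1e-12 inside the optimizer only; quantile
normalization resolves ties by assigning the mean of the reference values the
tied run spans (dialects differ here, so the choice is pinned by a test);
BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
hypergeometric tails and t/Welch distributions come from scipy. Seeds: every
stochastic routine takes an explicit seed or `numpy.random.Generator`; fixed
seeds reproduce outputs bit-for-bit.

## Known limitations

- Per-gene fits ignore gene–gene correlation; the PAG p-values are marginal.
- The all-parameters calling rule conflates grade-margin geometry with
  effect strength (see above); the slope rule is the recommended default for
  power, and both are exposed.
- No multiple-testing correction is applied to PAG calling itself (the
  stringent raw threshold stands in for it); BH-adjusted slope p-values are
  provided for users who prefer an FDR view.
- The moderated-t hyperparameter fit uses log-variance moments, which is
  slightly less efficient than a full F-distribution fit when d is tiny.
- GTF promoter extraction keeps one TSS per gene (the 5'-most transcript
  start); alternative promoters are not modeled.
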