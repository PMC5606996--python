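"""Synthetic data with the statistical structure each analysis stage assumes.

The ordinal cohort generator emulates a postmortem severity-graded cohort:
one shared grade vector per cohort (a fixed case-control-style design, 32
controls + 38 graded patients by default), log-scale expression with unit SD,
and a small fraction of genes whose expression tracks the grade through the
latent cumulative-probit relation ``z* = beta * x + eps``, ``eps ~ N(0, 1)``,
thresholded at per-gene boundaries ``alpha``.

Expression for associated genes is drawn *conditionally on the grade* (exact
rejection sampling from ``p(x | Y = y)``), mirroring a design in which the
grade strata are fixed by sample collection.  To keep one shared grade vector
exactly consistent across genes with different slopes, the base thresholds
``a`` (on the marginal-probability scale) are rescaled per gene to
``alpha_g = a * sqrt(1 + beta_g^2 * sigma_x^2)``, which makes the marginal
grade distribution ``Phi(a)`` identical for every gene.  Conditioning changes
the likelihood only through the grade margins, not the ``beta`` estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .model_core import OrdinalPhenotype

__all__ = [
    "SimTruth",
    "DEFAULT_GRADE_FRACTIONS",
    "simulate_ordinal_cohort",
    "simulate_two_groups",
    "simulate_peak_landscape",
]

#: Default grade mix: 32 controls and 38 patients split over three grade
#: groups, echoing a 70-sample severity-graded brain cohort.
DEFAULT_GRADE_FRACTIONS = np.array([32, 13, 13, 12], dtype=float) / 70.0


@dataclass
class SimTruth:
    """Ground truth of a simulated ordinal cohort (bit-reproducible per seed)."""

    beta: np.ndarray            # per-gene true slope (0 for null genes)
    is_pag: np.ndarray          # per-gene true association flag
    alphas: np.ndarray          # per-gene latent thresholds, shape (n_genes, k)
    base_alphas: np.ndarray     # thresholds on the marginal scale, shape (k,)
    grade_fractions: np.ndarray
    sigma_x: float
    seed: object


def _conditional_expression(
    rng: np.random.Generator,
    grades: np.ndarray,
    beta: float,
    alphas_g: np.ndarray,
    sigma_x: float,
    n_levels: int,
    batch: int = 4096,
    max_draws: int = 2_000_000,
) -> np.ndarray:
    """Exact draws from p(x | Y = y) by rejection from the latent joint."""
    need = np.bincount(grades, minlength=n_levels)
    pools = [[] for _ in range(n_levels)]
    drawn = 0
    while any(len(pools[j]) < need[j] for j in range(n_levels)):
        if drawn > max_draws:
            raise RuntimeError(
                "conditional sampler exhausted its draw budget; the requested "
                "grade mix is too improbable under the given thresholds"
            )
        xb = rng.normal(0.0, sigma_x, size=batch)
        zb = beta * xb + rng.normal(0.0, 1.0, size=batch)
        yb = np.searchsorted(alphas_g, zb)
        drawn += batch
        for j in range(n_levels):
            if len(pools[j]) < need[j]:
                pools[j].extend(xb[yb == j][: need[j] - len(pools[j])])
    x = np.empty(grades.size)
    taken = np.zeros(n_levels, dtype=int)
    for i, y in enumerate(grades):
        x[i] = pools[y][taken[y]]
        taken[y] += 1
    return x


def simulate_ordinal_cohort(
    n_genes: int,
    n_samples: int = 70,
    n_levels: int = 4,
    pag_fraction: float = 0.05,
    beta_range=(1.5, 3.0),
    alphas=None,
    grade_fractions=None,
    sigma_x: float = 1.0,
    baseline: float = 0.0,
    seed=None,
):
    """Simulate an expression matrix tied to an ordinal severity grade.

    Parameters
    ----------
    n_genes, n_samples, n_levels : cohort dimensions.
    pag_fraction : fraction of genes truly associated with the grade.
    beta_range : (lo, hi); associated genes get ``|beta| ~ U(lo, hi)`` with a
        random sign.
    alphas : optional explicit base thresholds (length ``n_levels - 1``,
        strictly increasing, on the marginal scale: the cohort's grade
        probabilities are ``diff(Phi(alphas))``).  Overrides
        ``grade_fractions``.
    grade_fractions : optional level probabilities (length ``n_levels``);
        default 32/13/13/12 out of 70.
    sigma_x : SD of log-scale expression.
    baseline : additive per-cohort expression offset.
    seed : anything accepted by ``numpy.random.default_rng``.

    Returns
    -------
    (expression DataFrame genes x samples, OrdinalPhenotype, SimTruth)
    """
    if not 0 <= pag_fraction <= 1:
        raise ValueError("pag_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = n_levels - 1
    if alphas is not None:
        base_alphas = np.asarray(alphas, dtype=float)
        if base_alphas.size != k:
            raise ValueError(f"alphas must have length {k}")
        if np.any(np.diff(base_alphas) <= 0):
            raise ValueError("alphas must be strictly increasing")
        from scipy.special import ndtr
        cum = ndtr(base_alphas)
        fractions = np.diff(np.concatenate([[0.0], cum, [1.0]]))
        if np.any(fractions <= 0):
            raise ValueError("alphas imply an empty ordinal category")
    else:
        fractions = (
            DEFAULT_GRADE_FRACTIONS
            if grade_fractions is None
            else np.asarray(grade_fractions, dtype=float)
        )
        if fractions.size != n_levels:
            raise ValueError(f"grade_fractions must have length {n_levels}")
        fractions = fractions / fractions.sum()
        base_alphas = ndtri(np.cumsum(fractions[:-1]))

    grades = rng.choice(n_levels, size=n_samples, p=fractions)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    betas = np.zeros(n_genes)
    n_pag = int(round(pag_fraction * n_genes))
    pag_idx = rng.choice(n_genes, size=n_pag, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_pag)
    betas[pag_idx] = signs * rng.uniform(beta_range[0], beta_range[1], size=n_pag)
    is_pag = betas != 0

    scale = np.sqrt(1.0 + betas**2 * sigma_x**2)
    alphas_per_gene = base_alphas[None, :] * scale[:, None]

    values = np.empty((n_genes, n_samples))
    for g in range(n_genes):
        if betas[g] == 0.0:
            values[g] = rng.normal(0.0, sigma_x, size=n_samples)
        else:
            values[g] = _conditional_expression(
                rng, grades, betas[g], alphas_per_gene[g], sigma_x, n_levels
            )
    values += baseline

    expression = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"
    phenotype = (
        OrdinalPhenotype(sample_ids, grades, [f"grade_{i}" for i in range(n_levels)])
        if n_samples
        else None
    )
    truth = SimTruth(
        beta=betas,
        is_pag=is_pag,
        alphas=alphas_per_gene,
        base_alphas=base_alphas,
        grade_fractions=fractions,
        sigma_x=sigma_x,
        seed=seed,
    )
    return expression, phenotype, truth


def simulate_two_groups(
    n_genes: int,
    n_per_group: int = 10,
    de_fraction: float = 0.1,
    effect_size: float = 1.0,
    sigma: float = 1.0,
    baseline: float = 8.0,
    seed=None,
):
    """Gaussian log-expression for a two-group (disease vs control) design.

    DE genes are mean-shifted by ``+/- effect_size`` (same units as ``sigma``)
    in the second group.  Returns ``(expression, labels, truth)`` where truth
    has per-gene ``true_lfc`` and ``is_de``.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"ctrl_{i}" for i in range(n_per_group)] + [
        f"case_{i}" for i in range(n_per_group)
    ]
    labels = pd.Series(
        ["control"] * n_per_group + ["case"] * n_per_group, index=samples
    )
    shifts = np.zeros(n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    shifts[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * effect_size
    values = baseline + rng.normal(0.0, sigma, size=(n_genes, 2 * n_per_group))
    values[:, n_per_group:] += shifts[:, None]
    expression = pd.DataFrame(values, index=gene_ids, columns=samples)
    expression.index.name = "gene_id"
    truth = pd.DataFrame(
        {"true_lfc": shifts, "is_de": shifts != 0},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return expression, labels, truth


def simulate_peak_landscape(
    n_genes: int = 50,
    peaks_per_gene=(0, 3),
    m_value_loc: float = 0.5,
    m_value_scale: float = 1.0,
    window: int = 10000,
    n_decoys: int = 20,
    seed=None,
):
    """Random promoter/peak layout with known per-gene summed M-values.

    Genes are spaced ``10 * window`` apart so windows never overlap; true
    peaks land fully inside each gene's ``tss +/- window``; decoy peaks land in
    the gaps, outside every window.  Returns ``(peaks, promoters, truth)``
    where truth is a Series of true summed M-values for genes with >= 1 peak.
    """
    rng = np.random.default_rng(seed)
    spacing = 10 * window
    promoters = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "chrom": ["chr1"] * n_genes,
            "tss": [spacing * (i + 1) for i in range(n_genes)],
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )
    lo, hi = peaks_per_gene
    counts = rng.integers(lo, hi + 1, size=n_genes)
    rows, truth = [], {}
    for i, (tss, c) in enumerate(zip(promoters["tss"], counts)):
        if c == 0:
            continue
        total = 0.0
        for _ in range(c):
            length = int(rng.integers(100, 800))
            start = int(rng.integers(tss - window, tss + window - length))
            m = float(rng.normal(m_value_loc, m_value_scale))
            rows.append(("chr1", start, start + length, m))
            total += m
        truth[promoters["gene_id"].iloc[i]] = total
    for _ in range(n_decoys):
        gene = int(rng.integers(0, n_genes))
        tss = int(promoters["tss"].iloc[gene])
        length = int(rng.integers(100, 800))
        # strictly between this window's end and the next window's start
        start = int(rng.integers(tss + window + 100, tss + spacing - window - length - 100))
        rows.append(("chr1", start, start + length, float(rng.normal(0, 1))))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "m_value"])
    return peaks, promoters, pd.Series(truth, name="true_x1", dtype=float)
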