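"""Binary disease-vs-control comparator: empirical-Bayes moderated t-test.

This is the two-group contrast against which the ordinal screen is compared.
Per gene, the pooled variance ``s^2`` (residual df ``d = n1 + n2 - 2``) is
shrunk toward a prior ``s0^2`` with prior df ``d0``::

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t = (mean_2 - mean_1) / (s_tilde * sqrt(1/n1 + 1/n2)),   df = d0 + d

When ``d0``/``s0^2`` are not supplied they are estimated from the ensemble of
per-gene variances by matching the moments of ``log s^2`` (under the scaled-F
marginal implied by an inverse-chi-square prior on the true variances).
``d0 = 0`` recovers the ordinary pooled t-test exactly; ``d0 -> inf`` gives a
z-like statistic with fully shared variance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

_log = logging.getLogger(__name__)

__all__ = [
    "moderated_two_group_test",
    "bh_adjust",
    "overlap_stats",
    "trigamma_inverse",
]


def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for ``x > 0`` by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _estimate_prior(s2: np.ndarray, d: int):
    """Moments-on-log-variances fit of (d0, s0^2) from per-gene variances."""
    z = np.log(s2)
    e_const = digamma(d / 2.0) - np.log(d / 2.0)
    if z.size < 2:
        return np.inf, float(np.exp(np.mean(z) - e_const))
    excess = np.var(z, ddof=1) - polygamma(1, d / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = np.mean(z) - e_const
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        log_s0 = np.mean(z) - e_const + digamma(d0 / 2.0) - np.log(d0 / 2.0)
    return d0, float(np.exp(log_s0))


def moderated_two_group_test(
    expression: pd.DataFrame,
    labels,
    d0: float | None = None,
    s0sq: float | None = None,
    p_threshold: float = 0.001,
    group_order=None,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per gene between two sample groups.

    Parameters
    ----------
    expression : DataFrame, genes x samples (log scale).
    labels : array-like aligned with the columns; exactly two distinct values,
        each with at least 2 samples.
    d0, s0sq : prior df and prior variance; estimated from the data when None.
        ``d0 = 0`` gives the ordinary pooled two-sample t-test.
    p_threshold : DEG threshold on the adjusted p-value.
    group_order : optional pair (reference, treatment); the reported ``logfc``
        is ``mean(treatment) - mean(reference)``.  Defaults to sorted labels.
    correction : ``"fdr_bh"`` (default) or ``"bonferroni"``.

    Returns a DataFrame indexed by gene with columns ``logfc, s2, s2_post, t,
    df, p, p_adj, is_deg, zero_variance``; the hyperparameters used are in
    ``.attrs["prior"]``.
    """
    labels = np.asarray(labels)
    if labels.size != expression.shape[1]:
        raise ValueError("labels must align with expression columns")
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if group_order is None:
        group_order = uniq
    g_ref, g_trt = group_order
    m1 = labels == g_ref
    m2 = labels == g_trt
    n1, n2 = int(m1.sum()), int(m2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")

    a = expression.loc[:, m1].to_numpy(dtype=float)
    b = expression.loc[:, m2].to_numpy(dtype=float)
    mean1 = a.mean(axis=1)
    mean2 = b.mean(axis=1)
    d = n1 + n2 - 2
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / d
    zero_var = s2 <= 0

    if d0 is None or s0sq is None:
        if np.any(~zero_var):
            est_d0, est_s0 = _estimate_prior(s2[~zero_var], d)
        else:
            est_d0, est_s0 = np.inf, np.nan
        d0 = est_d0 if d0 is None else d0
        s0sq = est_s0 if s0sq is None else s0sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d
    logfc = mean2 - mean1
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / denom
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_var & (s2_post <= 0), np.nan, p)

    table = pd.DataFrame(
        {
            "logfc": logfc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df": df_total,
            "p": p,
            "zero_variance": zero_var,
        },
        index=expression.index,
    )
    ok = np.isfinite(table["p"].to_numpy())
    p_adj = np.full(len(table), np.nan)
    if ok.any():
        if correction == "fdr_bh":
            p_adj[ok] = bh_adjust(table.loc[ok, "p"].to_numpy())
        elif correction == "bonferroni":
            p_adj[ok] = np.minimum(table.loc[ok, "p"].to_numpy() * ok.sum(), 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
    table["p_adj"] = p_adj
    table["is_deg"] = np.where(np.isfinite(p_adj), p_adj < p_threshold, False)
    table.attrs["prior"] = {"d0": float(d0), "s0sq": float(s0sq), "d": d}
    n_deg = int(table["is_deg"].sum())
    _log.info(
        "moderated test: d0=%.4g s0^2=%.4g, %d/%d DEGs at adjusted p<%g",
        d0, s0sq, n_deg, len(table), p_threshold,
    )
    return table


def bh_adjust(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone-enforced)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def overlap_stats(set_a, set_b, universe_size: int):
    """Intersection of two gene sets plus its upper-tail hypergeometric p.

    ``p = P(|A ∩ B| >= k)`` when drawing ``|B|`` genes from a universe of
    ``universe_size`` containing ``|A|`` marked genes.
    """
    set_a, set_b = set(set_a), set(set_b)
    if len(set_a | set_b) > universe_size:
        raise ValueError("universe smaller than the union of the two sets")
    inter = sorted(set_a & set_b)
    k = len(inter)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(set_a), len(set_b)))
    return inter, p
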