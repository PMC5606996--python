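"""Gene-set over-representation and enrichment-score comparison.

For each term with members ``K`` in a background of ``N`` genes and a target
list of ``n`` genes overlapping the term in ``k`` genes:

* upper-tail hypergeometric p-value of the overlap,
* enrichment score ``(k / n) / (K / N)`` — the frequency of term genes in the
  target list relative to their frequency in the background.

Two score distributions (e.g. over the terms enriched in two competing gene
lists) are compared by a two-tailed Welch t-test.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

_log = logging.getLogger(__name__)

__all__ = ["enrich", "compare_score_distributions", "ScoreComparison"]


def enrich(
    target_genes,
    background_genes,
    gene_sets: dict,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_sets`` in the target list.

    Parameters
    ----------
    target_genes : iterable of gene ids; must be a subset of the background.
    background_genes : iterable of gene ids (the tested universe).
    gene_sets : mapping term_id -> member iterable, or term_id ->
        (description, members) as produced by ``io.read_gmt``.
    p_cutoff : significance cutoff on the BH-adjusted p-value.

    Returns a DataFrame (one row per term with overlap ``k >= 1``) with
    columns ``description, k, n, K, N, enrichment_score, p, p_adj,
    significant``, sorted by p-value.
    """
    background = set(background_genes)
    target = set(target_genes)
    if not target <= background:
        raise ValueError(
            f"target genes not in background: {sorted(target - background)[:5]} ..."
        )
    columns = ["description", "k", "n", "K", "N", "enrichment_score", "p",
               "p_adj", "significant"]
    if not target:
        warnings.warn("enrich: empty target list")
        empty = pd.DataFrame(columns=columns)
        empty.index.name = "term_id"
        return empty
    n, N = len(target), len(background)
    rows = []
    for term_id, members in gene_sets.items():
        if isinstance(members, tuple) and len(members) == 2:
            description, genes = members
        else:
            description, genes = "", members
        genes = set(genes) & background
        if not genes:
            continue
        K = len(genes)
        k = len(genes & target)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "description": description,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "enrichment_score": (k / n) / (K / N),
                "p": float(stats.hypergeom.sf(k - 1, N, K, n)),
            }
        )
    if not rows:
        empty = pd.DataFrame(columns=columns)
        empty.index.name = "term_id"
        return empty
    result = pd.DataFrame(rows).set_index("term_id")
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["p_adj"] < p_cutoff
    return result.sort_values("p", kind="mergesort")


class ScoreComparison(NamedTuple):
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float


def compare_score_distributions(scores_a, scores_b) -> ScoreComparison:
    """Welch two-tailed t-test comparing two enrichment-score vectors.

    Means and standard deviations are reported alongside the test.  If both
    vectors have zero variance and equal means, ``t = 0, p = 1``.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each score list needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return ScoreComparison(a.mean(), b.mean(), 0.0, 0.0, 0.0, 1.0)
        return ScoreComparison(a.mean(), b.mean(), 0.0, 0.0, np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ScoreComparison(
        float(a.mean()), float(b.mean()),
        float(a.std(ddof=1)), float(b.std(ddof=1)),
        float(t), float(p),
    )
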