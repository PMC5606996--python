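"""H3K9ac / expression integration.

Differential ChIP-seq peaks (with MAnorm-style M-values, the log-ratio of
normalized peak intensity between two conditions) are assigned to genes whose
promoter window they overlap.  Per gene:

* ``X1`` — H3K9ac score: sum of M-values of the peaks in the promoter window,
* ``X2`` — expression log2 fold-change between the same two conditions,
* interaction effect ``IE = g0 + g1*X1 + g2*X2 + g3*X1*X2`` with defaults
  ``g0 = 0`` (rank-invariant) and ``g1 = g2 = g3 = 1``,
* ``IE_Z`` — z-score of IE across the candidate genes; ``IE_Z > 0`` (strict)
  selects the primary candidates.

``gamma_robustness`` re-draws the gamma weights (default independent
U(0.5, 2)) and reports how often the selected set is identical to the
default-gamma set.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

_log = logging.getLogger(__name__)

__all__ = [
    "assign_peaks",
    "h3k9ac_score",
    "h3k9ac_scores",
    "interaction_effect",
    "gamma_robustness",
]


def assign_peaks(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    window: int = 10000,
    window_upstream: int | None = None,
    window_downstream: int | None = None,
) -> dict:
    """Map each gene to the peaks overlapping its promoter window.

    Coordinates are 0-based half-open.  The default window is the symmetric
    ``[tss - window, tss + window)``; pass ``window_upstream`` /
    ``window_downstream`` for an asymmetric window, which is oriented by the
    gene's strand.  A peak ``[s, e)`` is assigned iff it overlaps the window
    (``s < win_end and e > win_start``); one peak may serve several genes.

    Parameters
    ----------
    peaks : DataFrame with columns ``chrom, start, end, m_value``.
    promoters : DataFrame with columns ``gene_id, chrom, tss, strand``.

    Returns
    -------
    dict gene_id -> sorted list of peak row positions (integer indices into
    ``peaks``).  Genes without any assigned peak are absent from the dict.
    """
    up = window if window_upstream is None else window_upstream
    down = window if window_downstream is None else window_downstream
    bad = peaks["start"] >= peaks["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} peaks have start >= end")
    if not np.all(np.isfinite(peaks["m_value"])):
        raise ValueError("non-finite M-values")
    if len(peaks) and len(promoters):
        shared = set(peaks["chrom"]) & set(promoters["chrom"])
        if not shared:
            warnings.warn(
                "assign_peaks: no chromosome shared between peaks and promoters"
            )
            return {}
    trees = {}
    for pos, (chrom, start, end) in enumerate(
        zip(peaks["chrom"], peaks["start"], peaks["end"])
    ):
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end), pos)
    mapping = {}
    for gene, chrom, tss, strand in zip(
        promoters["gene_id"], promoters["chrom"], promoters["tss"], promoters["strand"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        if strand == "-":
            win_start, win_end = int(tss) - down, int(tss) + up
        else:
            win_start, win_end = int(tss) - up, int(tss) + down
        hits = sorted(iv.data for iv in tree.overlap(win_start, win_end))
        if hits:
            mapping[gene] = hits
    return mapping


def h3k9ac_score(gene, mapping: dict, peaks: pd.DataFrame) -> float:
    """Sum of M-values of the peaks assigned to ``gene``."""
    if gene not in mapping:
        raise KeyError(f"gene {gene!r} has no assigned peaks")
    return float(peaks["m_value"].to_numpy()[mapping[gene]].sum())


def h3k9ac_scores(mapping: dict, peaks: pd.DataFrame) -> pd.Series:
    """H3K9ac score per gene with at least one assigned peak."""
    m = peaks["m_value"].to_numpy()
    return pd.Series(
        {gene: float(m[idx].sum()) for gene, idx in mapping.items()},
        name="x1",
        dtype=float,
    )


def interaction_effect(
    x1_vector,
    x2_vector,
    gammas=(0.0, 1.0, 1.0, 1.0),
    gene_ids=None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Interaction-effect statistic and z-score over the candidate genes.

    ``IE = g0 + g1*x1 + g2*x2 + g3*x1*x2`` per gene; ``IE_Z`` standardizes IE
    across the candidates (population SD by default, ``ddof=1`` for sample
    SD).  Candidates are selected when ``IE_Z > 0`` (strict), and the table is
    ranked by ``IE_Z`` descending.
    """
    x1 = np.asarray(x1_vector, dtype=float)
    x2 = np.asarray(x2_vector, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be equal-length 1-D vectors")
    if x1.size < 2:
        raise ValueError("need at least 2 candidate genes to z-score the IE")
    g0, g1, g2, g3 = gammas
    ie = g0 + g1 * x1 + g2 * x2 + g3 * x1 * x2
    sd = ie.std(ddof=ddof)
    if sd == 0:
        warnings.warn("interaction_effect: IE has zero spread; no gene selected")
        ie_z = np.zeros_like(ie)
    else:
        ie_z = (ie - ie.mean()) / sd
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(x1.size)]
    table = pd.DataFrame(
        {"x1": x1, "x2": x2, "ie": ie, "ie_z": ie_z, "selected": ie_z > 0},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    table = table.sort_values("ie_z", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _uniform_gamma_sampler(rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.5, 2.0, size=3)


def _selected_mask(x1: np.ndarray, x2: np.ndarray, gammas) -> np.ndarray:
    """Boolean IE_Z > 0 mask in input order (population SD)."""
    g0, g1, g2, g3 = gammas
    ie = g0 + g1 * x1 + g2 * x2 + g3 * x1 * x2
    sd = ie.std()
    if sd == 0:
        return np.zeros(ie.size, dtype=bool)
    return (ie - ie.mean()) / sd > 0


def gamma_robustness(
    x1,
    x2,
    n_iter: int = 100,
    sampler=None,
    seed=None,
    reference_gammas=(0.0, 1.0, 1.0, 1.0),
) -> float:
    """Fraction of random-gamma draws whose selected set equals the default set.

    ``gamma_0`` stays fixed at 0 (it cannot change the ranking); ``sampler``
    draws ``(g1, g2, g3)`` given a ``numpy.random.Generator`` (default:
    independent U(0.5, 2)).  Reproducible under a fixed ``seed``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    rng = np.random.default_rng(seed)
    if sampler is None:
        sampler = _uniform_gamma_sampler
    reference = _selected_mask(x1, x2, reference_gammas)
    n_identical = 0
    for _ in range(n_iter):
        g1, g2, g3 = np.asarray(sampler(rng), dtype=float)
        mask = _selected_mask(x1, x2, (0.0, g1, g2, g3))
        if np.array_equal(mask, reference):
            n_identical += 1
    return n_identical / n_iter
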