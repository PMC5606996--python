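"""Compendium-stage preprocessing: quantile normalization, probe collapse,
homolog mapping.

These operate on probe- or gene-level matrices that have already been
summarized per array (e.g. by RMA); chip-level summarization is out of scope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "collapse_probes", "map_homologs"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every column shares one value distribution.

    The reference distribution is the row-wise mean of the sorted columns.
    Within-column ranks are preserved.  Tied input values receive the mean of
    the reference values their positions span (the "average rank" dialect; the
    tie handling differs between implementations, so it is pinned down here).

    A single-column matrix is returned unchanged with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("quantile normalization requires finite values")
    n_rows, n_cols = values.shape
    if n_cols < 2:
        warnings.warn("quantile_normalize: single column, returning a copy")
        return matrix.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_rows)
        ranked[order] = reference
        # ties: average the reference values spanned by each tied run
        tied = pd.Series(ranked).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_map) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene x sample by averaging probes.

    ``probe_map`` maps probe id -> gene id (dict, Series, or two-column
    DataFrame ``probe_id, gene_id``).  A probe mapping to two genes is an
    error; probes absent from the map are dropped and counted.
    """
    if isinstance(probe_map, pd.DataFrame):
        if probe_map.shape[1] < 2:
            raise ValueError("probe map DataFrame needs (probe_id, gene_id) columns")
        pairs = probe_map.iloc[:, :2].drop_duplicates()
        dup = pairs.iloc[:, 0].duplicated()
        if dup.any():
            raise ValueError(
                f"probes mapped to multiple genes: {pairs.iloc[:, 0][dup].tolist()[:5]}"
            )
        probe_map = dict(zip(pairs.iloc[:, 0], pairs.iloc[:, 1]))
    elif isinstance(probe_map, pd.Series):
        probe_map = probe_map.to_dict()

    genes = matrix.index.map(lambda p: probe_map.get(p))
    keep = genes.notna()
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no probes in the matrix are covered by the probe map")
    if n_dropped:
        _log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    collapsed = matrix.loc[keep].groupby(genes[keep]).mean()
    collapsed.index.name = "gene_id"
    collapsed.attrs["n_unmapped_probes"] = n_dropped
    return collapsed


def map_homologs(gene_list, homology_table) -> list:
    """Map genes across species through a (source_gene, target_gene) table.

    Inner join: unmapped genes are dropped (logged); one-to-many mappings
    expand with a warning.  Duplicate pairs are deduplicated.  Input order is
    preserved, expansions kept adjacent.
    """
    if isinstance(homology_table, pd.DataFrame):
        pairs = homology_table.iloc[:, :2].drop_duplicates()
        table = {}
        for src, tgt in pairs.itertuples(index=False):
            table.setdefault(src, []).append(tgt)
    else:
        table = {k: v if isinstance(v, (list, tuple)) else [v]
                 for k, v in dict(homology_table).items()}
    mapped, n_unmapped, n_expanded = [], 0, 0
    for g in gene_list:
        targets = table.get(g)
        if not targets:
            n_unmapped += 1
            continue
        if len(targets) > 1:
            n_expanded += 1
        mapped.extend(targets)
    if n_unmapped:
        _log.info("map_homologs: %d of %d genes had no homolog",
                  n_unmapped, len(list(gene_list)))
    if n_expanded:
        warnings.warn(f"map_homologs: {n_expanded} genes expanded one-to-many")
    return mapped
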