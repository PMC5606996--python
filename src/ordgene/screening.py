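"""Per-gene ordinal screening: grade mapping, PAG calling, orientation, ranking.

A phenotype-associated gene (PAG) is a gene whose cumulative-link fit against
the ordinal severity grade passes a Wald-test threshold.  By default *all*
fitted parameters (the ``k`` intercepts and the slope) must each have
two-tailed ``p < p_threshold``; the alternative reading, slope-only, is
available via ``params="slope"``.  PAGs are oriented by the sign of the slope
(``beta > 0`` up with severity, ``beta < 0`` down) and ranked by ``|beta|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import OrdinalPhenotype, fit_cumulative_link
from .diffexp import bh_adjust

_log = logging.getLogger(__name__)

__all__ = [
    "GradeMapping",
    "DEFAULT_HD_MAPPING",
    "map_grades_to_categories",
    "screen_genes",
    "split_and_rank",
]


@dataclass
class GradeMapping:
    """An order-preserving map from raw grade labels to ordinal levels.

    ``order`` lists the raw labels from least to most severe; ``levels`` maps
    each raw label to its (possibly collapsed) integer category.  The map must
    be monotone non-decreasing along ``order``.
    """

    order: Sequence[str]
    levels: Mapping[str, int]

    def __post_init__(self):
        missing = [lab for lab in self.order if lab not in self.levels]
        if missing:
            raise ValueError(f"labels in order but not in levels: {missing}")
        vals = [self.levels[lab] for lab in self.order]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(
                f"mapping violates the label order {list(self.order)}: "
                f"levels {vals} are not non-decreasing"
            )

    @classmethod
    def from_dict(cls, d) -> "GradeMapping":
        if isinstance(d, GradeMapping):
            return d
        if "order" in d and "levels" in d:
            return cls(order=list(d["order"]), levels=dict(d["levels"]))
        # plain {label: level}; insertion order is taken as the label order
        return cls(order=list(d), levels=dict(d))


#: Default Huntington's-disease mapping of controls + Vonsattel grades 0-4 to
#: four ordinal categories.  This collapse is a configurable assumption, not a
#: published table; edit it to match your cohort's metadata.
DEFAULT_HD_MAPPING = GradeMapping(
    order=["control", "grade0", "grade1", "grade2", "grade3", "grade4"],
    levels={
        "control": 0,
        "grade0": 1,
        "grade1": 1,
        "grade2": 2,
        "grade3": 3,
        "grade4": 3,
    },
)


def map_grades_to_categories(
    raw_grades: Sequence,
    mapping_config,
    sample_ids: Sequence[str] | None = None,
) -> OrdinalPhenotype:
    """Map raw grade labels to contiguous ordinal categories ``0..k``.

    Raises a ``ValueError`` naming the offending sample if a raw grade is not
    covered by the mapping, and if the mapping is not order-preserving.
    Collapsed levels are compressed to a contiguous range starting at 0.
    """
    mapping = GradeMapping.from_dict(mapping_config)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(len(raw_grades))]
    coded = []
    for sid, raw in zip(sample_ids, raw_grades):
        key = str(raw)
        if key not in mapping.levels:
            raise ValueError(
                f"sample {sid!r}: raw grade {raw!r} is not covered by the mapping"
            )
        coded.append(int(mapping.levels[key]))
    coded = np.asarray(coded, dtype=int)
    # compress to contiguous 0..k over observed levels, preserving order
    observed = np.unique(coded)
    coded = np.searchsorted(observed, coded)
    label_by_level = {}
    for lab in mapping.order:
        label_by_level.setdefault(mapping.levels[lab], []).append(lab)
    level_labels = [
        "|".join(label_by_level.get(lv, [f"level_{lv}"])) for lv in observed
    ]
    pheno = OrdinalPhenotype(
        sample_ids=list(sample_ids), grades=coded, level_labels=level_labels
    )
    counts = pheno.level_counts()
    _log.info(
        "grade mapping: %s",
        ", ".join(f"{lab}: n={c}" for lab, c in zip(level_labels, counts)),
    )
    return pheno


def screen_genes(
    expression: pd.DataFrame,
    phenotype: OrdinalPhenotype,
    link: str = "probit",
    p_threshold: float = 1e-6,
    params: str = "all",
) -> pd.DataFrame:
    """Fit the cumulative-link model per gene and call PAGs.

    Parameters
    ----------
    expression : DataFrame
        Genes as rows, samples as columns (log-scale values assumed).  Columns
        must match the phenotype's sample ids as a set; they are aligned.
    phenotype : OrdinalPhenotype
    link : str
        Link function name (``"probit"`` default).
    p_threshold : float
        PAG calling threshold on the Wald p-values.
    params : str
        ``"all"`` (every intercept and the slope must pass) or ``"slope"``.

    Returns
    -------
    DataFrame indexed by gene id with columns ``beta, se_beta, z_slope,
    p_slope, p_max, q_slope`` (BH-adjusted slope p), ``direction, is_pag,
    rank, converged, separated``.  Non-converged / separated genes are never
    PAGs; constant or non-finite genes are skipped (logged, not in the
    table).  A summary dict of the filter counts is stored in ``.attrs``.
    """
    if params not in {"all", "slope"}:
        raise ValueError("params must be 'all' or 'slope'")
    if phenotype.n_levels < 2:
        raise ValueError("phenotype must have at least 2 levels")
    if set(expression.columns) != set(phenotype.sample_ids):
        raise ValueError(
            "expression columns and phenotype samples differ: "
            f"{sorted(set(expression.columns) ^ set(phenotype.sample_ids))[:5]} ..."
        )
    expr = expression[list(phenotype.sample_ids)]
    grades = phenotype.grades

    rows = []
    n_constant = n_nonfinite = n_nonconverged = n_separated = 0
    for gene, values in expr.iterrows():
        x = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            n_nonfinite += 1
            _log.debug("skipping %s: non-finite values", gene)
            continue
        if np.ptp(x) == 0:
            n_constant += 1
            _log.debug("skipping %s: constant expression", gene)
            continue
        fit = fit_cumulative_link(x, grades, link=link)
        if not fit.converged:
            n_nonconverged += 1
        if fit.separated:
            n_separated += 1
        p_relevant = fit.p_max if params == "all" else fit.p_slope
        rows.append(
            {
                "gene_id": gene,
                "beta": fit.beta,
                "se_beta": fit.se_beta,
                "z_slope": float(fit.z_values[-1]),
                "p_slope": fit.p_slope,
                "p_max": fit.p_max,
                "direction": "up" if fit.beta > 0 else "down",
                "is_pag": bool(
                    fit.converged and not fit.separated and p_relevant < p_threshold
                ),
                "converged": fit.converged,
                "separated": fit.separated,
            }
        )

    if rows:
        table = pd.DataFrame(rows).set_index("gene_id")
        table["q_slope"] = bh_adjust(table["p_slope"].to_numpy())
    else:
        table = pd.DataFrame(
            columns=[
                "beta", "se_beta", "z_slope", "p_slope", "p_max", "direction",
                "is_pag", "converged", "separated", "q_slope",
            ]
        )
        table.index.name = "gene_id"
    table["rank"] = _global_ranks(table)
    summary = {
        "n_genes": int(expression.shape[0]),
        "n_fitted": int(len(table)),
        "n_skipped_constant": n_constant,
        "n_skipped_nonfinite": n_nonfinite,
        "n_nonconverged": n_nonconverged,
        "n_separated": n_separated,
        "n_pags": int(table["is_pag"].sum()) if len(table) else 0,
        "n_up": int((table["is_pag"] & (table["direction"] == "up")).sum())
        if len(table)
        else 0,
        "n_down": int((table["is_pag"] & (table["direction"] == "down")).sum())
        if len(table)
        else 0,
    }
    table.attrs["summary"] = summary
    _log.info("screen summary: %s", summary)
    return table


def _sorted_pags(table: pd.DataFrame) -> pd.DataFrame:
    """PAG rows sorted by |beta| desc, then slope p asc, then gene id."""
    pags = table[table["is_pag"]]
    order = np.lexsort(
        (
            pags.index.astype(str).to_numpy(),
            pags["p_slope"].to_numpy(),
            -pags["beta"].abs().to_numpy(),
        )
    )
    return pags.iloc[order].copy()


def _global_ranks(table: pd.DataFrame) -> pd.Series:
    ranks = pd.Series(np.nan, index=table.index, dtype=float)
    if len(table) and table["is_pag"].any():
        ordered = _sorted_pags(table)
        ranks.loc[ordered.index] = np.arange(1, len(ordered) + 1)
    return ranks


def split_and_rank(pag_table: pd.DataFrame):
    """Partition PAGs by slope sign and rank by ``|beta|`` (descending).

    Ties are broken by smaller slope p-value, then lexicographic gene id.
    Returns ``(up, down)`` DataFrames, each carrying a within-direction
    ``rank`` and the global ``rank_global`` across both directions.
    """
    ordered = _sorted_pags(pag_table)
    ordered["rank_global"] = np.arange(1, len(ordered) + 1)
    up = ordered[ordered["beta"] > 0].copy()
    down = ordered[ordered["beta"] < 0].copy()
    up["rank"] = np.arange(1, len(up) + 1)
    down["rank"] = np.arange(1, len(down) + 1)
    return up, down
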