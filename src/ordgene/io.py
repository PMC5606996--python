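"""Readers/writers for the plain-text formats the pipeline consumes.

All tables are tab-separated with headers; peaks are BED-like TSV with an
M-value column; gene sets are standard GMT; promoters come from a 4-column
TSV or a GTF (TSS derived strand-aware from transcript starts).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "read_gmt",
    "read_peaks",
    "read_promoters",
    "read_grade_mapping_yaml",
]


@dataclass
class RunConfig:
    """Pipeline-wide configuration with the default thresholds.

    ``pag_p`` — Wald threshold for phenotype-associated genes; ``deg_p`` —
    adjusted-p threshold for the binary comparator; ``enrich_p`` — adjusted-p
    cutoff for over-represented terms; ``window`` — promoter half-window in
    bp; ``gammas`` — IE weights; ``n_iter`` — robustness iterations.
    """

    link: str = "probit"
    pag_p: float = 1e-6
    pag_params: str = "all"
    deg_p: float = 0.001
    enrich_p: float = 0.01
    window: int = 10000
    gammas: tuple = (0.0, 1.0, 1.0, 1.0)
    n_iter: int = 100
    seed: int | None = None
    grade_mapping: dict | None = None

    def __post_init__(self):
        for name in ("pag_p", "deg_p", "enrich_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        self.gammas = tuple(float(g) for g in self.gammas)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gammas"] = list(self.gammas)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_expression_tsv(path, allow_nan: bool = False) -> pd.DataFrame:
    """Gene x sample TSV (first column = gene id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    values = df.to_numpy()
    if not allow_nan and values.size and not np.all(np.isfinite(values)):
        n_bad = int((~np.isfinite(values)).sum())
        raise ValueError(
            f"{path}: {n_bad} non-finite expression values "
            "(pass allow_nan=True to keep them; such genes are skipped downstream)"
        )
    return df


def write_expression_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t")


def read_metadata_tsv(path, sample_col: str = "sample_id", grade_col: str = "grade"):
    """Sample metadata TSV with at least ``sample_id`` and ``grade`` columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (sample_col, grade_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing required column {col!r} (found {list(df.columns)})"
            )
    if df[sample_col].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def read_gmt(path) -> dict:
    """GMT gene sets: term <tab> description <tab> member genes."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            term, description = parts[0], parts[1]
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {term!r} is empty")
            sets[term] = (description, members)
    return sets


def read_peaks(path) -> pd.DataFrame:
    """BED-like peaks TSV: chrom, start, end, m_value (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "m_value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: start >= end")
    if not np.all(np.isfinite(df["m_value"])):
        raise ValueError(f"{path}: non-finite m_value")
    return df


def _tss_from_gtf(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = {}
    featuretypes = set(db.featuretypes())
    source_type = "transcript" if "transcript" in featuretypes else "gene"
    for feat in db.features_of_type(source_type):
        gene_id = (feat.attributes.get("gene_id") or [feat.id])[0]
        # GTF is 1-based inclusive; the TSS as a 0-based coordinate is the
        # 5'-most transcript start on the feature's strand.
        tss = feat.start - 1 if feat.strand != "-" else feat.end - 1
        prev = records.get(gene_id)
        if prev is None:
            records[gene_id] = [feat.seqid, tss, feat.strand]
        else:
            # keep the 5'-most TSS across transcripts of the gene
            if (feat.strand != "-" and tss < prev[1]) or (
                feat.strand == "-" and tss > prev[1]
            ):
                records[gene_id] = [feat.seqid, tss, feat.strand]
    return pd.DataFrame(
        [(g, c, t, s) for g, (c, t, s) in records.items()],
        columns=["gene_id", "chrom", "tss", "strand"],
    )


def read_promoters(path) -> pd.DataFrame:
    """Promoter/TSS table from a 4-column TSV or a GTF file.

    TSV columns: ``gene_id, chrom, tss, strand``.  For GTF input the TSS is
    derived strand-aware from transcript starts (5'-most per gene).
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        df = _tss_from_gtf(path)
    else:
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: need columns {sorted(required)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: one TSS record per gene required")
    df["tss"] = df["tss"].astype(int)
    return df


def read_grade_mapping_yaml(path) -> dict:
    """Grade-mapping YAML with ``order`` (list) and ``levels`` (label -> int)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "levels" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'levels' key")
    return data
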