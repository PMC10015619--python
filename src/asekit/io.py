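"""Readers and writers for every file format the pipeline touches.

Conventions
-----------
* Allelic/site count tables are tab-separated with a header line.
* Site positions are 1-based; BED intervals are 0-based half-open.
  Each format keeps its native convention; all internal interval math
  is 0-based half-open.
* All floats in output TSVs are rendered with 6 significant digits so
  that two writes of the same table are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLELIC_COUNT_COLUMNS = [
    "gene_id",
    "tissue",
    "timepoint",
    "replicate",
    "marine_count",
    "freshwater_count",
]
ALLELIC_COUNT_KEY = ["gene_id", "tissue", "timepoint", "replicate"]

SITE_COUNT_COLUMNS = ["chrom", "pos", "gene_id", "marine_count", "freshwater_count"]

INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "score", "kind"]

INTERVAL_KINDS = frozenset({"gene", "css_window", "ecopeak", "qtl"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _check_count_column(df: pd.DataFrame, column: str, path: str) -> pd.Series:
    values = df[column]
    numeric = pd.to_numeric(values, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad.any():
        # +2 for the header line and 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}:{line}: column {column!r} must be a non-negative integer, "
            f"got {values.iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r}"
        )
    return numeric.astype(np.int64)


def read_allelic_counts(path) -> pd.DataFrame:
    """Read a gene-level allelic count table.

    Expects a TSV with columns ``gene_id, tissue, timepoint, replicate,
    marine_count, freshwater_count``. The key (gene_id, tissue, timepoint,
    replicate) must be unique and counts must be non-negative integers.
    """
    path = str(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ALLELIC_COUNT_COLUMNS, path)
    df = df[ALLELIC_COUNT_COLUMNS].copy()
    for col in ("timepoint", "replicate", "marine_count", "freshwater_count"):
        df[col] = _check_count_column(df, col, path)
    if (df["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate numbers must be >= 1")
    dup = df.duplicated(ALLELIC_COUNT_KEY)
    if dup.any():
        key = df.loc[dup.idxmax(), ALLELIC_COUNT_KEY].tolist()
        raise FormatError(f"{path}: duplicated (gene, tissue, timepoint, replicate) key: {key}")
    return df.reset_index(drop=True)


def write_allelic_counts(table: pd.DataFrame, path) -> None:
    table[ALLELIC_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_site_counts(path) -> pd.DataFrame:
    """Read a per-heterozygous-site allelic count table (1-based positions)."""
    path = str(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SITE_COUNT_COLUMNS, path)
    df = df[SITE_COUNT_COLUMNS].copy()
    for col in ("pos", "marine_count", "freshwater_count"):
        df[col] = _check_count_column(df, col, path)
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: positions are 1-based and must be >= 1")
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(f"{path}: duplicated site {row['chrom']}:{row['pos']}")
    return df.reset_index(drop=True)


def write_site_counts(table: pd.DataFrame, path) -> None:
    table[SITE_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path, kind: str) -> pd.DataFrame:
    """Read a BED3+ file into an interval table.

    Coordinates are kept 0-based half-open exactly as in BED. Column 4 is
    the interval name and column 5 the score (CSS Z-score for
    ``kind='css_window'``); both are optional in the file.
    """
    path = str(path)
    if kind not in INTERVAL_KINDS:
        raise ValueError(f"unknown interval kind {kind!r}; expected one of {sorted(INTERVAL_KINDS)}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED requires at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": pd.to_numeric(df[1], errors="raise").astype(np.int64),
            "end": pd.to_numeric(df[2], errors="raise").astype(np.int64),
        }
    )
    out["name"] = (
        df[3].astype(str)
        if df.shape[1] > 3
        else [f"{kind}_{i}" for i in range(len(df))]
    )
    out["score"] = (
        pd.to_numeric(df[4], errors="coerce") if df.shape[1] > 4 else np.nan
    )
    out["kind"] = kind
    bad = out["start"] >= out["end"]
    if bad.any():
        row = out.loc[bad.idxmax()]
        raise FormatError(
            f"{path}: empty or inverted interval {row['chrom']}:{row['start']}-{row['end']}"
        )
    if kind == "css_window" and out["score"].isna().any():
        raise FormatError(f"{path}: css_window intervals require a numeric score column")
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write an interval table as BED5 (name and score always emitted)."""
    out = intervals[["chrom", "start", "end", "name", "score"]].copy()
    out["score"] = out["score"].map(lambda v: "." if pd.isna(v) else _format_float(v))
    out.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class GeneSetCollection:
    """Named gene sets after ortholog mapping to target-species identifiers."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()


def read_gene_sets(set_path, ortholog_path=None) -> GeneSetCollection:
    """Read two-column gene sets and optionally map members through orthologs.

    ``set_path`` holds (set_id, source_gene) pairs; ``ortholog_path`` holds
    (source_gene, target_gene) pairs, one-to-many allowed. Set members are
    the union of all target genes of all source members. Source genes
    absent from the map are skipped with a logged warning. With no
    ortholog file, source identifiers are used directly.
    """
    set_path = str(set_path)
    sets_df = pd.read_csv(set_path, sep="\t", header=None, dtype=str, comment="#")
    if sets_df.shape[1] < 2:
        raise FormatError(f"{set_path}: gene-set file requires two columns (set_id, gene)")
    mapping: dict[str, list[str]] | None = None
    if ortholog_path is not None:
        odf = pd.read_csv(str(ortholog_path), sep="\t", header=None, dtype=str, comment="#")
        if odf.shape[1] < 2:
            raise FormatError(f"{ortholog_path}: ortholog map requires two columns")
        mapping = {}
        for src, tgt in zip(odf[0], odf[1]):
            mapping.setdefault(src, []).append(tgt)

    collection = GeneSetCollection()
    n_dropped = 0
    for set_id, group in sets_df.groupby(0, sort=True):
        members: set[str] = set()
        for gene in group[1]:
            if mapping is None:
                members.add(gene)
            elif gene in mapping:
                members.update(mapping[gene])
            else:
                n_dropped += 1
                logger.warning("gene set %s: source gene %s absent from ortholog map, dropped", set_id, gene)
        if members:
            collection.sets[str(set_id)] = frozenset(members)
            collection.names[str(set_id)] = str(set_id)
    if n_dropped:
        logger.warning("%d source genes dropped during ortholog mapping", n_dropped)
    if not collection.sets:
        raise FormatError(f"{set_path}: no gene set has any mappable member")
    return collection


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    rows = [
        (set_id, gene)
        for set_id in sorted(collection.sets)
        for gene in sorted(collection.sets[set_id])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _format_float(value: float) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if pd.isna(value):
        return "NA"
    return f"{value:.6g}"


def write_results_tsv(table: pd.DataFrame, path) -> None:
    """Write any result table deterministically.

    Column order is preserved, floats are rendered with 6 significant
    digits, NaN becomes ``NA``, and the header is always present — two
    writes of the same table produce byte-identical files.
    """
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
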