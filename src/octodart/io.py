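"""Readers/writers for marker matrices, maps, anchors and trees, plus run configuration.

Presence/absence marker data are held as a pandas DataFrame of floats
(1.0 = band present, 0.0 = absent, NaN = missing call), always oriented
accessions x markers regardless of the on-disk orientation.
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

MISSING_TOKENS = ("NA", "-", "")

__all__ = [
    "MarkerMatrix",
    "SNPAlleleTable",
    "RunConfig",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_snp_allele_table",
    "read_genetic_map",
    "read_anchors",
    "read_newick",
    "write_newick",
    "load_config",
]


@dataclass
class MarkerMatrix:
    """Accessions x markers presence/absence grid with missing-value support.

    ``scores`` is a float DataFrame indexed by accession id with marker ids as
    columns; every cell is 0.0, 1.0 or NaN.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.scores.index
        cols = self.scores.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accession ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        vals = self.scores.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"score at accession {idx[i]!r}, marker {cols[j]!r} is "
                f"{vals[i, j]!r}; expected 0, 1 or missing"
            )
        self.scores = self.scores.astype(float)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_accessions(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    def select_markers(self, marker_ids: Sequence[str]) -> "MarkerMatrix":
        return MarkerMatrix(self.scores.loc[:, list(marker_ids)])


@dataclass
class SNPAlleleTable:
    """Two-row-per-SNP allele scoring table.

    ``rows`` holds one row per allele scoring (2 x n_snps rows, accessions as
    columns); consecutive row pairs belong to one SNP, in the order of
    ``snp_ids``.  ``row_sum`` is the total sequencing-read count supporting
    each allele row (a depth proxy).
    """

    snp_ids: list[str]
    rows: pd.DataFrame
    row_sum: pd.Series
    clone_sequence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) != 2 * len(self.snp_ids):
            raise ValueError(
                f"allele-row count {len(self.rows)} != 2 x SNP count {len(self.snp_ids)}"
            )
        if (self.row_sum < 0).any():
            raise ValueError("row_sum must be nonnegative")
        if not self.row_sum.index.equals(self.rows.index):
            self.row_sum = self.row_sum.reindex(self.rows.index)
            if self.row_sum.isna().any():
                raise ValueError("row_sum index does not match allele rows")


# Paper-protocol default thresholds for the full pipeline.
_CONFIG_DEFAULTS = {
    "seed": 0,
    "alpha_simplex": 0.001,
    "alpha_multiplex": 0.01,
    "max_missing_fraction": 0.10,
    "min_row_sum": 600,
    "similarity_threshold": 0.99,
    "lod_threshold": 5.0,
    "bootstrap_replicates": 1000,
    "restriction_site_length": 6,
}


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults are the published protocol values."""

    seed: int = 0
    alpha_simplex: float = 0.001
    alpha_multiplex: float = 0.01
    max_missing_fraction: float = 0.10
    min_row_sum: float = 600
    similarity_threshold: float = 0.99
    lod_threshold: float = 5.0
    bootstrap_replicates: int = 1000
    restriction_site_length: int = 6

    def __post_init__(self) -> None:
        for key in ("alpha_simplex", "alpha_multiplex", "max_missing_fraction"):
            v = getattr(self, key)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{key} must lie in (0, 1); got {v}")
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError(
                f"similarity_threshold must lie in (0, 1]; got {self.similarity_threshold}"
            )
        for key in ("min_row_sum", "lod_threshold", "restriction_site_length"):
            v = getattr(self, key)
            if v <= 0:
                raise ValueError(f"{key} must be positive; got {v}")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")
        self.seed = int(self.seed)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML key: value config; absent keys take protocol defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a flat key: value mapping")
    unknown = set(data) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _parse_cell(token: str, missing_tokens: Sequence[str], row: str, col: str) -> float:
    tok = token.strip()
    if tok in missing_tokens:
        return math.nan
    if tok == "0":
        return 0.0
    if tok == "1":
        return 1.0
    raise ValueError(
        f"cannot parse score {token!r} at row {row!r}, column {col!r}: "
        f"expected 0, 1 or one of {tuple(missing_tokens)}"
    )


def read_marker_matrix(
    path: str | Path,
    sep: str = "\t",
    missing_tokens: Sequence[str] = MISSING_TOKENS,
    transposed: bool = False,
) -> MarkerMatrix:
    """Read a delimited 0/1 matrix with a header row and an id first column.

    ``transposed=True`` declares the file as markers x accessions; the
    in-memory result is always accessions x markers.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    parsed = pd.DataFrame(
        {
            col: [
                _parse_cell(raw.at[row, col], missing_tokens, str(row), str(col))
                for row in raw.index
            ]
            for col in raw.columns
        },
        index=raw.index.astype(str),
    )
    parsed.columns = parsed.columns.astype(str)
    if transposed:
        parsed = parsed.T
    return MarkerMatrix(parsed)


def write_marker_matrix(
    matrix: MarkerMatrix, path: str | Path, sep: str = "\t", missing_token: str = "NA"
) -> None:
    out = matrix.scores.map(
        lambda v: missing_token if (isinstance(v, float) and math.isnan(v)) else str(int(v))
    )
    out.to_csv(path, sep=sep)


def read_snp_allele_table(
    path: str | Path,
    sep: str = "\t",
    missing_tokens: Sequence[str] = MISSING_TOKENS,
    row_sum_column: str = "row_sum",
) -> SNPAlleleTable:
    """Read a two-row-per-SNP allele table: allele id column, row_sum column,
    then one 0/1/missing column per accession.  Row pairs must be consecutive
    and share a SNP stem (the id up to the last ``_``)."""
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if row_sum_column not in raw.columns:
        raise ValueError(f"missing {row_sum_column!r} column")
    row_sum = raw[row_sum_column].astype(float)
    calls = raw.drop(columns=[row_sum_column])
    parsed = pd.DataFrame(
        {
            col: [
                _parse_cell(calls.at[row, col], missing_tokens, str(row), str(col))
                for row in calls.index
            ]
            for col in calls.columns
        },
        index=calls.index.astype(str),
    )
    if len(parsed) % 2:
        raise ValueError(f"odd allele-row count {len(parsed)}: rows must pair per SNP")
    snp_ids = []
    for i in range(0, len(parsed), 2):
        a, b = parsed.index[i], parsed.index[i + 1]
        stem_a, stem_b = a.rsplit("_", 1)[0], b.rsplit("_", 1)[0]
        if stem_a != stem_b:
            raise ValueError(f"rows {a!r} and {b!r} do not pair to one SNP")
        snp_ids.append(stem_a)
    return SNPAlleleTable(snp_ids=snp_ids, rows=parsed, row_sum=row_sum)


def read_genetic_map(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a genetic map TSV with columns marker, lg, cm (extra columns kept)."""
    df = pd.read_csv(path, sep=sep, dtype={"marker": str, "lg": str})
    for col in ("marker", "lg", "cm"):
        if col not in df.columns:
            raise ValueError(f"map file missing column {col!r}")
    df["cm"] = df["cm"].astype(float)
    if (df["cm"] < 0).any():
        raise ValueError("cM positions must be nonnegative")
    return df


def read_anchors(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read physical anchors TSV with columns marker, chrom, bp (1-based)."""
    df = pd.read_csv(path, sep=sep, dtype={"marker": str})
    for col in ("marker", "chrom", "bp"):
        if col not in df.columns:
            raise ValueError(f"anchor file missing column {col!r}")
    df["bp"] = df["bp"].astype(int)
    if (df["bp"] < 1).any():
        raise ValueError("bp positions are 1-based and must be >= 1")
    return df


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths; internal node labels carry
    bootstrap supports when present."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled leaf")
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    Path(path).write_text(s)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of an (un)rooted tree as unordered label-set pairs."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset({side, other}))
    return out
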