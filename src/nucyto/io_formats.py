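"""Tabular readers/writers and gene-symbol aggregation.

Canonical on-disk dialect is TSV (CSV behind ``dialect="csv"``).  Expression
matrices are gene/locus rows x sample columns of non-negative finite FPKM;
missing values are not permitted (absence of expression is encoded as 0).
Result tables carry a single ``#``-prefixed header comment recording the tool
version and a config hash; comment lines are skipped on read.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control", "repeat")
FRACTIONS = ("nuclear", "cytoplasmic")

_SEPARATORS = {"tsv": "\t", "csv": ","}


class FormatError(ValueError):
    """A file violates its format contract (parse or invariant failure)."""


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:  # pragma: no cover - guarded by CLI choices
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative expression values, row identifiers x sample identifiers.

    ``data`` is a float64 DataFrame whose index holds locus or gene symbols
    (unique) and whose columns hold sample identifiers (unique).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate row id {dup!r} in expression matrix")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in expression matrix")
        values = df.to_numpy()
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid expression value {values[i, j]!r} at row "
                f"{df.index[i]!r}, column {df.columns[j]!r} (must be finite and >= 0)"
            )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix (first column row ids, header of sample ids).

    Raises :class:`FormatError` on duplicate sample ids or on a negative /
    non-numeric cell, naming the offending row and column.
    """
    sep = _sep(dialect)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty expression matrix file")
    header = lines[0].split(sep)
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r} in header")
        seen.add(s)
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(sep)
        if len(fields) != len(samples) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
            )
        row_id = fields[0]
        values = []
        for sample, field in zip(samples, fields[1:]):
            try:
                value = float(field)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {field!r} at row {row_id!r}, "
                    f"column {sample!r}"
                ) from None
            if not np.isfinite(value) or value < 0:
                raise FormatError(
                    f"{path}: invalid expression value {field!r} at row "
                    f"{row_id!r}, column {sample!r} (must be finite and >= 0)"
                )
            values.append(value)
        row_ids.append(row_id)
        rows.append(values)
    df = pd.DataFrame(rows, index=row_ids, columns=samples, dtype=float)
    return ExpressionMatrix(df)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    matrix.data.to_csv(path, sep=_sep(dialect), index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to (condition, fraction, replicate) design factors.

    The design must be complete: each of the four (condition, fraction) cells
    carries the same replicate count R >= 2, and the (condition, fraction,
    replicate) triples are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"sample_id", "condition", "fraction", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in sample sheet")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown condition(s) {sorted(bad_cond)}; expected {CONDITIONS}")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise FormatError(f"unknown fraction(s) {sorted(bad_frac)}; expected {FRACTIONS}")
        triples = df[["condition", "fraction", "replicate"]]
        if triples.duplicated().any():
            row = triples.loc[triples.duplicated()].iloc[0]
            raise FormatError(
                f"duplicate design triple ({row['condition']}, {row['fraction']}, "
                f"{row['replicate']})"
            )
        counts = df.groupby(["condition", "fraction"]).size()
        if len(counts) != len(CONDITIONS) * len(FRACTIONS):
            raise FormatError("incomplete design: a (condition, fraction) cell is empty")
        if counts.nunique() != 1:
            raise FormatError(
                f"unbalanced design: replicate counts per cell are {sorted(set(counts))}"
            )
        if counts.iloc[0] < 2:
            raise FormatError("fewer than 2 replicates per (condition, fraction) cell")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n_replicates(self) -> int:
        return int(
            self.data[(self.data["condition"] == CONDITIONS[0])
                      & (self.data["fraction"] == FRACTIONS[0])].shape[0]
        )

    def samples(self, condition: str, fraction: str) -> dict[int, str]:
        """Return ``{replicate: sample_id}`` for one design cell."""
        sub = self.data[
            (self.data["condition"] == condition) & (self.data["fraction"] == fraction)
        ]
        return {int(r): s for r, s in zip(sub["replicate"], sub["sample_id"])}


def read_sample_sheet(path: str | Path, dialect: str = "tsv") -> SampleSheet:
    df = pd.read_csv(path, sep=_sep(dialect), comment="#", dtype={"sample_id": str})
    df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, dialect: str = "tsv") -> None:
    sheet.data.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# Locus map + aggregation
# ---------------------------------------------------------------------------


def read_locus_map(path: str | Path, dialect: str = "tsv") -> dict[str, str]:
    """Read a two-column (locus_id, gene_symbol) table into a dict."""
    df = pd.read_csv(path, sep=_sep(dialect), comment="#", dtype=str)
    if not {"locus_id", "gene_symbol"} <= set(df.columns):
        raise FormatError(f"{path}: locus map needs columns locus_id, gene_symbol")
    if df["locus_id"].duplicated().any():
        dup = df.loc[df["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise FormatError(f"{path}: locus {dup!r} mapped more than once")
    return dict(zip(df["locus_id"], df["gene_symbol"]))


def write_locus_map(locus_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"locus_id": list(locus_map), "gene_symbol": list(locus_map.values())}
    ).to_csv(path, sep="\t", index=False)


def aggregate_by_gene(
    matrix: ExpressionMatrix,
    locus_map: Mapping[str, str],
    on_unmapped: str = "error",
) -> ExpressionMatrix:
    """Collapse loci to gene symbols by the arithmetic mean per sample.

    Single-locus genes pass through unchanged.  An unmapped locus is a hard
    error unless ``on_unmapped="passthrough"``, in which case the locus id is
    used as its own gene symbol.  Output rows follow first occurrence order.
    """
    if on_unmapped not in ("error", "passthrough"):
        raise ValueError("on_unmapped must be 'error' or 'passthrough'")
    symbols = []
    for locus in matrix.row_ids:
        symbol = locus_map.get(locus)
        if symbol is None:
            if on_unmapped == "error":
                raise FormatError(f"locus {locus!r} has no gene-symbol mapping")
            symbol = locus
        symbols.append(symbol)
    grouped = matrix.data.groupby(pd.Index(symbols, name="gene_id"), sort=False).mean()
    return ExpressionMatrix(grouped)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a symbol universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set (and the universe) with ``universe``."""
        uni = frozenset(universe)
        return GeneSetCollection(
            sets={name: members & uni for name, members in self.sets.items()},
            universe=self.universe & uni,
        )

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...; tab-separated).

    Duplicate members within a line are deduplicated; a line with fewer than
    three fields or a repeated set name is a hard error naming the line.
    """
    sets: dict[str, frozenset[str]] = {}
    members_union: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            sets[name] = members
            members_union |= members
    uni = frozenset(universe) if universe is not None else frozenset(members_union)
    collection = GeneSetCollection(sets=sets, universe=uni)
    if universe is not None:
        collection = GeneSetCollection(
            sets={n: m & uni for n, m in collection.sets.items()}, universe=uni
        )
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Gene lists and result tables
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and ``#`` comments skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    tool_version: str = "unknown",
    config_hash: str = "unset",
    index: bool = False,
) -> None:
    """Write a result table as TSV preceded by a provenance comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# nucyto={tool_version} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
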