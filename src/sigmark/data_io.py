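"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices are genes x samples tables of log2 intensities (TSV),
gene sets come in the MSigDB GMT dialect, and clinical data is a CSV with one
row per patient. Gene identity is by symbol, case-sensitive; probe-to-symbol
mapping is assumed to have happened upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "CohortTable",
    "parse_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
]


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class ValidationError(ValueError):
    """A loaded table violated a container invariant."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes in rows and samples in columns.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns. After construction the matrix holds no duplicate genes, no
    missing values, and only finite entries.
    """

    values: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Rows for ``genes`` that are present, in the given order."""
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.platform_tag)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


REQUIRED_CLINICAL_COLUMNS = ("sample_id", "time", "event", "stage_group", "marker")


@dataclass
class CohortTable:
    """Per-patient survival endpoints, stage grouping, and marker value.

    ``table`` is indexed by sample_id with columns time (months, > 0),
    event (0/1), stage_group (0 = TNM I-II, 1 = TNM III-IV) and marker
    (continuous, e.g. an nc886-like qRT-PCR value). Downstream modules may
    append score columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event", "stage_group", "marker"):
            if col not in t.columns:
                raise ValidationError(f"missing required column {col!r}")
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample ids in cohort table")
        if not (t["time"] > 0).all():
            bad = t.index[~(t["time"] > 0)][0]
            raise ValidationError(f"time must be > 0 (sample {bad!r})")
        if not t["event"].isin([0, 1]).all():
            bad = t.index[~t["event"].isin([0, 1])][0]
            raise ValidationError(f"event must be 0 or 1 (sample {bad!r})")
        if not t["stage_group"].isin([0, 1]).all():
            bad = t.index[~t["stage_group"].isin([0, 1])][0]
            raise ValidationError(f"stage_group must be 0 or 1 (sample {bad!r})")
        if not np.isfinite(t["marker"].to_numpy(dtype=float)).all():
            raise ValidationError("marker must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-set collection in the MSigDB GMT dialect.

    Each line is ``name<TAB>description<TAB>member1<TAB>member2...``.
    Duplicate member symbols within one line are collapsed to their first
    occurrence with a logged warning; a duplicate set name is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            members: list[str] = []
            for m in fields[2:]:
                if not m:
                    continue
                if m in members:
                    logger.warning(
                        "%s:%d: duplicate member %r in set %r collapsed",
                        path.name, lineno, m, name,
                    )
                    continue
                members.append(m)
            sets.append(GeneSet(name=name, description=description, members=members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_expression_matrix(path: str | Path, platform_tag: str = "") -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix of log2 values.

    First column holds gene symbols, the header row holds sample ids.
    Duplicate gene symbols are resolved by keeping the row with the highest
    mean (logged); rows containing missing values are dropped (count logged).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path.name}: empty file") from None
    if df.empty and df.columns.empty:
        raise ParseError(f"{path.name}: empty file")

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            # distinguish explicit NA strings (missing) from junk (error)
            bad = coerced.isna() & df[col].notna() & ~df[col].astype(str).str.strip().isin(
                ["NA", "NaN", "nan", ""]
            )
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ParseError(
                    f"{path.name}: non-numeric value {df.loc[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d gene rows with missing values", path.name, n_missing)
        df = df.dropna(axis=0)

    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        kept = df.iloc[order][~df.index[order].duplicated(keep="first")]
        kept = kept.loc[df.index.drop_duplicates()]  # restore input gene order
        n_dup = len(df) - len(kept)
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept highest-mean row)",
            path.name, n_dup,
        )
        df = kept

    df = df.astype(float)
    return ExpressionMatrix(df, platform_tag=platform_tag)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        # %.17g guarantees bit-identical float round trips through the TSV
        expr.values.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.17g")


def read_clinical_table(path: str | Path) -> CohortTable:
    """Read the per-patient clinical CSV (sample_id, time, event, stage_group, marker)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    df = df.set_index("sample_id")
    return CohortTable(df)


def write_clinical_table(cohort: CohortTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cohort.table.to_csv(fh, index_label="sample_id")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks skipped, order kept."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and sym not in out:
                out.append(sym)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(g + "\n")
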