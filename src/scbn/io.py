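"""Reading, writing and filtering of two-species ortholog count tables.

The central container is :class:`OrthologTable`: one row per one-to-one
orthologous gene pair, with the read count and gene/transcript length in each
species.  The per-species sequencing depths ``N1``/``N2`` are *derived*
quantities — the column sums of the counts over the orthologous set — and are
recomputed on demand so they always reflect the rows currently in the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrthologTable",
    "ConservedSet",
    "TableFormatError",
    "TableValidationError",
    "read_ortholog_table",
    "write_ortholog_table",
    "filter_transcripts",
    "read_conserved_list",
]

#: canonical column roles of an ortholog table
REQUIRED_COLUMNS = ("gene_id", "x1", "L1", "x2", "L2")


class TableFormatError(ValueError):
    """Raised when an input file cannot be mapped onto the required columns."""


class TableValidationError(ValueError):
    """Raised when a table contains invalid counts or lengths."""


def _check_integral(series: pd.Series, name: str, minimum: int) -> None:
    values = series.dropna()
    if len(values) == 0:
        return
    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr) | (arr != np.floor(arr)) | (arr < minimum)
    if bad.any():
        idx = values.index[np.argmax(bad)]
        raise TableValidationError(
            f"column {name!r} has an invalid value {values.loc[idx]!r} at row "
            f"{idx} (must be an integer >= {minimum})"
        )


@dataclass
class OrthologTable:
    """Per-ortholog-pair read counts and lengths for two species.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain columns ``gene_id, x1, L1, x2, L2``.  Counts must be
        non-negative integers and lengths positive integers; missing values
        are tolerated (they mark structurally incomplete, "unmatched" rows
        that :func:`filter_transcripts` removes).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"missing required columns: {missing}")
        if len(self.data) == 0:
            raise TableValidationError("ortholog table is empty")
        _check_integral(self.data["x1"], "x1", 0)
        _check_integral(self.data["x2"], "x2", 0)
        _check_integral(self.data["L1"], "L1", 1)
        _check_integral(self.data["L2"], "L2", 1)

    # -- derived totals -----------------------------------------------------
    @property
    def n1(self) -> int:
        """Total orthologous reads in species 1 (sum of x1 over rows)."""
        return int(np.nansum(self.data["x1"].to_numpy(dtype=float)))

    @property
    def n2(self) -> int:
        """Total orthologous reads in species 2 (sum of x2 over rows)."""
        return int(np.nansum(self.data["x2"].to_numpy(dtype=float)))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> pd.Series:
        return self.data["gene_id"]

    def subset(self, ids: Iterable[str]) -> "OrthologTable":
        """Rows whose gene_id is in ``ids`` (table order preserved)."""
        ids = set(ids)
        mask = self.data["gene_id"].isin(ids)
        return OrthologTable(self.data.loc[mask].reset_index(drop=True))


@dataclass
class ConservedSet:
    """Identifiers of orthologous genes assumed non-DE (the anchor set H)."""

    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        dupes = []
        for i in self.ids:
            if i in seen:
                dupes.append(i)
            seen[i] = None
        if dupes:
            warnings.warn(f"conserved list contains duplicates (dropped): {dupes[:5]}")
        self.ids = list(seen)
        if not self.ids:
            raise ValueError("conserved set is empty")

    @property
    def m(self) -> int:
        return len(self.ids)


def _resolve_columns(
    df: pd.DataFrame, columns: Mapping[str, str | Sequence[str]] | None
) -> pd.DataFrame:
    """Locate required columns by name (case-insensitive) and pool replicate
    count columns (``x1``, ``x1_a``, ``x1_b`` ... summed per species)."""
    lower = {str(c).lower(): c for c in df.columns}
    out = {}
    for role in REQUIRED_COLUMNS:
        if columns and role in columns:
            spec = columns[role]
            names = [spec] if isinstance(spec, str) else list(spec)
            for n in names:
                if n not in df.columns:
                    raise TableFormatError(f"column {n!r} (role {role}) not found")
            if role in ("x1", "x2") and len(names) > 1:
                out[role] = df[names].sum(axis=1)
            else:
                out[role] = df[names[0]]
            continue
        # auto-detect: exact name, plus x1_*/x2_* replicate columns
        if role in ("x1", "x2"):
            reps = [
                orig
                for low, orig in lower.items()
                if low == role or low.startswith(role + "_")
            ]
            if not reps:
                raise TableFormatError(f"no column found for {role!r}")
            out[role] = df[reps].sum(axis=1) if len(reps) > 1 else df[reps[0]]
        else:
            if role.lower() not in lower:
                raise TableFormatError(f"no column found for {role!r}")
            out[role] = df[lower[role.lower()]]
    return pd.DataFrame(out)


def read_ortholog_table(
    path: str | Path,
    delimiter: str | None = None,
    columns: Mapping[str, str | Sequence[str]] | None = None,
) -> OrthologTable:
    """Read a delimited ortholog count/length table.

    Both TSV and CSV are accepted (the delimiter is sniffed when not given);
    a header row is required and columns are located by name, not position.
    Lines starting with ``#`` are treated as provenance comments.  Extra
    per-species count columns named ``x1_<sample>`` / ``x2_<sample>`` are
    pooled by summation — the conditional test consumes one count per species.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            comment="#",
        )
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise TableValidationError(f"{path} is empty or not delimited text") from exc
    if len(df) == 0:
        raise TableValidationError(f"{path} contains no data rows")
    return OrthologTable(_resolve_columns(df, columns).reset_index(drop=True))


def write_ortholog_table(
    table: OrthologTable,
    path: str | Path,
    comments: Sequence[str] = (),
    delimiter: str = "\t",
) -> None:
    """Write the table as delimited text with '#' provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        table.data.to_csv(fh, sep=delimiter, index=False)


def filter_transcripts(table: OrthologTable) -> OrthologTable:
    """Apply the transcript-filtering rules before testing.

    Removes rows that are (a) structurally incomplete — any of gene_id,
    counts or lengths missing ("unmatched"); (b) duplicated — *all* rows
    sharing a gene_id are dropped, since a duplicated ortholog mapping is
    ambiguous in both species; (c) unexpressed — zero count in *both*
    species.  A gene expressed in exactly one species is a unique gene and
    is retained (it is testable).  Depths N1/N2 are derived properties and
    therefore reflect the retained rows automatically.
    """
    df = table.data
    incomplete = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    ids = df["gene_id"].astype(str)
    duplicated = ids.duplicated(keep=False)
    x1 = df["x1"].fillna(0)
    x2 = df["x2"].fillna(0)
    unexpressed = (x1 == 0) & (x2 == 0)
    keep = ~(incomplete | duplicated | unexpressed)
    if not keep.any():
        warnings.warn("filtering removed every row of the ortholog table")
        out = df.loc[keep]
        out = out.reset_index(drop=True)
        # bypass the emptiness check: an empty result is allowed, flagged above
        obj = object.__new__(OrthologTable)
        obj.data = out
        return obj
    out = df.loc[keep].reset_index(drop=True).copy()
    for col in ("x1", "x2", "L1", "L2"):
        out[col] = out[col].astype(np.int64)
    return OrthologTable(out)


def read_conserved_list(path: str | Path, table: OrthologTable) -> ConservedSet:
    """Read a conserved-gene list (one id per line, or first CSV column) and
    intersect it with the table's gene ids.

    Ids absent from the table are reported via a warning, not silently
    dropped; an empty intersection is an error (the scaling-factor objective
    is undefined over an empty anchor set).
    """
    raw: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw.append(line.split(",")[0].strip())
    if not raw:
        raise TableValidationError(f"{path} contains no identifiers")
    present = set(table.gene_ids.astype(str))
    kept = [i for i in raw if i in present]
    missing = [i for i in raw if i not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} conserved ids not in the ortholog table: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    if not kept:
        raise ValueError("conserved list is disjoint from the ortholog table")
    return ConservedSet(ids=kept)
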