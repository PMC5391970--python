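"""Readers and writers for the tabular artifacts of the pipeline.

All inputs are plain TSV/CSV with a header row.  Column dialects are
configurable by name mapping because the source screens ship with
different headers; gene symbols are stored verbatim (case normalisation
is the homology module's job) and duplicate symbols are retained at read
time and resolved downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

KNOWN_SPECIES = ("mouse", "rat", "human")
GROUP_LABELS = ("vulnerable", "resistant")

#: standard column names used internally for DE records
DE_COLUMNS = ("gene", "log2fc", "p", "q")

#: default header dialects for the four source screens
DEFAULT_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {"gene": "gene", "log2fc": "log2fc", "p": "p", "q": "q"},
    "rnaseq_cuffdiff": {
        "gene": "gene", "log2fc": "log2_fold_change", "p": "p_value", "q": "q_value",
    },
    "microarray": {"gene": "Gene Symbol", "log2fc": "Log Fold Change", "q": "Q Value"},
}


class SchemaError(ValueError):
    """A required column is missing or a table-level invariant is broken."""


@dataclass
class ScreenResult:
    """One screen's per-gene differential-expression statistics.

    ``records`` has columns gene, log2fc, p, q; log2fc is vulnerable
    minus resistant on the log2 scale.  ``p`` may be NaN when the source
    table reports only adjusted values.
    """

    screen_id: str
    species: str
    records: pd.DataFrame
    parse_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.species not in KNOWN_SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; expected one of {KNOWN_SPECIES}"
            )
        missing = [c for c in DE_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing columns: {missing}")
        rec = self.records
        if len(rec):
            if (rec["gene"].astype(str).str.len() == 0).any():
                raise ValueError("empty gene symbol in records")
            q = rec["q"].to_numpy(float)
            if np.nanmin(q) < 0 or np.nanmax(q) > 1:
                raise ValueError("q values must lie in [0, 1]")
        self.records = rec.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def duplicated_symbols(self) -> list[str]:
        dup = self.records["gene"][self.records["gene"].duplicated()]
        return sorted(set(dup))


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities with a two-level group factor."""

    values: pd.DataFrame                  # index: gene ids, columns: sample ids
    groups: pd.Series                     # sample id -> vulnerable/resistant

    def __post_init__(self) -> None:
        if list(self.groups.index) != list(self.values.columns):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; use {GROUP_LABELS}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    def require_testable(self) -> None:
        """Both group labels present with at least two samples each."""
        for label in GROUP_LABELS:
            n = int((self.groups == label).sum())
            if n < 2:
                raise ValueError(f"group {label!r} has {n} samples; need >= 2")


@dataclass
class PhenotypeTables:
    """Validation-experiment phenotype tables (any subset may be present).

    eye_areas: line_id, genotype_class, fly_id, area (mm^2, average of the
    two eyes of one fly).  survival: animal_id, group, day, event in
    {death, censored}.  endplates: muscle_id, group, n_full, n_partial,
    n_vacant endplate counts per muscle.
    """

    eye_areas: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    endplates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.eye_areas is not None and len(self.eye_areas):
            if (self.eye_areas["area"] <= 0).any():
                raise ValueError("eye areas must be strictly positive")
        if self.survival is not None and len(self.survival):
            if (self.survival["day"] <= 0).any():
                raise ValueError("survival days must be strictly positive")
            bad = set(self.survival["event"]) - {"death", "censored"}
            if bad:
                raise ValueError(f"unknown event codes: {sorted(bad)}")
        if self.endplates is not None and len(self.endplates):
            counts = self.endplates[["n_full", "n_partial", "n_vacant"]]
            if (counts < 0).any().any():
                raise ValueError("endplate counts must be non-negative")
            if (counts.sum(axis=1) < 1).any():
                raise ValueError("each muscle needs at least one classified endplate")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _to_log2(value: float, fc_scale: str) -> float:
    """Convert a reported fold change to log2 units.

    ``signed_linear`` is the convention where -2.0 means a 2-fold
    decrease; magnitudes below 1 are invalid on that scale.
    """
    if fc_scale == "log2":
        return value
    if fc_scale == "signed_linear":
        mag = abs(value)
        if mag < 1:
            raise ValueError(f"signed-linear fold change with |value| < 1: {value}")
        return math.copysign(math.log2(mag), value)
    raise ValueError(f"fc_scale must be 'log2' or 'signed_linear', got {fc_scale!r}")


def read_de_table(
    path: str | Path,
    *,
    screen_id: str,
    species: str,
    dialect: Mapping[str, str] | str = "generic",
    fc_scale: str = "log2",
    on_row_error: str = "collect",
) -> ScreenResult:
    """Read a per-gene differential-expression table.

    ``dialect`` maps the internal names gene/log2fc/p/q to the file's
    header names (``p`` and ``q`` may be omitted individually, but at
    least one of the two must be mapped; a missing ``p`` is stored as NaN
    and a missing ``q`` is copied from ``p``).  Scientific notation,
    including an exact zero like ``0E+00``, parses as a float.  Rows with
    a non-numeric fold change are collected into ``parse_errors`` (or
    raised when ``on_row_error='raise'``).
    """
    path = Path(path)
    if isinstance(dialect, str):
        dialect = DEFAULT_DIALECTS[dialect]
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    table.columns = [c.strip() for c in table.columns]

    for name in ("gene", "log2fc"):
        col = dialect.get(name)
        if col is None:
            raise SchemaError(f"dialect does not map required column {name!r}")
        if col not in table.columns:
            raise SchemaError(f"column {col!r} (for {name}) not found in {path.name}")
    # p and q are individually optional, but at least one must resolve
    dialect = dict(dialect)
    for name in ("p", "q"):
        if dialect.get(name) is not None and dialect[name] not in table.columns:
            dialect.pop(name)
    if dialect.get("p") is None and dialect.get("q") is None:
        raise SchemaError(
            f"no p or q column found in {path.name}; map one in the dialect"
        )

    errors: list[str] = []
    rows: list[tuple[str, float, float, float]] = []
    p_col = dialect.get("p")
    q_col = dialect.get("q")
    for i, row in table.iterrows():
        line_no = i + 2  # header is line 1
        gene = str(row[dialect["gene"]]).strip()
        if not gene or gene.lower() == "nan":
            errors.append(f"line {line_no}: empty gene symbol")
            continue
        try:
            log2fc = _to_log2(float(str(row[dialect["log2fc"]]).strip()), fc_scale)
        except (TypeError, ValueError) as exc:
            errors.append(f"line {line_no}: bad fold change for {gene}: {exc}")
            continue
        try:
            p = float(str(row[p_col]).strip()) if p_col else math.nan
            q = float(str(row[q_col]).strip()) if q_col else p
        except (TypeError, ValueError) as exc:
            errors.append(f"line {line_no}: bad p/q for {gene}: {exc}")
            continue
        rows.append((gene, log2fc, p, q))

    if errors and on_row_error == "raise":
        raise ValueError("; ".join(errors))
    records = pd.DataFrame(rows, columns=list(DE_COLUMNS))
    result = ScreenResult(screen_id, species, records, parse_errors=errors)
    if result.duplicated_symbols:
        warnings.warn(
            f"{screen_id}: duplicate gene symbols retained: "
            f"{result.duplicated_symbols[:5]}...",
            stacklevel=2,
        )
    return result


def read_expression_matrix(
    path: str | Path, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a genes x samples intensity matrix (first column = gene id).

    Samples are restricted to, and grouped by, ``group_map``; a mapped
    sample absent from the file is an error naming the sample.  Gene and
    sample order follow the file; duplicate gene ids are kept (with a
    warning) because probe-level duplication is a property of the data.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    missing = [s for s in group_map if s not in table.columns]
    if missing:
        raise ValueError(f"samples in group_map absent from {path.name}: {missing}")
    table = table[list(group_map)]
    if table.index.duplicated().any():
        dup = sorted(set(table.index[table.index.duplicated()]))
        warnings.warn(f"duplicate gene ids retained: {dup[:5]}...", stacklevel=2)
    groups = pd.Series(dict(group_map), name="group").reindex(table.columns)
    return ExpressionMatrix(values=table.astype(float), groups=groups)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.values.rename_axis("gene").to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# concordance table round trip

def write_concordance_table(matrix, path: str | Path) -> None:
    """Write a concordance matrix as one row per reference symbol.

    Columns: ref_symbol, <screen_id>_log2fc per screen (absent coded as
    an empty field), n_screens, tier, direction.  Written so that
    :func:`read_concordance_table` reproduces the matrix exactly.
    """
    if not len(matrix.ref_symbols):
        raise ValueError("refusing to write an empty concordance matrix")
    path = Path(path)
    out = matrix.log2fc.copy()
    out.columns = [f"{c}_log2fc" for c in out.columns]
    out["n_screens"] = matrix.n_present
    out["tier"] = matrix.tier
    out["direction"] = matrix.direction
    out.rename_axis("ref_symbol").to_csv(path, sep=_sep_for(path))


def read_concordance_table(path: str | Path):
    """Read a concordance table written by :func:`write_concordance_table`."""
    from concord.concordance import ConcordanceMatrix

    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col="ref_symbol")
    fc_cols = [c for c in table.columns if c.endswith("_log2fc")]
    log2fc = table[fc_cols].astype(float)
    log2fc.columns = [c[: -len("_log2fc")] for c in fc_cols]
    return ConcordanceMatrix(
        log2fc=log2fc,
        n_present=table["n_screens"].astype(int),
        direction=table["direction"].astype(str),
        tier=table["tier"].astype(int),
    )


# ---------------------------------------------------------------------------
# phenotype tables

def read_eye_areas(path: str | Path) -> pd.DataFrame:
    """Eye-area table: line_id, genotype_class, fly_id, area columns."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    _require(table, ["line_id", "area"], path)
    table["area"] = table["area"].astype(float)
    PhenotypeTables(eye_areas=table)
    return table


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival table: animal_id, group, day, event columns."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    _require(table, ["animal_id", "group", "day", "event"], path)
    table["day"] = table["day"].astype(float)
    PhenotypeTables(survival=table)
    return table


def read_endplates(path: str | Path) -> pd.DataFrame:
    """Endplate occupancy table: muscle_id, group, n_full/n_partial/n_vacant."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    _require(table, ["muscle_id", "group", "n_full", "n_partial", "n_vacant"], path)
    for col in ("n_full", "n_partial", "n_vacant"):
        table[col] = table[col].astype(int)
    PhenotypeTables(endplates=table)
    return table


def _require(table: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
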