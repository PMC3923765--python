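"""Tabular omics readers: CSV, TSV and a minimal GEO SOFT dialect.

The leading non-numeric column(s) are identifier columns (cells may hold
several ids joined by a separator, ``;`` by default); the header row names
the samples; blank or non-numeric data cells become missing values.

The SOFT dialect parses the lines between ``!sample_table_begin`` and
``!sample_table_end`` as TSV and retains ``!``-prefixed metadata lines as
annotations.
"""

from __future__ import annotations

import io as _io
import logging

import numpy as np
import pandas as pd

from ..errors import FormatError
from ..series import DataSeries

logger = logging.getLogger(__name__)


def read_table(text: str, dialect: str = "tsv", id_separator: str = ";",
               name: str = "series") -> DataSeries:
    if dialect not in ("csv", "tsv", "soft"):
        raise FormatError(f"unknown table dialect {dialect!r}")
    annotations: dict[str, str] = {}
    if dialect == "soft":
        text, annotations = _extract_soft_table(text)
        sep = "\t"
    else:
        sep = "," if dialect == "csv" else "\t"

    try:
        df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str,
                         keep_default_na=False, skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"unparsable table: {exc}") from exc
    if df.empty or df.shape[1] < 2:
        raise FormatError("table needs an identifier column and at least one sample")

    numeric = df.apply(lambda col: pd.to_numeric(
        col.replace("", np.nan), errors="coerce"))
    # identifier columns = leading maximal run of fully non-numeric columns
    n_id = 0
    for c in df.columns:
        if numeric[c].notna().any():
            break
        n_id += 1
    n_id = max(n_id, 1)
    if n_id == df.shape[1]:
        raise FormatError("table has no numeric sample column")

    id_cols = list(df.columns[:n_id])
    sample_cols = list(df.columns[n_id:])
    row_ids = []
    for _, row in df[id_cols].iterrows():
        ids: set[str] = set()
        for cell in row:
            ids.update(t.strip() for t in str(cell).split(id_separator) if t.strip())
        row_ids.append(frozenset(ids))

    duplicates = [i for i, r in enumerate(row_ids) if row_ids.index(r) != i]
    if duplicates:
        logger.warning("table: %d duplicate row identifiers kept", len(duplicates))

    matrix = numeric[sample_cols].to_numpy(dtype=float)
    return DataSeries(
        name=name, row_ids=row_ids, samples=[str(c) for c in sample_cols],
        matrix=matrix, annotations=annotations, duplicate_rows=duplicates,
    )


def _extract_soft_table(text: str) -> tuple[str, dict[str, str]]:
    annotations: dict[str, str] = {}
    table_lines: list[str] = []
    in_table = False
    for line in text.splitlines():
        stripped = line.strip()
        low = stripped.lower()
        if low == "!sample_table_begin":
            in_table = True
            continue
        if low == "!sample_table_end":
            in_table = False
            continue
        if in_table:
            if stripped:
                table_lines.append(line)
        elif stripped.startswith("!") or stripped.startswith("^"):
            key, _, value = stripped.lstrip("!^").partition("=")
            annotations[key.strip()] = value.strip()
    if not table_lines:
        raise FormatError("SOFT input has no sample table")
    return "\n".join(table_lines), annotations
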