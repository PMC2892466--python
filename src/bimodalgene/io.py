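"""Reading and writing the tab-separated expression / survival formats.

Expression matrices follow the layout in which GEO series matrices are
usually consumed: a header row of sample ids, one row per gene with the gene
id in the first column, tab-separated, ``NA`` or empty cells for missing
values.  Survival tables are CSV with columns ``sample_id``, ``time`` and
``event`` (1 = event observed, 0 = right-censored).  Gene and sample ids are
opaque strings (probe-set ids and gene symbols are equally fine).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
]

log = logging.getLogger("bimodalgene")

#: float format used by every writer: pandas' shortest round-trip repr, which
#: is both exact on re-read and deterministic across identical runs
FLOAT_FORMAT = None


def read_expression(path) -> pd.DataFrame:
    """Parse a genes x samples TSV into a float DataFrame.

    Raises
    ------
    ParseError
        On ragged rows (with the offending line number), duplicated gene or
        sample ids, or an empty file.  Non-numeric cells become NaN.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        columns = header.rstrip("\n").split("\t")[1:]
        n_cols = len(columns)
        if len(set(columns)) != n_cols:
            raise ParseError(f"{path}: duplicate sample ids in header")
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row = np.empty(n_cols)
            for j, cell in enumerate(fields[1:]):
                try:
                    row[j] = float(cell)
                except ValueError:
                    row[j] = np.nan
            rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Index(gene_ids)
        dupes = sorted(set(dupes[dupes.duplicated()]))
        raise ParseError(f"{path}: duplicate gene ids {dupes[:5]}")
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_cols)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=columns,
    )


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples frame as TSV (missing cells as ``NA``)."""
    matrix.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA",
                  float_format=FLOAT_FORMAT)


def read_survival(path) -> pd.DataFrame:
    """Parse a survival CSV into a frame indexed by sample id.

    Requires columns ``sample_id``, ``time`` and ``event``; extra columns are
    ignored with a logged warning.

    Raises
    ------
    ValidationError
        On negative times, events outside {0, 1}, missing required columns or
        duplicated sample ids.
    """
    frame = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    extra = [c for c in frame.columns if c not in required]
    if extra:
        log.warning("%s: ignoring extra column(s) %s", path, extra)
    if frame["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    time = pd.to_numeric(frame["time"], errors="coerce")
    if time.isna().any() or (time < 0).any():
        raise ValidationError(f"{path}: times must be non-negative numbers")
    event = pd.to_numeric(frame["event"], errors="coerce")
    if not event.isin([0, 1]).all():
        raise ValidationError(f"{path}: event indicator must be 0 or 1")
    out = pd.DataFrame(
        {"time": time.to_numpy(dtype=float), "event": event.to_numpy(dtype=np.int8)},
        index=pd.Index(frame["sample_id"].astype(str), name="sample_id"),
    )
    return out


def write_survival(survival: pd.DataFrame, path) -> None:
    """Write a survival frame as CSV with sample_id, time, event columns."""
    survival.to_csv(path, index_label="sample_id", float_format=FLOAT_FORMAT)
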