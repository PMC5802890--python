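"""Readers and writers for expression matrices, clinical tables and labels.

All formats are plain delimited text.  The delimiter is inferred from the
file extension (``.tsv``/``.txt`` tab, ``.csv`` comma) and can be overridden.
Expression matrices are genes x samples with gene IDs in the first column and
sample IDs in the header.  Missing trait values (empty, ``NA``, ``NaN``) drop
the affected sample at alignment time rather than erroring, since public
tumour expression matrices routinely contain sporadic NAs.
"""

from __future__ import annotations

import difflib
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import BinaryTrait, ClinicalTable, CohortTrait, SurvivalOutcome

log = logging.getLogger("cutscan")

_NA_VALUES = ["", "NA", "NaN", "nan", "N/A", "null"]


def _delimiter(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def read_expression_matrix(path, gene: str | None = None, delimiter: str | None = None):
    """Read a genes x samples matrix; return one ``CohortTrait`` or a dict of them.

    With ``gene`` given, only that row is returned (samples with missing
    values for it are dropped, with a log line).  Duplicated gene IDs are an
    error; an unknown gene name raises with closest-match suggestions.
    """
    df = pd.read_csv(path, sep=_delimiter(path, delimiter), index_col=0,
                     na_values=_NA_VALUES, keep_default_na=False)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene IDs in {path}: {dups}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = df[col].map(lambda v: isinstance(v, str))
        row = df.index[bad.to_numpy().nonzero()[0][0]] if bad.any() else "?"
        raise ValueError(f"non-numeric expression value in {path} at gene {row!r}, sample {col!r}")

    def _row_trait(name: str) -> CohortTrait:
        row = df.loc[name]
        mask = row.notna().to_numpy()
        n_drop = int((~mask).sum())
        if n_drop:
            log.info("gene %s: dropped %d samples with missing expression", name, n_drop)
        return CohortTrait(df.columns.to_numpy(dtype=object)[mask],
                           row.to_numpy(dtype=float)[mask], name=str(name))

    if gene is not None:
        if gene not in df.index:
            close = difflib.get_close_matches(gene, [str(g) for g in df.index], n=3)
            hint = f"; closest matches: {close}" if close else ""
            raise KeyError(f"gene {gene!r} not found in {path}{hint}")
        return _row_trait(gene)
    return {str(g): _row_trait(g) for g in df.index}


def read_clinical_table(
    path,
    time_col: str,
    event_col: str,
    covariate_types: Mapping[str, str] | None = None,
    sample_col: str | None = None,
    delimiter: str | None = None,
):
    """Read per-sample clinical data; returns ``(SurvivalOutcome, ClinicalTable)``.

    ``sample_col`` defaults to the first column.  Samples with missing or
    non-positive survival time, or missing event status, are dropped with a
    log line.  ``covariate_types`` maps column name to ``'categorical'`` or
    ``'continuous'``; the returned ``ClinicalTable`` holds only those columns.
    """
    df = pd.read_csv(path, sep=_delimiter(path, delimiter),
                     na_values=_NA_VALUES, keep_default_na=False)
    if sample_col is None:
        sample_col = df.columns[0]
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    df = df.set_index(sample_col)
    t = pd.to_numeric(df[time_col], errors="coerce")
    e = pd.to_numeric(df[event_col], errors="coerce")
    ok = t.notna() & (t > 0) & e.isin([0, 1])
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("clinical table: dropped %d samples with unusable time/event", n_drop)
    df, t, e = df[ok], t[ok], e[ok]
    outcome = SurvivalOutcome(df.index.to_numpy(dtype=object), t.to_numpy(), e.to_numpy())
    covariate_types = dict(covariate_types or {})
    clin = ClinicalTable(df[list(covariate_types)], covariate_types)
    return outcome, clin


def read_binary_labels(path, label_col: str | None = None,
                       sample_col: str | None = None, delimiter: str | None = None) -> BinaryTrait:
    """Read a sample -> 0/1 table (first column samples, second labels by default)."""
    df = pd.read_csv(path, sep=_delimiter(path, delimiter),
                     na_values=_NA_VALUES, keep_default_na=False)
    if sample_col is None:
        sample_col = df.columns[0]
    if label_col is None:
        label_col = [c for c in df.columns if c != sample_col][0]
    g = pd.to_numeric(df[label_col], errors="coerce")
    ok = g.isin([0, 1])
    if (~ok).any():
        log.info("binary labels: dropped %d samples with non-binary labels", int((~ok).sum()))
    return BinaryTrait(df[sample_col][ok].to_numpy(dtype=object),
                       g[ok].to_numpy(), name=str(label_col))


def write_trait(trait: CohortTrait, path, delimiter: str | None = None) -> None:
    """Write a single trait as a one-row expression matrix (round-trips exactly)."""
    pd.DataFrame([trait.values], index=pd.Index([trait.name], name="gene"),
                 columns=trait.sample_ids).to_csv(path, sep=_delimiter(path, delimiter))
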