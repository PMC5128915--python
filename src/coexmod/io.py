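"""Reading, validation and preprocessing of expression matrices.

The on-disk format is a UTF-8 tab-delimited table: row 1 is
``GENE\t<sample ids...>``, each following row is one gene.  ``NA``,
``NaN``/``nan`` or an empty cell denotes a missing measurement.  Sample
class labels (e.g. ``normal`` / ``disease``) are never inferred from
sample names; they come from a two-column sidecar TSV
(``sample_id\tclass``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_MISSING_TOKENS = {"", "na", "nan", "null", "n/a"}


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued table with optional sample classes.

    Attributes
    ----------
    data : pandas.DataFrame
        Float matrix indexed by gene ID with sample IDs as columns.
        Missing measurements are ``NaN``.
    sample_class : pandas.Series or None
        Class label per sample (index == ``data.columns``).
    malformed_genes : set of str
        Gene IDs whose rows contained cells that failed numeric parsing;
        removed by :func:`preprocess` as "unformatted".
    """

    data: pd.DataFrame
    sample_class: pd.Series | None = None
    malformed_genes: set[str] = field(default_factory=set)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class PreprocessReport:
    """Counts of rows removed by each preprocessing rule."""

    unlabeled: int = 0
    unformatted: int = 0
    all_missing: int = 0
    duplicates: int = 0

    @property
    def total_removed(self) -> int:
        return self.unlabeled + self.unformatted + self.all_missing + self.duplicates


def _parse_cell(token: str) -> tuple[float, bool]:
    """Return (value, ok).  Missing tokens parse to NaN with ok=True."""
    t = token.strip()
    if t.lower() in _MISSING_TOKENS:
        return math.nan, True
    try:
        return float(t), True
    except ValueError:
        return math.nan, False


def read_expression(
    path,
    *,
    log2: bool = False,
    class_path=None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Parameters
    ----------
    path : path-like
        TSV file; first column gene IDs, header row holds sample IDs.
    log2 : bool
        If True, apply ``log2(x + 1)`` to all values after reading.
        Values are otherwise taken as-is (normalization and log
        transformation are assumed to have been done upstream).
    class_path : path-like, optional
        Two-column sidecar TSV mapping sample ID to class label.

    Raises
    ------
    ValueError
        On a row with the wrong number of columns (the message names the
        1-based line number) or on duplicate sample IDs.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [c.strip() for c in header[1:]]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {dupes}")
        ncol = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        malformed: set[str] = set()
        for lineno, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # blank line
            if len(fields) != ncol:
                raise ValueError(
                    f"line {lineno}: expected {ncol} columns, got {len(fields)}"
                )
            gid = fields[0].strip()
            vals = []
            ok_row = True
            for token in fields[1:]:
                v, ok = _parse_cell(token)
                vals.append(v)
                ok_row = ok_row and ok
            gene_ids.append(gid)
            rows.append(vals)
            if not ok_row and gid:
                malformed.add(gid)

    data = pd.DataFrame(rows, columns=sample_ids, dtype=float)
    data.index = pd.Index(gene_ids, name="GENE")
    if log2:
        data = np.log2(data + 1.0)

    sample_class = None
    if class_path is not None:
        sample_class = read_sample_classes(class_path, sample_ids)
    return ExpressionMatrix(data=data, sample_class=sample_class,
                            malformed_genes=malformed)


def read_sample_classes(path, sample_ids=None) -> pd.Series:
    """Read a two-column (sample_id, class) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["sample_id", "class"])
    ser = pd.Series(df["class"].values, index=df["sample_id"].values,
                    name="class")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in ser.index]
        if missing:
            raise ValueError(f"sample classes missing for: {missing}")
        ser = ser.loc[sample_ids]
    return ser


def preprocess(m: ExpressionMatrix) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Clean an expression matrix before similarity computation.

    Applies, in order: removal of rows with unlabeled (empty /
    whitespace-only) gene IDs, removal of rows with unformatted
    (non-numeric) value cells, removal of rows whose values are all
    missing, and collapse of duplicate gene IDs.  Duplicate collapse
    keeps the row with the fewest missing values, ties broken by first
    occurrence.  Partially missing rows are kept; downstream similarity
    uses pairwise-complete values.  The sample dimension never changes
    and row order is otherwise preserved, so the function is idempotent.
    """
    report = PreprocessReport()
    data = m.data

    labeled = np.array([bool(str(g).strip()) for g in data.index])
    report.unlabeled = int((~labeled).sum())
    data = data.loc[labeled]

    if m.malformed_genes:
        bad = data.index.isin(m.malformed_genes)
        report.unformatted = int(bad.sum())
        data = data.loc[~bad]

    all_missing = data.isna().all(axis=1).to_numpy()
    report.all_missing = int(all_missing.sum())
    data = data.loc[~all_missing]

    if data.index.has_duplicates:
        n_missing = data.isna().sum(axis=1).to_numpy()
        keep = np.ones(len(data), dtype=bool)
        best: dict[str, int] = {}
        for i, gid in enumerate(data.index):
            if gid not in best:
                best[gid] = i
            elif n_missing[i] < n_missing[best[gid]]:
                keep[best[gid]] = False
                best[gid] = i
            else:
                keep[i] = False
        report.duplicates = int((~keep).sum())
        data = data.loc[keep]

    if len(data) == 0:
        raise ValueError("empty after preprocessing")
    out = ExpressionMatrix(data=data.copy(), sample_class=m.sample_class,
                           malformed_genes=set())
    return out, report


def write_expression(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="GENE", na_rep="NA")


def write_sample_classes(sample_class: pd.Series, path) -> None:
    sample_class.to_csv(path, sep="\t", header=False)
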