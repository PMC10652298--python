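"""Tab-separated readers and writers for every pipeline table.

All tables are one-header-line TSV.  Missing values are written as the
explicit token ``NA`` (only where a field may legitimately be undefined);
blank numeric cells are rejected.  Floats are serialized at 12 significant
digits, so write -> read round-trips preserve values to that precision.
Row order is preserved by every reader.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import (
    CellTypeExpression,
    DegRecord,
    EphysCell,
    GoAnnotation,
    HomologPair,
    IntegratedRecord,
    PeakRecord,
    RecordValidationError,
)

NA_TOKEN = "NA"
_FLOAT_FMT = "%.12g"

PEAK_COLUMNS = ("chrom", "start", "end", "peak_id", "gene_symbol",
                "chromatin_state", "coef_abeta", "fdr")
DEG_COLUMNS = ("gene_symbol", "cell_type", "log2fc", "adj_p")
INTEGRATED_COLUMNS = ("gene_symbol", "cell_type", "coef_abeta", "log2fc",
                      "same_sign", "is_primary")
HOMOLOG_COLUMNS = ("human_gene", "fly_gene", "confidence")
EXPRESSION_COLUMNS = ("cell_type", "gene_symbol", "mean_expr", "frac_expressing")
GO_COLUMNS = ("term_id", "term_name", "genes")
EPHYS_COLUMNS = ("genotype", "phtx", "mepsp_mv", "epsp_mv")


class TableError(ValueError):
    """A table could not be parsed or failed validation.

    ``row`` is the 1-based data-row number (header excluded) of the
    offending line, or None for file-level problems.
    """

    def __init__(self, path, message: str, row: int | None = None):
        self.path = str(path)
        self.row = row
        where = f"{self.path}" + (f", row {row}" if row is not None else "")
        super().__init__(f"{where}: {message}")


def _fmt(value) -> str:
    if value is None:
        return NA_TOKEN
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


def _read_rows(path, expected_columns: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise TableError(path, "file does not exist")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableError(path, "empty file (missing header)") from None
        missing = set(expected_columns) - set(header)
        if missing:
            raise TableError(path, f"missing required column(s): {sorted(missing)}")
        idx = {c: header.index(c) for c in expected_columns}
        rows = []
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise TableError(path, f"expected {len(header)} fields, got {len(row)}", row=i)
            rows.append((i, {c: row[idx[c]] for c in expected_columns}))
    return rows


def _parse_float(raw: str, path, row: int, col: str) -> float:
    if raw.strip() == "" or raw == NA_TOKEN:
        raise TableError(path, f"missing numeric value in column {col!r}", row=row)
    try:
        return float(raw)
    except ValueError:
        raise TableError(path, f"malformed numeric value {raw!r} in column {col!r}",
                         row=row) from None


def _parse_int(raw: str, path, row: int, col: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise TableError(path, f"malformed integer {raw!r} in column {col!r}", row=row) from None


def _parse_bool(raw: str, path, row: int, col: str):
    low = raw.strip().lower()
    if low in ("true", "1"):
        return True
    if low in ("false", "0"):
        return False
    if raw == NA_TOKEN:
        return None
    raise TableError(path, f"malformed boolean {raw!r} in column {col!r}", row=row)


def _write_table(path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def _build(cls, path, row_no, **kwargs):
    try:
        return cls(**kwargs)
    except RecordValidationError as exc:
        raise TableError(path, str(exc), row=row_no) from None


# ---------------------------------------------------------------------------
# Peaks (BED-like: coordinate columns first)

def read_peaks(path) -> list[PeakRecord]:
    out = []
    for row_no, f in _read_rows(path, PEAK_COLUMNS):
        start = _parse_int(f["start"], path, row_no, "start")
        end = _parse_int(f["end"], path, row_no, "end")
        out.append(_build(
            PeakRecord, path, row_no,
            peak_id=f["peak_id"], chrom=f["chrom"], start=start, end=end,
            gene_symbol=f["gene_symbol"], chromatin_state=f["chromatin_state"],
            coef_abeta=_parse_float(f["coef_abeta"], path, row_no, "coef_abeta"),
            fdr=_parse_float(f["fdr"], path, row_no, "fdr")))
    return out


def write_peaks(records: Iterable[PeakRecord], path) -> None:
    _write_table(path, PEAK_COLUMNS,
                 ((r.chrom, r.start, r.end, r.peak_id, r.gene_symbol,
                   r.chromatin_state, r.coef_abeta, r.fdr) for r in records))


# ---------------------------------------------------------------------------
# DEGs

def read_degs(path) -> list[DegRecord]:
    out = []
    for row_no, f in _read_rows(path, DEG_COLUMNS):
        out.append(_build(
            DegRecord, path, row_no,
            gene_symbol=f["gene_symbol"], cell_type=f["cell_type"],
            log2fc=_parse_float(f["log2fc"], path, row_no, "log2fc"),
            adj_p=_parse_float(f["adj_p"], path, row_no, "adj_p")))
    return out


def write_degs(records: Iterable[DegRecord], path) -> None:
    _write_table(path, DEG_COLUMNS,
                 ((r.gene_symbol, r.cell_type, r.log2fc, r.adj_p) for r in records))


# ---------------------------------------------------------------------------
# Integrated records

def read_integrated(path) -> list[IntegratedRecord]:
    out = []
    for row_no, f in _read_rows(path, INTEGRATED_COLUMNS):
        out.append(_build(
            IntegratedRecord, path, row_no,
            gene_symbol=f["gene_symbol"], cell_type=f["cell_type"],
            coef_abeta=_parse_float(f["coef_abeta"], path, row_no, "coef_abeta"),
            log2fc=_parse_float(f["log2fc"], path, row_no, "log2fc"),
            same_sign=_parse_bool(f["same_sign"], path, row_no, "same_sign"),
            is_primary=bool(_parse_bool(f["is_primary"], path, row_no, "is_primary"))))
    return out


def write_integrated(records: Iterable[IntegratedRecord], path) -> None:
    _write_table(path, INTEGRATED_COLUMNS,
                 ((r.gene_symbol, r.cell_type, r.coef_abeta, r.log2fc,
                   r.same_sign, r.is_primary) for r in records))


# ---------------------------------------------------------------------------
# Homolog map

def read_homologs(path) -> list[HomologPair]:
    out = []
    for row_no, f in _read_rows(path, HOMOLOG_COLUMNS):
        out.append(_build(
            HomologPair, path, row_no,
            human_gene=f["human_gene"], fly_gene=f["fly_gene"],
            confidence=_parse_float(f["confidence"], path, row_no, "confidence")))
    return out


def write_homologs(records: Iterable[HomologPair], path) -> None:
    _write_table(path, HOMOLOG_COLUMNS,
                 ((r.human_gene, r.fly_gene, r.confidence) for r in records))


# ---------------------------------------------------------------------------
# Expression summaries (long format; one file can hold many cell types)

def read_expression(path) -> dict[str, CellTypeExpression]:
    rows = _read_rows(path, EXPRESSION_COLUMNS)
    by_ct: dict[str, list] = {}
    for row_no, f in rows:
        mean_expr = _parse_float(f["mean_expr"], path, row_no, "mean_expr")
        frac = _parse_float(f["frac_expressing"], path, row_no, "frac_expressing")
        by_ct.setdefault(f["cell_type"], []).append((f["gene_symbol"], mean_expr, frac))
    out = {}
    for ct, entries in by_ct.items():
        table = pd.DataFrame(entries, columns=["gene_symbol", "mean_expr", "frac_expressing"])
        table = table.set_index("gene_symbol")
        try:
            out[ct] = CellTypeExpression(cell_type=ct, table=table)
        except RecordValidationError as exc:
            raise TableError(path, str(exc)) from None
    return out


def write_expression(expr: Mapping[str, CellTypeExpression] | Iterable[CellTypeExpression],
                     path) -> None:
    if isinstance(expr, Mapping):
        expr = expr.values()
    rows = []
    for cte in expr:
        for gene, row in cte.table.iterrows():
            rows.append((cte.cell_type, gene, float(row["mean_expr"]),
                         float(row["frac_expressing"])))
    _write_table(path, EXPRESSION_COLUMNS, rows)


# ---------------------------------------------------------------------------
# GO annotation (gene sets comma-joined in one cell)

def read_go(path) -> list[GoAnnotation]:
    out = []
    for row_no, f in _read_rows(path, GO_COLUMNS):
        genes = frozenset(g for g in f["genes"].split(",") if g)
        out.append(_build(GoAnnotation, path, row_no,
                          term_id=f["term_id"], term_name=f["term_name"], genes=genes))
    return out


def write_go(records: Iterable[GoAnnotation], path) -> None:
    _write_table(path, GO_COLUMNS,
                 ((r.term_id, r.term_name, ",".join(sorted(r.genes))) for r in records))


# ---------------------------------------------------------------------------
# Electrophysiology cohort

def read_ephys(path) -> list[EphysCell]:
    out = []
    for row_no, f in _read_rows(path, EPHYS_COLUMNS):
        out.append(_build(
            EphysCell, path, row_no,
            genotype=f["genotype"], phtx=f["phtx"],
            mepsp_mv=_parse_float(f["mepsp_mv"], path, row_no, "mepsp_mv"),
            epsp_mv=_parse_float(f["epsp_mv"], path, row_no, "epsp_mv")))
    return out


def write_ephys(records: Iterable[EphysCell], path) -> None:
    _write_table(path, EPHYS_COLUMNS,
                 ((r.genotype, r.phtx, r.mepsp_mv, r.epsp_mv) for r in records))


# ---------------------------------------------------------------------------
# Bundle convenience

_READERS = {
    "peaks": read_peaks,
    "degs": read_degs,
    "integrated": read_integrated,
    "homologs": read_homologs,
    "human_expression": read_expression,
    "fly_expression": read_expression,
    "go": read_go,
    "ephys": read_ephys,
}


def read_tables(paths: Mapping[str, str]) -> dict:
    """Read a named set of tables.

    ``paths`` maps table names (a subset of: peaks, degs, integrated,
    homologs, human_expression, fly_expression, go, ephys) to file paths.
    """
    unknown = set(paths) - set(_READERS)
    if unknown:
        raise ValueError(f"unknown table name(s): {sorted(unknown)}")
    return {name: _READERS[name](path) for name, path in paths.items()}
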