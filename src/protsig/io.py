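"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices travel as TSV (first column = gene/probe ids, header row
= sample ids) or GCT 1.2.  Signatures travel as a two-column TSV
(gene, coefficient) or as a GMT pair of ``<NAME>_UP`` / ``<NAME>_DOWN`` sets.
Clinical tables are CSV with an optional column-mapping (YAML or dict).
Probe-level matrices are collapsed to gene level by per-gene averaging.

Gene symbols are matched case-sensitively after whitespace trimming; missing
cells are kept as NaN, never imputed here.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import CLINICAL_COLUMNS, ClinicalTable, ExpressionMatrix, GeneSignature
from .exceptions import DataFormatError, ValidationError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _read_header(handle, path) -> list:
    """Read a table header line without pandas' duplicate-name mangling."""
    header = [c.strip() for c in handle.readline().rstrip("\r\n").split("\t")]
    if len(header) < 2:
        raise DataFormatError(f"{path}: header row has no sample columns")
    names = pd.Index(header[1:])
    if names.has_duplicates:
        dups = names[names.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicate sample ids {dups}")
    return header


def _finish_expression_frame(frame: pd.DataFrame, path) -> ExpressionMatrix:
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicate sample ids {dups}")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicate row ids {dups}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric value {frame.iat[row, col]!r} at row "
            f"{frame.index[row]!r}, column {frame.columns[col]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def read_expression_matrix(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes-x-samples expression matrix from TSV or GCT 1.2.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"tsv", "gct"}
        ``tsv``: header row of sample ids, first column of gene/probe ids.
        ``gct``: the GCT 1.2 layout ("#1.2" line, dimensions line, then a
        table with Name and Description columns).
    """
    if format == "tsv":
        with open(path, "rt", encoding="utf-8") as handle:
            header = _read_header(handle, path)
            frame = pd.read_csv(handle, sep="\t", index_col=0, dtype=str,
                                header=None, names=header)
        return _finish_expression_frame(frame, path)
    if format == "gct":
        with open(path, "rt", encoding="utf-8") as handle:
            version = handle.readline().strip()
            if version not in ("#1.2",):
                raise DataFormatError(f"{path}: unsupported GCT version line {version!r}")
            dims = handle.readline().split()
            if len(dims) < 2:
                raise DataFormatError(f"{path}: malformed GCT dimensions line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            header = _read_header(handle, path)
            frame = pd.read_csv(handle, sep="\t", index_col=0, dtype=str,
                                header=None, names=header)
        frame = frame.drop(columns=["Description"], errors="ignore")
        if frame.shape != (n_rows, n_cols):
            raise DataFormatError(
                f"{path}: GCT header declares {(n_rows, n_cols)} but table is {frame.shape}"
            )
        return _finish_expression_frame(frame, path)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV or GCT 1.2 (UTF-8, LF endings)."""
    if format == "tsv":
        with open(path, "wt", encoding="utf-8", newline="\n") as handle:
            matrix.data.to_csv(handle, sep="\t", float_format=_FLOAT_FMT, index_label="gene")
        return
    if format == "gct":
        frame = matrix.data.copy()
        frame.insert(0, "Description", "na")
        with open(path, "wt", encoding="utf-8", newline="\n") as handle:
            handle.write("#1.2\n")
            handle.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            frame.to_csv(handle, sep="\t", float_format=_FLOAT_FMT, index_label="Name")
        return
    raise ValueError(f"unknown expression format {format!r}")


def read_probe_map(path) -> dict:
    """Read a two-column TSV (probe id, gene symbol) into a dict."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise DataFormatError(f"{path}: probe map needs two columns")
    return {
        str(p).strip(): str(g).strip()
        for p, g in zip(frame.iloc[:, 0], frame.iloc[:, 1])
    }


def collapse_probes_to_genes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by per-gene averaging.

    Each gene's value per sample is the arithmetic mean of its probes'
    values in that sample; missing probe values are excluded from the mean.
    Probes absent from the map are dropped (the count is logged).
    """
    probe_map = {str(k).strip(): str(v).strip() for k, v in probe_map.items()}
    for probe, gene in probe_map.items():
        if not gene:
            raise ValidationError(f"probe {probe!r} maps to an empty symbol")
    mapped = [p for p in matrix.data.index if p in probe_map]
    n_dropped = matrix.n_genes - len(mapped)
    if not mapped:
        raise ValidationError("no probe in the matrix is present in the probe map")
    if n_dropped:
        logger.info("collapse_probes_to_genes: dropped %d unmapped probes", n_dropped)
    sub = matrix.data.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes, sort=True).mean()
    return ExpressionMatrix(collapsed)


def read_signature(path) -> GeneSignature:
    """Read a signed gene signature from 2-column TSV or GMT UP/DOWN pair.

    The TSV layout is ``gene<TAB>coefficient`` with coefficients in
    {-1, +1}; an optional header line ``gene\\tcoefficient`` is skipped.
    A GMT file must contain exactly one ``<NAME>_UP`` and/or ``<NAME>_DOWN``
    line pair sharing the same stem.
    """
    with open(path, "rt", encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise DataFormatError(f"{path}: empty signature file")
    first = lines[0].split("\t")
    is_gmt = len(first) >= 2 and (
        first[0].endswith("_UP") or first[0].endswith("_DOWN")
    )
    entries = []
    if is_gmt:
        name = None
        for line in lines:
            fields = line.split("\t")
            setname = fields[0]
            if setname.endswith("_UP"):
                stem, coef = setname[: -len("_UP")], 1
            elif setname.endswith("_DOWN"):
                stem, coef = setname[: -len("_DOWN")], -1
            else:
                raise DataFormatError(
                    f"{path}: GMT set name {setname!r} must end in _UP or _DOWN"
                )
            if name is None:
                name = stem
            elif name != stem:
                raise DataFormatError(f"{path}: mixed GMT signature stems {name!r}/{stem!r}")
            # field 2 is the GMT description slot; genes start at field 3
            for gene in fields[2:]:
                if gene.strip():
                    entries.append((gene.strip(), coef))
        return GeneSignature(tuple(entries), name=name or "signature")
    start = 1 if first[0].lower() == "gene" else 0
    for line in lines[start:]:
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataFormatError(f"{path}: malformed signature line {line!r}")
        gene = fields[0].strip()
        try:
            coef = int(float(fields[1]))
        except ValueError as exc:
            raise DataFormatError(f"{path}: non-numeric coefficient {fields[1]!r}") from exc
        if coef not in (-1, 1) or float(fields[1]) != coef:
            raise ValidationError(f"{path}: coefficient for {gene} must be -1 or +1")
        entries.append((gene, coef))
    return GeneSignature(tuple(entries))


def write_signature(signature: GeneSignature, path, format: str = "tsv") -> None:
    """Write a signature as 2-column TSV or as a GMT UP/DOWN pair."""
    if format == "tsv":
        with open(path, "wt", encoding="utf-8", newline="\n") as handle:
            handle.write("gene\tcoefficient\n")
            for gene, coef in signature.entries:
                handle.write(f"{gene}\t{coef:+d}\n")
        return
    if format == "gmt":
        up = [g for g, c in signature.entries if c == 1]
        down = [g for g, c in signature.entries if c == -1]
        with open(path, "wt", encoding="utf-8", newline="\n") as handle:
            if up:
                handle.write("\t".join([f"{signature.name}_UP", "na"] + up) + "\n")
            if down:
                handle.write("\t".join([f"{signature.name}_DOWN", "na"] + down) + "\n")
        return
    raise ValueError(f"unknown signature format {format!r}")


def read_clinical_table(path, column_map: Optional[Mapping[str, str]] = None) -> ClinicalTable:
    """Read a clinical CSV into a validated :class:`ClinicalTable`.

    ``column_map`` maps the canonical field names (``sample_id``, ``time``,
    ``event``, ``treatment``, ``er_status``, ``age``, ``tumor_size``,
    ``grade``, ``nodal_status``) to the column names used in the file.
    """
    frame = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in frame.columns}
    frame = frame.rename(columns=rename)
    id_col = "sample_id" if "sample_id" in frame.columns else frame.columns[0]
    frame[id_col] = frame[id_col].astype(str).str.strip()
    frame = frame.set_index(id_col)
    frame.index.name = "sample_id"
    keep = [c for c in CLINICAL_COLUMNS if c in frame.columns]
    missing = {"time", "event"} - set(keep)
    if missing:
        raise DataFormatError(f"{path}: clinical table missing columns {sorted(missing)}")
    table = ClinicalTable(frame[keep])
    n_unusable = int((~table.usable_for_survival).sum())
    if n_unusable:
        logger.info(
            "read_clinical_table: %d rows lack time/event and are excluded "
            "from survival operations", n_unusable,
        )
    return table


def write_clinical_table(table: ClinicalTable, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        table.data.to_csv(handle, float_format=_FLOAT_FMT, index_label="sample_id")


def read_protein_values(path) -> pd.Series:
    """Read per-sample protein values from a 2-column TSV (sample, value)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    series = pd.to_numeric(frame.iloc[:, 0], errors="raise")
    series.index = series.index.astype(str).str.strip()
    if series.index.has_duplicates:
        raise DataFormatError(f"{path}: duplicate sample ids")
    return series.astype(float)


def write_protein_values(values: pd.Series, path, name: str = "protein") -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        values.rename(name).to_csv(
            handle, sep="\t", float_format=_FLOAT_FMT, index_label="sample_id"
        )
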