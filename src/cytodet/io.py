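"""Tab-delimited readers and writers for all pipeline tables.

Expression matrices: first column probe id, optional second column gene
symbol (header ``gene`` or ``symbol``), remaining columns one per sample.
A GCT-style dialect is accepted: a ``#1.2``-style version line followed
by a dimensions line before the header.  Detection P-values come in a
separate file of identical shape and identical probe/sample order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleMetadata

GENE_COLUMN_NAMES = {"gene", "gene_symbol", "symbol", "description"}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#"):  # GCT-style: version line + dimensions line
            skip = 2
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed table ({exc})") from exc
    return df


def _numeric_block(df: pd.DataFrame, path, columns) -> pd.DataFrame:
    block = df[columns]
    try:
        return block.astype(float)
    except ValueError:
        for i, row in enumerate(block.itertuples(index=False), start=2):
            for v in row:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {v!r} at line {i}"
                    ) from None
        raise


def read_expression(path, detection_path=None) -> ExpressionMatrix:
    """Read a log2 expression matrix, optionally with detection P-values."""
    df = _read_table(path)
    probe_col = df.columns[0]
    gene_col = df.columns[1] if df.columns[1].lower() in GENE_COLUMN_NAMES else None
    sample_cols = [c for c in df.columns[1:] if c != gene_col]
    probes = pd.Index(df[probe_col], name="probe_id")
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].unique()
        raise ValueError(f"{path}: duplicate probe id {dup[0]!r}")
    if df[sample_cols].isna().any().any():
        raise ValueError(f"{path}: missing cells in expression matrix")
    values = _numeric_block(df, path, sample_cols)
    values.index = probes
    genes = None
    if gene_col is not None:
        genes = pd.Series(df[gene_col].to_numpy(), index=probes, name="gene")

    detection = None
    if detection_path is not None:
        ddf = _read_table(detection_path)
        d_samples = [c for c in ddf.columns[1:] if c.lower() not in GENE_COLUMN_NAMES]
        d_probes = pd.Index(ddf[ddf.columns[0]], name="probe_id")
        if list(d_probes) != list(probes) or d_samples != sample_cols:
            raise ValueError(
                f"{detection_path}: probe/sample order does not match {path} "
                "(order must match exactly)"
            )
        detection = _numeric_block(ddf, detection_path, d_samples)
        detection.index = d_probes
    return ExpressionMatrix(values=values, detection_p=detection, gene_symbols=genes)


def write_expression(expr: ExpressionMatrix, path, detection_path=None) -> None:
    out = expr.values.copy()
    out.insert(0, "probe_id", expr.probe_ids)
    if expr.gene_symbols is not None:
        out.insert(1, "gene", expr.gene_symbols.to_numpy())
    out.to_csv(path, sep="\t", index=False)
    if detection_path is not None and expr.detection_p is not None:
        d = expr.detection_p.copy()
        d.insert(0, "probe_id", expr.probe_ids)
        d.to_csv(detection_path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata requires a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_cytokines(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df["concentration_pg_ml"] = df["concentration_pg_ml"].astype(float)
    return df


def write_cytokines(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.Series:
    """Dosage table: columns sample_id, dosage (0/1/2)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    dos = df.set_index("sample_id")["dosage"].astype(int)
    bad = dos[~dos.isin((0, 1, 2))]
    if len(bad):
        raise ValueError(f"{path}: dosages must be 0/1/2, got {bad.iloc[0]}")
    return dos


def read_genotypes_vcf(path, snp_id: str | None = None) -> pd.Series:
    """Minimal VCF adapter: biallelic sites, GT field only.

    Returns minor(ALT)-allele dosage per sample for the requested site
    (or the first site when ``snp_id`` is None).
    """
    with open(path) as fh:
        samples = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}: missing #CHROM header line")
            fields = line.split("\t")
            if snp_id is not None and fields[2] != snp_id:
                continue
            if "," in fields[4]:
                raise ValueError(f"{path}: multi-allelic site {fields[2]!r} unsupported")
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            dosages = {}
            for s, cell in zip(samples, fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    continue
                dosages[s] = sum(int(a) for a in alleles)
            return pd.Series(dosages, name="dosage", dtype=int)
    raise ValueError(f"{path}: site {snp_id!r} not found")


def read_qpcr(path) -> pd.DataFrame:
    """qPCR input: sample_id, group, target_ct, reference_ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("target_ct", "reference_ct"):
        df[col] = df[col].astype(float)
        if not np.isfinite(df[col]).all():
            raise ValueError(f"{path}: non-finite Ct in column {col}")
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sample_id": str})
    df["passes"] = df["passes"].astype(bool)
    return df


def write_recurrence(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in ("carriers_under", "carriers_over"):
        if col in out.columns:
            out[col] = out[col].map(lambda ids: ",".join(ids))
    out.to_csv(path, sep="\t", index=True, index_label="probe_id")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
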