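"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 0-based half-open internally; conversion happens only at
format boundaries (GFF3 is 1-based inclusive on disk, BED6 is already
half-open). Gene-id matching everywhere is exact and case-sensitive.

In-memory containers are plain :class:`pandas.DataFrame` objects with
documented column contracts:

* annotation: ``gene_id, chrom, start, end, strand, operon_id`` sorted by
  ``(chrom, start, gene_id)``;
* differential-expression (DE) table: ``gene_id, log2fc, pvalue, fdr,
  mean_expr`` with condition/strain labels in ``df.attrs``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "operon_id"]
DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "fdr", "mean_expr"]


class FormatError(ValueError):
    """A malformed input file (carries the offending line number)."""


def _finalize_annotation(df: pd.DataFrame, chrom_order=None) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in annotation")
    if chrom_order is not None:
        df["chrom"] = pd.Categorical(df["chrom"], categories=list(chrom_order), ordered=True)
    df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    return df[ANNOTATION_COLUMNS]


def _attr_field(attrs: str, keys=("ID", "gene_id", "Name")) -> str | None:
    for part in attrs.strip().strip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def read_annotation(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene annotation from GFF3 or BED6.

    ``fmt`` is auto-detected from the extension (``.gff``/``.gff3`` vs
    ``.bed``) unless given explicitly. GFF3 keeps only ``gene`` features and
    converts 1-based inclusive coordinates to 0-based half-open.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".gff", ".gff3"):
            fmt = "GFF3"
        elif suffix == ".bed":
            fmt = "BED6"
        else:
            raise ValueError(f"cannot auto-detect annotation format from {path.name!r}")
    fmt = fmt.upper()
    if fmt not in ("GFF3", "BED6"):
        raise ValueError(f"unsupported annotation format {fmt!r}")

    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "GFF3":
                if len(fields) != 9:
                    raise FormatError(f"{path.name}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
                if fields[2] != "gene":
                    continue
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
                gene_id = _attr_field(fields[8])
                if gene_id is None:
                    raise FormatError(f"{path.name}:{lineno}: no ID/gene_id attribute")
                if start1 < 1 or end1 < start1:
                    raise FormatError(f"{path.name}:{lineno}: invalid GFF3 interval {start1}-{end1}")
                records.append((gene_id, fields[0], start1 - 1, end1, fields[6] if fields[6] in "+-" else "."))
            else:  # BED6
                if len(fields) < 6:
                    raise FormatError(f"{path.name}:{lineno}: expected 6 BED columns, got {len(fields)}")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
                if start < 0 or end <= start:
                    raise FormatError(f"{path.name}:{lineno}: invalid BED interval {start}-{end}")
                records.append((fields[3], fields[0], start, end, fields[5] if fields[5] in "+-" else "."))
    df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["operon_id"] = None
    return _finalize_annotation(df)


def write_annotation_gff3(annotation: pd.DataFrame, path) -> None:
    """Write gene features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            if getattr(row, "operon_id", None):
                attrs += f";operon_id={row.operon_id}"
            fh.write(
                f"{row.chrom}\tseesawtx\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def write_annotation_bed6(annotation: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n")


def read_de_table(path, condition: str | None = None, strain: str | None = None) -> pd.DataFrame:
    """Read a per-gene differential-expression table (TSV with header).

    Rows with missing ``log2fc`` or ``pvalue`` are dropped (count logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing required column(s) {missing}")
    n0 = len(df)
    df = df.dropna(subset=["log2fc", "pvalue"]).reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.warning("%s: dropped %d row(s) with missing log2fc/pvalue", Path(path).name, dropped)
    for col in ("pvalue", "fdr"):
        vals = df[col].to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            raise FormatError(f"{Path(path).name}: {col} outside [0,1] for gene {df.loc[bad.argmax(), 'gene_id']!r}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{Path(path).name}: duplicate gene_id")
    df = df[DE_COLUMNS].copy()
    df.attrs["condition"] = condition
    df.attrs["strain"] = strain
    df.attrs["n_dropped"] = dropped
    logger.info("%s: %d genes in universe", Path(path).name, len(df))
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    de[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")


def read_gene_list(path) -> set[str]:
    """Read a one-id-per-line gene list into a set (duplicates logged)."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    out = set(ids)
    dups = len(ids) - len(out)
    if dups:
        logger.warning("%s: removed %d duplicate id(s)", Path(path).name, dups)
    if not out:
        logger.warning("%s: empty gene list", Path(path).name)
    return out


def write_gene_list(ids, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


def read_operon_table(path) -> dict[str, list[str]]:
    """Read a TSV ``operon_id  gene_id  rank`` into operon -> ordered members."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "operon_id":
                continue
            if len(fields) < 3:
                raise FormatError(f"{Path(path).name}:{lineno}: expected 3 columns")
            rows.append((fields[0], fields[1], int(fields[2])))
    mapping: dict[str, list[tuple[int, str]]] = {}
    for op, gid, rank in rows:
        mapping.setdefault(op, []).append((rank, gid))
    return {op: [g for _, g in sorted(members)] for op, members in mapping.items()}


def write_operon_table(operons: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("operon_id\tgene_id\trank\n")
        for op in sorted(operons):
            for rank, gid in enumerate(operons[op], start=1):
                fh.write(f"{op}\t{gid}\t{rank}\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    return obj


def write_results(tables: dict[str, pd.DataFrame], summary: dict, out_dir) -> Path:
    """Write result tables (TSV, full precision + rounded display columns)
    and a machine-readable JSON summary. Deterministic: reruns on identical
    inputs produce byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        out = df.copy()
        for col in list(out.columns):
            if pd.api.types.is_float_dtype(out[col]):
                out[f"{col}_display"] = out[col].round(4)
        out.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                   float_format="%.17g", lineterminator="\n")
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary_path
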