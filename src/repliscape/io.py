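"""Readers and writers for the plain-text formats the pipeline uses.

Internal coordinates are universally 0-based half-open; GFF3 (1-based
inclusive) is converted at the boundary. All writers are deterministic.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "load_config",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"]


class FormatError(ValueError):
    pass


def read_bed(path) -> pd.DataFrame:
    """BED (3-6 columns), 0-based half-open, as a DataFrame."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
            for key, val in zip(BED_COLUMNS[3:], parts[3:]):
                row[key] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    out = df[cols].copy()
    if "score" in out.columns:
        out["score"] = out["score"].fillna(0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    """GFF3 features converted to internal 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
            try:
                start = int(parts[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(parts[4])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            rows.append({"chrom": parts[0], "source": parts[1], "type": parts[2],
                         "start": start, "end": end, "score": parts[5],
                         "strand": parts[6], "phase": parts[7], "attributes": attrs})
    return pd.DataFrame(rows)


def write_gff3(df: pd.DataFrame, path) -> None:
    """Write features (internal coordinates) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in df.iterrows():
            attrs = r.get("attributes", {})
            if isinstance(attrs, dict):
                attrs = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [str(r["chrom"]), str(r.get("source", ".")),
                     str(r.get("type", "region")), str(int(r["start"]) + 1),
                     str(int(r["end"])), str(r.get("score", ".")),
                     str(r.get("strand", ".")), str(r.get("phase", ".")),
                     attrs or "."]
                ) + "\n"
            )


def read_counts_tsv(path) -> pd.DataFrame:
    """Feature x sample table (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_bedgraph(
    bins: pd.DataFrame, values: np.ndarray, path
) -> None:
    """Write per-bin values as bedGraph, merging adjacent equal values.

    Bins must be sorted and non-overlapping within each chromosome;
    NaN-valued bins are skipped.
    """
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        prev = None
        for (_, b), v in zip(bins.iterrows(), values):
            if prev is not None and b["chrom"] == prev[0] and b["start"] < prev[2]:
                raise ValueError("overlapping bins")
            if np.isnan(v):
                if prev is not None:
                    fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]:g}\n")
                    prev = None
                continue
            if prev is not None and prev[0] == b["chrom"] and prev[2] == b["start"] \
                    and prev[3] == v:
                prev = (prev[0], prev[1], b["end"], v)
            else:
                if prev is not None:
                    fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]:g}\n")
                prev = (b["chrom"], b["start"], b["end"], v)
        if prev is not None:
            fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    return df


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def load_config(path, schema=None) -> dict:
    """YAML config; unknown keys are rejected against the schema.

    ``schema`` is a dataclass type (its field names are the allowed
    keys) or an iterable of allowed key names.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    if schema is not None:
        if is_dataclass(schema):
            allowed = {f.name for f in fields(schema)}
        else:
            allowed = set(schema)
        unknown = set(cfg) - allowed
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_resolved_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
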