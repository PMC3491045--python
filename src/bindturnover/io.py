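"""Readers and writers for the standard text formats shared across stages.

A single internal coordinate convention is used everywhere: 0-based,
half-open intervals on the + strand of the reference. Conversions to the
1-based conventions of GFF3 (inclusive) and fixedStep wiggle happen here,
at the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


class FormatError(ValueError):
    """Raised when a file violates its format's coordinate conventions."""


# ---------------------------------------------------------------------------
# BED6 (0-based, half-open)
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6 table. ``start``/``end`` are internal 0-based half-open."""
    out = df.loc[:, BED6_COLUMNS]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BED6_COLUMNS, dtype={"chrom": str, "name": str})
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise FormatError(
            f"{path}: BED interval with end<=start or start<0 at line {bad[0] + 1}"
        )
    return df


# ---------------------------------------------------------------------------
# GFF3 (1-based, inclusive)
# ---------------------------------------------------------------------------

def write_gff3(df: pd.DataFrame, path) -> None:
    """Write features to GFF3. Input ``start``/``end`` are internal 0-based
    half-open; stored as 1-based inclusive."""
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out = out.loc[:, GFF3_COLUMNS]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=GFF3_COLUMNS, dtype={"seqid": str, "attributes": str})
    bad = df.index[df["start"] < 1]
    if len(bad):
        raise FormatError(f"{path}: GFF3 start<1 at data line {bad[0] + 1}")
    df["start"] = df["start"] - 1  # back to 0-based half-open
    return df


def gff3_attribute(attributes: str, key: str) -> str | None:
    for field in attributes.split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


# ---------------------------------------------------------------------------
# fixedStep wiggle (1-based starts)
# ---------------------------------------------------------------------------

def write_wiggle(values: np.ndarray, chrom: str, path, start: int = 0,
                 step: int = 1) -> None:
    """Write a dense track as fixedStep wiggle. ``start`` is internal 0-based."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start={start + 1} step={step}\n")
        np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.6g")


def read_wiggle(path) -> tuple[str, int, np.ndarray]:
    """Return (chrom, internal 0-based start, values)."""
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "fixedStep":
            raise FormatError(f"{path}: expected fixedStep header at line 1")
        fields = dict(kv.split("=") for kv in header[1:])
        start = int(fields["start"])
        if start < 1:
            raise FormatError(f"{path}: wiggle start<1 at line 1")
        values = np.loadtxt(fh, ndmin=1)
    return fields["chrom"], start - 1, values


# ---------------------------------------------------------------------------
# FASTA panels (Biopython-backed)
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    seqio_write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()],
        path, "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse
    return {rec.id: str(rec.seq) for rec in parse(path, "fasta")}


# ---------------------------------------------------------------------------
# TSV + manifests
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: dict | None = None) -> Path:
    """Checksum every artifact in ``outdir`` into manifest.json."""
    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config or {},
        "files": {str(p.relative_to(outdir)): sha256_file(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
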