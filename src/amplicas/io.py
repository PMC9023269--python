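"""Sequence and table I/O: FASTA/FASTQ (gzip-aware), TSV/JSON artifacts.

All TSV artifacts start with ``#`` header lines carrying the tool version,
a hash of the run configuration and the seed, so a run can be reproduced
byte-for-byte from its own output.  Coordinates in outputs are 0-based,
half-open.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

from Bio import SeqIO

from . import __version__

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_count_table",
    "tsv_header",
    "write_tsv",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    suffix = Path(name).suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")


def read_sequences(path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ records as ``(id, uppercase sequence)`` tuples.

    Format is inferred from the extension unless given; ``.gz`` files are
    decompressed transparently.  Malformed records raise ``ValueError``
    naming the file.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    try:
        with _open_text(path) as fh:
            return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    except ValueError as e:
        raise ValueError(f"malformed {fmt} in {path}: {e}") from e


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(path, records: list[tuple[str, str]], quality_char: str = "I") -> None:
    """Write reads with a constant quality string (synthetic reads carry no qualities)."""
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_count_table(path) -> tuple[list[str], list[str], list[list[int]]]:
    """Read a labeled count TSV: first row column labels, first column row labels."""
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 3:
        raise ValueError("count table needs a header row and at least two data rows")
    cols = lines[0].split("\t")[1:]
    row_labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        row_labels.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    return row_labels, cols, rows


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def tsv_header(config: dict, seed=None) -> str:
    lines = [
        f"# amplicas {__version__}",
        f"# config_hash={config_hash(config)} seed={seed}",
        "# coordinates are 0-based, half-open",
    ]
    return "\n".join(lines) + "\n"


def write_tsv(path, columns: list[str], rows: list[list], config: dict, seed=None) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(tsv_header(config, seed))
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
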