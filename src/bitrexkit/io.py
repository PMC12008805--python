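"""File-format helpers: FASTA/FASTQ via Biopython, BED, and trajectory TSV.

All genomic coordinates are 0-based half-open throughout the package.
"""
from __future__ import annotations

import gzip
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with _open_text(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


def read_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path, "r") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fastq(reads, path) -> None:
    """Write SimRead-like objects (``.read_id``, ``.sequence``) as FASTQ.

    Dummy 'I' qualities (Q40) are emitted; the simulator models substitution
    errors in the base calls themselves, not in the quality track.
    """
    with _open_text(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_sequences(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (optionally gzipped), sniffing by extension."""
    name = str(path)
    base = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if base.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path, "r") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_bed(intervals: Iterable[Sequence], path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bedgraph(profile, path) -> None:
    """Write a DepthProfile as bedGraph (one row per bin)."""
    with open(path, "w") as fh:
        for chrom, vals in profile.values.items():
            length = profile.lengths[chrom]
            for i, v in enumerate(vals):
                start = i * profile.bin_size
                end = min(start + profile.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def write_series_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_series_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
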