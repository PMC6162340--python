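"""File-format helpers: FASTA/FASTQ via Biopython, BED intervals, manifests."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .calling import SampleReads
from .template import VGeneTemplate

__all__ = [
    "read_template_fasta",
    "read_bed_intervals",
    "read_reads",
    "read_manifest",
]


def read_template_fasta(fasta_path, bed_path=None) -> VGeneTemplate:
    """Load a single-record template FASTA, optionally with CDR BED intervals."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single-record FASTA, found {len(records)} records")
    rec = records[0]
    cdrs = tuple(read_bed_intervals(bed_path)) if bed_path else ()
    return VGeneTemplate(rec.id, str(rec.seq), cdrs)


def read_bed_intervals(path) -> list[tuple[int, int]]:
    """3+ column BED (0-based, half-open); returns sorted (start, end) pairs."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line has fewer than 3 columns: {line!r}")
            intervals.append((int(fields[1]), int(fields[2])))
    return sorted(intervals)


def read_reads(path, mode: str, sample_id: str, n_cells_sorted: int) -> SampleReads:
    """Load a FASTA (sanger) or FASTQ (ngs) read file into a SampleReads."""
    fmt = "fasta" if mode == "sanger" else "fastq"
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
    return SampleReads(sample_id=sample_id, n_cells_sorted=n_cells_sorted,
                       reads=reads, mode=mode)


def read_manifest(path) -> pd.DataFrame:
    """Sample manifest CSV with columns sample_id, file, n_cells_sorted, mode."""
    df = pd.read_csv(path)
    required = {"sample_id", "file", "n_cells_sorted", "mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    df["file"] = df["file"].map(lambda p: str(p) if Path(p).is_absolute()
                                else str(base / p) if not Path(p).exists() else str(p))
    return df
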