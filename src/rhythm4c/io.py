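"""Plain-text readers/writers for the formats used across the pipeline.

All genomic coordinates are 0-based half-open, matching BED/bedGraph.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fourc_prep import CountMatrix
from .synthgen import ActivityTrace

__all__ = [
    "read_fasta",
    "write_fragment_bed",
    "write_bedgraph",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_actogram_tsv",
    "read_actogram_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small, uncompressed) FASTA file into ``{name: sequence}``."""
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            elif name is None:
                raise ValueError(f"{path}: sequence data before any header")
            else:
                sequences[name].append(line)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return {k: "".join(v) for k, v in sequences.items()}


def write_fragment_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    """Fragment map as BED6 with the fragment id in the name column."""
    bed = fragments[["chrom", "start", "end", "fragment_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "."
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    intervals: pd.DataFrame, value_column: str, path: str | Path, chrom_column: str = "chrom"
) -> None:
    """Write ``chrom start end value`` rows (non-finite values skipped)."""
    df = intervals[[chrom_column, "start", "end", value_column]].copy()
    df = df[np.isfinite(df[value_column])]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_counts_tsv(cm: CountMatrix, prefix: str | Path) -> None:
    """Write counts, fragment map and sample metadata as three TSVs."""
    prefix = Path(prefix)
    merged = cm.counts.merge(
        cm.fragments[["fragment_id", "chrom", "start", "end"]], on="fragment_id"
    )
    cols = ["fragment_id", "chrom", "start", "end", "end1", "end2", "sample_id"]
    extra = [c for c in ("score", "norm_score") if c in merged]
    merged[cols + extra].to_csv(f"{prefix}.counts.tsv", sep="\t", index=False)
    cm.fragments.to_csv(f"{prefix}.fragments.tsv", sep="\t", index=False)
    cm.samples.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def read_counts_tsv(prefix: str | Path, bait: str | None = None) -> CountMatrix:
    """Read the TSV triple written by :func:`write_counts_tsv`.

    ``bait`` is ``"chrom:pos"``; when given, the fragment table's bait
    annotation is recomputed.
    """
    from .fourc_prep import annotate_bait

    prefix = Path(prefix)
    counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t")
    fragments = pd.read_csv(f"{prefix}.fragments.tsv", sep="\t")
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    bait_chrom, bait_pos = None, None
    if bait is not None:
        bait_chrom, pos = bait.rsplit(":", 1)
        bait_pos = int(pos)
        fragments = annotate_bait(fragments, bait_chrom, bait_pos)
    keep = [c for c in counts.columns if c in
            ("fragment_id", "sample_id", "end1", "end2", "score", "norm_score")]
    return CountMatrix(
        fragments=fragments,
        counts=counts[keep],
        samples=samples,
        bait_chrom=bait_chrom,
        bait_pos=bait_pos,
    )


def write_actogram_tsv(trace: ActivityTrace, path: str | Path) -> None:
    """Two columns: minutes since start, counts."""
    minutes = np.arange(trace.counts.size) * trace.bin_minutes
    pd.DataFrame({"minutes": minutes, "counts": trace.counts}).to_csv(
        path, sep="\t", index=False
    )


def read_actogram_tsv(path: str | Path) -> ActivityTrace:
    df = pd.read_csv(path, sep="\t")
    if len(df) < 2:
        raise ValueError("actogram needs at least two bins")
    bin_minutes = int(df["minutes"].iloc[1] - df["minutes"].iloc[0])
    return ActivityTrace(counts=df["counts"].to_numpy(), bin_minutes=bin_minutes)
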