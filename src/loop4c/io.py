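"""Standard-format I/O: FASTA/FASTQ, BED/bedGraph, count tables, TIFF.

All genomic output is 0-based half-open (BED conventions).  Tables are TSV
with ``#``-prefixed provenance header lines (package version + configuration
hash) so any result file names the code and settings that produced it.
"""

from __future__ import annotations

import gzip
import hashlib
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_maybe_gzip(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str) -> dict[str, str]:
    """Multi-record, wrapped-line FASTA into {name: uppercase sequence}."""
    with _open_maybe_gzip(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_fastq(path: str):
    """Iterate FASTQ records; transparently handles .gz."""
    with _open_maybe_gzip(path) as handle:
        yield from SeqIO.parse(handle, "fastq")


def write_fastq(reads: Iterable, path: str) -> None:
    """Write reads (SeqRecords or plain strings) as FASTQ."""
    with _open_maybe_gzip(path, "wt") as handle:
        for i, read in enumerate(reads):
            if isinstance(read, str):
                read = SeqRecord(
                    Seq(read),
                    id=f"read{i}",
                    description="",
                    letter_annotations={"phred_quality": [40] * len(read)},
                )
            SeqIO.write(read, handle, "fastq")


def write_bed(intervals: pd.DataFrame | list, path: str, name_col: str | None = None) -> None:
    """BED (chrom, start, end[, name]); accepts a DataFrame or (chrom, start, end) tuples."""
    with open(path, "w") as handle:
        if isinstance(intervals, pd.DataFrame):
            for _, row in intervals.iterrows():
                fields = [row["chrom"], row["start"], row["end"]]
                if name_col is not None:
                    fields.append(row[name_col])
                handle.write("\t".join(str(f) for f in fields) + "\n")
        else:
            for iv in intervals:
                handle.write("\t".join(str(f) for f in iv) + "\n")


def read_bed(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame.columns = ["chrom", "start", "end", "name"][: frame.shape[1]]
    return frame


def write_bedgraph(fragends: pd.DataFrame, values: np.ndarray, path: str) -> None:
    """Per-fragment bedGraph; masked/NaN positions are omitted (no coverage), not zeros."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as handle:
        for (_, row), v in zip(fragends.iterrows(), values):
            if np.isnan(v):
                continue
            handle.write(f"{row['chrom']}\t{row['frag_start']}\t{row['frag_end']}\t{v:.6g}\n")


COUNT_COLUMNS = [
    "fragend_id",
    "chrom",
    "frag_start",
    "frag_end",
    "side",
    "anchor_pos",
    "ref_chrom",
    "ref_anchor",
    "count",
]


def write_counts(table: pd.DataFrame, path: str) -> None:
    out = table.copy()
    if "ref_chrom" not in out.columns:
        out["ref_chrom"] = out["chrom"]
        out["ref_anchor"] = out["anchor_pos"]
    out[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(config: Mapping) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def provenance_lines(config: Mapping | None = None) -> list[str]:
    from . import __version__

    lines = [f"# loop4c {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config_hash(config)}")
    return lines


def write_table(frame: pd.DataFrame, path: str, config: Mapping | None = None) -> None:
    """TSV with provenance header lines; body is deterministic given the frame."""
    with open(path, "w") as handle:
        for line in provenance_lines(config):
            handle.write(line + "\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_stack(stack, path: str) -> None:
    """Two-channel z-stack as TIFF, axes (channel, z, y, x)."""
    import tifffile

    data = np.stack([stack.nuclear, stack.rna]).astype(np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "CZYX", "voxel_size": list(stack.voxel_size)})


def read_stack(path: str, voxel_size=(0.3, 0.1, 0.1)):
    import tifffile

    from .smfish import ImageStack

    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[0] != 2:
        raise ValueError("expected a (2, z, y, x) two-channel TIFF stack")
    return ImageStack(data[0], data[1], tuple(voxel_size))


def write_workspace(fixture, outdir: str) -> None:
    """Emit a ready-to-run 4C workspace: per-library count TSVs + config.yaml."""
    os.makedirs(os.path.join(outdir, "counts"), exist_ok=True)
    manifest = []
    for lib, table in fixture.counts:
        rel = os.path.join("counts", f"{lib.sample_id}.tsv")
        write_counts(table, os.path.join(outdir, rel))
        manifest.append(
            {
                "sample_id": lib.sample_id,
                "bait": lib.bait,
                "allele": lib.allele,
                "condition": lib.condition,
                "replicate": lib.replicate,
                "counts": rel,
            }
        )
    config = {
        "bait": {"chrom": fixture.bait[0], "pos": int(fixture.bait[1])},
        "cis_window": 1_000_000,
        "regions": {
            name: [chrom, int(start), int(end)]
            for name, (chrom, start, end) in fixture.regions.items()
        },
        "deletions": {
            allele: [[chrom, int(start), int(end)]]
            for allele, (chrom, start, end) in fixture.deletions.items()
        },
        "libraries": manifest,
        "reference_condition": "WT",
        "params": {
            "W": 21,
            "delta": 2.0,
            "rho": 2.0,
            "min_frags": 3,
            "exclusion_frags": 10,
            "flank_frags": 2,
        },
    }
    with open(os.path.join(outdir, "config.yaml"), "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)
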