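"""Demultiplexing and fragment-end assignment of raw 4C reads.

Libraries are identified by an inline barcode/bait-primer prefix (sabre-style
exact matching by default).  After trimming, a read is assigned to a fragend
by exact lookup of its first L bases against the fragend capture-sequence
dictionary built by :func:`loop4c.digest.build_fragends`; capture sequences
shared by several fragends are excluded from the dictionary, and reads
matching them are counted as ambiguous.  This replaces an external aligner
while keeping the fragment-space representation the downstream statistics
operate on; externally produced per-fragend count tables can be imported via
:mod:`loop4c.io` instead.

Allele assignment is per-library (allele separation happens experimentally,
via SNP-specific digestion before inverse PCR), never per-read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibrarySpec:
    """One 4C library: bait x allele x condition x replicate, plus its barcode."""

    sample_id: str
    bait: str
    allele: str
    condition: str
    replicate: int
    prefix: str = ""


@dataclass
class FourCProfile:
    """Per-fragend raw or normalized counts for one library."""

    library: LibrarySpec | None
    fragends: pd.DataFrame
    counts: np.ndarray
    total_reads: int = 0
    ambiguous: int = 0
    unmatched: int = 0

    @property
    def assigned_reads(self) -> int:
        return int(self.counts.sum())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.fragends):
            raise ValueError("counts length must equal number of fragends")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _read_seq(read) -> str:
    """Accept plain strings, (id, seq, qual) tuples, or Bio SeqRecords."""
    if isinstance(read, str):
        return read
    if isinstance(read, tuple):
        return read[1]
    return str(read.seq)


def _trim(read, n: int):
    if isinstance(read, str):
        return read[n:]
    if isinstance(read, tuple):
        rid, seq, qual = read
        return (rid, seq[n:], qual[n:] if qual is not None else None)
    return read[n:]  # SeqRecord slicing keeps id/qualities


def demultiplex(
    reads: Iterable,
    libraries: Sequence[LibrarySpec],
    max_mismatch: int = 0,
) -> tuple[dict[str, list], list]:
    """Split reads by barcode prefix; trim the prefix from assigned reads.

    Returns ``(per_library, unassigned)`` where ``per_library`` maps
    sample_id to its (trimmed) reads.  Conservation holds: every input read
    lands in exactly one output bin.

    Raises a configuration error when two prefixes are within
    ``max_mismatch`` of each other (ambiguous design) or when the
    (bait, allele, condition, replicate) keys are not unique.
    """
    if not libraries:
        raise ValueError("no libraries configured")
    keys = [(l.bait, l.allele, l.condition, l.replicate) for l in libraries]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (bait, allele, condition, replicate) in manifest")
    for lib in libraries:
        if not lib.prefix:
            raise ValueError(f"library {lib.sample_id} has an empty prefix")
    for i, a in enumerate(libraries):
        for b in libraries[i + 1 :]:
            n = min(len(a.prefix), len(b.prefix))
            if _hamming(a.prefix[:n], b.prefix[:n]) <= max_mismatch:
                raise ValueError(
                    f"prefixes {a.prefix!r} and {b.prefix!r} are ambiguous at "
                    f"max_mismatch={max_mismatch}"
                )

    per_library: dict[str, list] = {lib.sample_id: [] for lib in libraries}
    unassigned: list = []
    for read in reads:
        seq = _read_seq(read)
        hit = None
        for lib in libraries:
            p = lib.prefix
            if len(seq) >= len(p) and _hamming(seq[: len(p)], p) <= max_mismatch:
                hit = lib
                break  # prefixes are mutually non-ambiguous, so first hit is unique
        if hit is None:
            unassigned.append(read)
        else:
            per_library[hit.sample_id].append(_trim(read, len(hit.prefix)))
    return per_library, unassigned


def build_capture_index(fragends: pd.DataFrame) -> dict[str, int]:
    """Capture-sequence -> fragend row lookup; colliding captures excluded.

    Collisions (identical capture on several fragends, e.g. repeats at the
    chosen L) are removed at build time so a read can never increment two
    counters; the excluded keys are kept to recognise ambiguous reads.
    """
    index: dict[str, int] = {}
    collided: set[str] = set()
    for row, cap in enumerate(fragends["capture"]):
        if cap in collided:
            continue
        if cap in index:
            del index[cap]
            collided.add(cap)
        else:
            index[cap] = row
    index.update({cap: -1 for cap in collided})
    return index


def assign_reads(
    reads: Iterable,
    fragends: pd.DataFrame,
    library: LibrarySpec | None = None,
) -> FourCProfile:
    """Count reads per fragend by exact lookup of their leading capture bases.

    Each read increments exactly one fragend when its first L bases (which
    begin with the primary restriction site after barcode trimming) match a
    unique capture sequence; reads hitting a colliding capture are counted
    ambiguous, everything else unmatched.  Conservation:
    ``assigned + ambiguous + unmatched == total``.
    """
    if len(fragends) == 0:
        raise ValueError("empty fragend dictionary")
    index = build_capture_index(fragends)
    lengths = sorted({len(c) for c in fragends["capture"]}, reverse=True)
    counts = np.zeros(len(fragends), dtype=np.int64)
    total = ambiguous = unmatched = 0
    for read in reads:
        seq = _read_seq(read)
        total += 1
        row = None
        for L in lengths:
            hit = index.get(seq[:L])
            if hit is not None:
                row = hit
                break
        if row is None:
            unmatched += 1
        elif row < 0:
            ambiguous += 1
        else:
            counts[row] += 1
    return FourCProfile(
        library=library,
        fragends=fragends,
        counts=counts,
        total_reads=total,
        ambiguous=ambiguous,
        unmatched=unmatched,
    )


def filter_cis(
    profile: FourCProfile,
    bait_chrom: str,
    bait_pos: int | None = None,
    window: int | None = None,
) -> FourCProfile:
    """Restrict a profile to the bait chromosome (optionally +/- ``window`` bp).

    4C statistics in this package are intrachromosomal; trans counts are
    dropped and totals updated (dropped reads remain in ``total_reads``).
    """
    keep = profile.fragends["chrom"] == bait_chrom
    if window is not None:
        if bait_pos is None:
            raise ValueError("window filtering requires bait_pos")
        keep &= (profile.fragends["anchor_pos"] - bait_pos).abs() <= window
    keep = keep.to_numpy()
    return FourCProfile(
        library=profile.library,
        fragends=profile.fragends.loc[keep].reset_index(drop=True),
        counts=profile.counts[keep],
        total_reads=profile.total_reads,
        ambiguous=profile.ambiguous,
        unmatched=profile.unmatched,
    )
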