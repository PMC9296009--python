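"""Restriction-fragment and fragment-end maps for 4C-seq.

4C-seq measures contact frequencies of one bait locus by counting ligation
junctions at restriction-fragment ends.  The analysis therefore lives in
*fragment space*: a genome digested in silico with the primary enzyme (e.g.
DpnII) yields an ordered tiling of fragments per chromosome, and each
fragment contributes two "fragends" -- the stretches adjacent to the primary
cut sites where a 4C read can start.  A secondary enzyme (e.g. Csp6I) is
needed for circularisation; fragments lacking a secondary site are "blind"
and cannot produce informative circles.

Engineered alleles (deletions, insertions) are handled by editing the
sequence, re-digesting, and keeping a coordinate-lift table so edited-allele
fragends can be reported in reference coordinates.

Coordinates are 0-based half-open throughout (BED conventions on output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site plus cut offset within the site.

    ``cut_offset`` is the number of bases from the start of the site to the
    cleavage position on the top strand: DpnII cuts ^GATC (offset 0), NlaIII
    CATG^ (offset 4), Csp6I G^TAC (offset 1).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.site:
            raise ValueError("enzyme site must be non-empty")
        bad = set(self.site) - set("ACGT")
        if bad:
            raise ValueError(f"enzyme site must be uppercase ACGT, got {bad!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(
                f"cut_offset must lie within the site: 0 <= {self.cut_offset} <= {len(self.site)}"
            )


DPNII = EnzymeSpec("DpnII", "GATC", 0)
NLAIII = EnzymeSpec("NlaIII", "CATG", 4)
CSP6I = EnzymeSpec("Csp6I", "GTAC", 1)

ENZYMES = {e.name: e for e in (DPNII, NLAIII, CSP6I)}


def cut_positions(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """All cleavage positions of ``enzyme`` in ``seq``, strictly inside (0, len).

    Overlapping site occurrences are all honoured; N (or any non-ACGT
    character) never matches, which is the conservative choice for assembly
    gaps.  Cuts coinciding with the sequence boundaries are dropped since
    they produce zero-length fragments.
    """
    positions: list[int] = []
    i = seq.find(enzyme.site)
    while i != -1:
        pos = i + enzyme.cut_offset
        if 0 < pos < len(seq):
            positions.append(pos)
        i = seq.find(enzyme.site, i + 1)
    return sorted(set(positions))


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    ``fragments`` has columns chrom, start, end, index (ordinal along its
    chromosome); fragments are disjoint, sorted, and tile [0, chrom_length).
    """

    fragments: pd.DataFrame
    chrom_lengths: dict[str, int]
    enzyme: EnzymeSpec

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.fragments[self.fragments["chrom"] == chrom].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fragments)


def digest_genome(genome: Mapping[str, str], enzyme: EnzymeSpec) -> FragmentMap:
    """In-silico digest: fragment boundaries at every cut site of ``enzyme``.

    Raises on an empty genome.  Adjacent/duplicate cut positions (possible
    when sites overlap) would give zero-length fragments; these are dropped
    silently with a logged count.
    """
    if not genome:
        raise ValueError("empty genome: no chromosomes to digest")
    rows = []
    n_dropped = 0
    for chrom, seq in genome.items():
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r} has empty sequence")
        cuts = cut_positions(seq, enzyme)
        bounds = [0, *cuts, len(seq)]
        idx = 0
        for start, end in zip(bounds[:-1], bounds[1:]):
            if end <= start:
                n_dropped += 1
                continue
            rows.append((chrom, start, end, idx))
            idx += 1
    if n_dropped:
        log.info("dropped %d zero-length fragments", n_dropped)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])
    return FragmentMap(frame, {c: len(s) for c, s in genome.items()}, enzyme)


def build_fragends(
    fragmap: FragmentMap,
    genome: Mapping[str, str],
    secondary: EnzymeSpec,
    L: int = 36,
) -> pd.DataFrame:
    """Two fragends per fragment (5' and 3' side of the primary cut).

    ``capture`` is the first ``L`` bases read inward from the primary site
    (for the 3' side, on the reverse strand, i.e. the sequence a 4C read
    starting at that end would produce).  ``blind`` marks fragments with no
    secondary-enzyme site, which cannot circularise informatively.

    Returns a DataFrame with columns: fragend_id, chrom, frag_index,
    frag_start, frag_end, side, anchor_pos, capture, blind -- sorted by
    (chrom, anchor_pos).
    """
    if L < 1:
        raise ValueError(f"capture length L must be >= 1, got {L}")
    rows = []
    for chrom, seq in genome.items():
        frags = fragmap.for_chrom(chrom)
        for start, end, idx in zip(frags["start"], frags["end"], frags["index"]):
            fragseq = seq[start:end]
            blind = secondary.site not in fragseq
            cap5 = fragseq[:L]
            cap3 = revcomp(fragseq[-L:] if end - start >= L else fragseq)
            rows.append(
                (f"{chrom}:{idx}:5p", chrom, idx, start, end, "5p", start, cap5, blind)
            )
            rows.append(
                (f"{chrom}:{idx}:3p", chrom, idx, start, end, "3p", end, cap3, blind)
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "fragend_id",
            "chrom",
            "frag_index",
            "frag_start",
            "frag_end",
            "side",
            "anchor_pos",
            "capture",
            "blind",
        ],
    )
    return frame.sort_values(["chrom", "anchor_pos", "side"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"deletion needs start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class Insertion:
    """Foreign sequence inserted at ``pos``; lifts to a contig named ``name``."""

    chrom: str
    pos: int
    seq: str
    name: str


@dataclass
class AlleleMap:
    """An engineered allele: edited sequence, re-digested map, coordinate lift.

    ``segments`` maps, per edited chromosome, half-open edited-axis intervals
    to their source: ``(edited_start, edited_end, source_name, source_start)``
    where ``source_name`` is the reference chromosome for retained sequence or
    the insertion's contig name for inserted sequence.  Deleted reference
    sequence has no image on the edited axis.
    """

    allele: str
    edits: tuple
    genome: dict[str, str]
    fragmap: FragmentMap
    segments: dict[str, list[tuple[int, int, str, int]]]

    def lift_to_reference(self, chrom: str, pos: int) -> tuple[str, int]:
        """Map an edited-axis coordinate to (source_name, source_pos)."""
        for e_start, e_end, source, s_start in self.segments[chrom]:
            if e_start <= pos < e_end or (pos == e_end and e_end == self.segments[chrom][-1][1]):
                return source, s_start + (pos - e_start)
        raise ValueError(f"position {chrom}:{pos} outside edited chromosome")

    def ref_to_edited(self, chrom: str, pos: int) -> int | None:
        """Map a reference coordinate to the edited axis (None if deleted)."""
        for e_start, e_end, source, s_start in self.segments.get(chrom, ()):
            if source == chrom and s_start <= pos < s_start + (e_end - e_start):
                return e_start + (pos - s_start)
        return None


def apply_allele_edits(
    fragmap: FragmentMap,
    genome: Mapping[str, str],
    edits: Sequence[Deletion | Insertion],
    allele: str = "edited",
) -> AlleleMap:
    """Apply deletions/insertions, re-digest, and build the coordinate lift.

    Edits must be in-bounds and mutually disjoint (an insertion is treated as
    a point).  After a deletion of D bp the edited chromosome is exactly D bp
    shorter; an insertion of I bp lengthens it by I and its span lifts to a
    named contig, making inserted sequence (e.g. a foreign 4C bait fragment)
    addressable.
    """
    by_chrom: dict[str, list] = {}
    for edit in edits:
        if edit.chrom not in genome:
            raise ValueError(f"edit on unknown chromosome {edit.chrom!r}")
        clen = len(genome[edit.chrom])
        if isinstance(edit, Deletion):
            if not (0 <= edit.start and edit.end <= clen):
                raise ValueError(f"deletion {edit} outside chromosome bounds")
        else:
            if not (0 <= edit.pos <= clen):
                raise ValueError(f"insertion {edit.name} outside chromosome bounds")
        by_chrom.setdefault(edit.chrom, []).append(edit)

    def _span(e):
        return (e.start, e.end) if isinstance(e, Deletion) else (e.pos, e.pos)

    edited_genome: dict[str, str] = {}
    segments: dict[str, list[tuple[int, int, str, int]]] = {}
    for chrom, seq in genome.items():
        chrom_edits = sorted(by_chrom.get(chrom, []), key=_span)
        for a, b in zip(chrom_edits[:-1], chrom_edits[1:]):
            if _span(a)[1] > _span(b)[0]:
                raise ValueError(f"overlapping edits on {chrom}: {a} / {b}")
        pieces: list[str] = []
        segs: list[tuple[int, int, str, int]] = []
        cursor = 0  # reference coordinate
        offset = 0  # edited coordinate
        for edit in chrom_edits:
            e_start, e_end = _span(edit)
            if e_start > cursor:
                pieces.append(seq[cursor:e_start])
                segs.append((offset, offset + (e_start - cursor), chrom, cursor))
                offset += e_start - cursor
            if isinstance(edit, Deletion):
                cursor = e_end
            else:
                pieces.append(edit.seq)
                segs.append((offset, offset + len(edit.seq), edit.name, 0))
                offset += len(edit.seq)
                cursor = e_start
        if cursor < len(seq):
            pieces.append(seq[cursor:])
            segs.append((offset, offset + (len(seq) - cursor), chrom, cursor))
        edited_genome[chrom] = "".join(pieces)
        segments[chrom] = segs

    edited_map = digest_genome(edited_genome, fragmap.enzyme)
    return AlleleMap(allele, tuple(edits), edited_genome, edited_map, segments)
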