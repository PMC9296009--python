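"""Profile normalisation, deletion masks and deletion-aware running means.

Engineered deletions leave a scar in the 4C profile: the deleted fragends no
longer exist on that allele and the fragments flanking the scar are fused or
shortened, inflating or deflating their signal.  For display and for any
window statistic, the signal is therefore *omitted* from the deleted region
and a configurable number of flanking fragends when computing running means,
rather than set to zero (a zero would drag window averages down and fake a
depletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def normalize_rpm(counts: np.ndarray) -> np.ndarray:
    """Scale counts to reads-per-million (sums to 1e6 when input is nonzero)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        log.warning("all-zero profile: rpm normalisation returns zeros")
        return np.zeros_like(counts)
    return counts * (1e6 / total)


@dataclass
class DeletionMask:
    """Boolean mask over fragend rows (True = excluded), with provenance."""

    mask: np.ndarray
    deletion: tuple[str, int, int] | None = None
    flank_frags: int = 0

    def __or__(self, other: "DeletionMask") -> "DeletionMask":
        return DeletionMask(self.mask | other.mask, None, max(self.flank_frags, other.flank_frags))


def build_deletion_mask(
    fragends: pd.DataFrame,
    deletion: tuple[str, int, int],
    flank_frags: int = 2,
) -> DeletionMask:
    """Mask fragends inside a deletion plus ``flank_frags`` fragends per side.

    A fragend is "inside" when its fragment overlaps the half-open deletion
    interval (so a deletion falling strictly within one fragment still masks
    that fragment's two fragends).  Flank expansion never crosses a
    chromosome boundary.
    """
    chrom, start, end = deletion
    if not start < end:
        raise ValueError("deletion interval needs start < end")
    inside = (
        (fragends["chrom"] == chrom)
        & (fragends["frag_start"] < end)
        & (fragends["frag_end"] > start)
    ).to_numpy()
    mask = inside.copy()
    if flank_frags > 0 and inside.any():
        same_chrom = (fragends["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(inside)
        lo = max(idx.min() - flank_frags, 0)
        hi = min(idx.max() + flank_frags, len(mask) - 1)
        mask[lo : hi + 1] = True
        mask &= same_chrom | inside
    return DeletionMask(mask, deletion, flank_frags)


@dataclass
class SmoothedTrack:
    """Per-fragend running-mean values; NaN where masked/undefined."""

    values: np.ndarray
    window: int


def running_mean(
    values: np.ndarray,
    W: int,
    mask: DeletionMask | np.ndarray | None = None,
) -> SmoothedTrack:
    """Deletion-aware centered running mean with window truncation at the ends.

    The value at position i is the mean of the *unmasked* values among the W
    window positions centered at i; the window is truncated at the profile
    ends.  Output is NaN at masked positions (no-coverage, not zero) and
    wherever the window holds no unmasked value.  W must be odd (>= 1);
    W = 1 is the identity on unmasked positions.
    """
    if W < 1 or W % 2 == 0:
        raise ValueError(f"window W must be odd and >= 1, got {W}")
    v = np.asarray(values, dtype=float)
    m = mask.mask if isinstance(mask, DeletionMask) else mask
    valid = np.isfinite(v)
    if m is not None:
        m = np.asarray(m, dtype=bool)
        if m.shape != v.shape:
            raise ValueError("mask shape must match values")
        valid &= ~m
    kernel = np.ones(W)
    num = np.convolve(np.where(valid, v, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    if m is not None:
        out[m] = np.nan
    return SmoothedTrack(out, W)


def plot_profiles(
    fragends: pd.DataFrame,
    tracks: dict[str, np.ndarray],
    path: str,
    bait_pos: int | None = None,
    title: str = "4C profile",
) -> None:
    """Overlay smoothed condition tracks (position vs signal) into an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    x = fragends["anchor_pos"].to_numpy() / 1e6
    for label, values in tracks.items():
        ax.plot(x, values, lw=0.9, label=label)
    if bait_pos is not None:
        ax.axvline(bait_pos / 1e6, ls="--", c="k", lw=0.8)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("normalized 4C signal")
    ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
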