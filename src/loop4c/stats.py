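"""Interaction-score statistics: quantile normalization, region scores,
condition comparisons and TAD leakiness.

The headline 4C statistic is the *interaction score*: for each library the
quantile-normalized counts within 1 Mb of the bait are summed over a
predefined region (e.g. the minimal bait-interacting region spanning Sox2),
per-replicate scores are averaged per condition, and conditions are compared
by two-tailed t-tests with the effect reported as a percent change of the
condition mean.  TAD "leakiness" applies the same machinery to a ~325-kb
region tiling the neighbouring domain, reported relative to the wild-type
mean so boundary weakening reads as a score above 1.

Quantile normalization is computed jointly over all libraries sharing a
bait (all conditions and replicates), and deletion-masked fragends are
removed from every column beforehand so ranks stay comparable between
wild-type and deletion alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

# mm10 coordinates used by the source study for the Sox2 locus.
SOX2_REGION = ("chr3", 34_644_922, 34_664_967)
SCR_REGION = ("chr3", 34_749_652, 34_760_919)
DOWNSTREAM_TAD = ("chr3", 34_800_000, 35_105_000)
UPSTREAM_TAD = ("chr3", 34_315_000, 34_640_000)


@dataclass
class LocusConfig:
    """Bait positions and named scored regions, all within the cis window."""

    baits: dict[str, tuple[str, int]]
    regions: dict[str, tuple[str, int, int]]
    cis_window: int = 1_000_000

    def validate(self) -> None:
        for name, (chrom, start, end) in self.regions.items():
            if not start < end:
                raise ValueError(f"region {name} needs start < end")
            if not any(
                bc == chrom and min(abs(start - bp), abs(end - bp)) <= self.cis_window
                for bc, bp in self.baits.values()
            ):
                raise ValueError(f"region {name} lies outside every bait's cis window")


def sox2_locus_config() -> LocusConfig:
    """The mm10 Sox2-locus configuration (near-SCR bait and scored regions)."""
    return LocusConfig(
        baits={"near_scr": ("chr3", 34_760_920)},
        regions={
            "sox2_region": SOX2_REGION,
            "scr_region": SCR_REGION,
            "downstream_tad": DOWNSTREAM_TAD,
            "upstream_tad": UPSTREAM_TAD,
        },
    )


def quantile_normalize(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference distribution.

    After normalization each column's sorted values equal the across-column
    mean of sorted values; tied entries within a column receive the mean of
    the reference values over their rank span.  Idempotent, and equalises
    column sums.  A single column is returned unchanged with a warning.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D fragends x libraries matrix")
    n, m = X.shape
    if m < 2:
        log.warning("single library: quantile normalization is the identity")
        out = X.copy()
    else:
        ref = np.sort(X, axis=0).mean(axis=1)
        out = np.empty_like(X)
        for j in range(m):
            col = X[:, j]
            sorter = np.argsort(col, kind="mergesort")
            assigned = ref.copy()
            sorted_col = col[sorter]
            # average the reference over each tied span
            boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
            for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, n]):
                if hi - lo > 1:
                    assigned[lo:hi] = ref[lo:hi].mean()
            out[sorter, j] = assigned
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def interaction_score(
    values: np.ndarray,
    fragends: pd.DataFrame,
    region: tuple[str, int, int],
    mask: np.ndarray | None = None,
) -> float:
    """Sum of (normalized) signal over fragends whose anchor lies in ``region``.

    Additive over disjoint regions; deletion-masked fragends never count.
    """
    chrom, start, end = region
    v = np.asarray(values, dtype=float)
    sel = (
        (fragends["chrom"] == chrom)
        & (fragends["anchor_pos"] >= start)
        & (fragends["anchor_pos"] < end)
    ).to_numpy()
    if mask is not None:
        sel &= ~np.asarray(mask, dtype=bool)
    return float(np.nansum(v[sel]))


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    mean_b: float
    percent_change: float  # 100 * (mean_b - mean_a) / mean_a
    t: float
    p: float
    n_a: int
    n_b: int


def compare_conditions(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test on per-replicate scores (Welch by default).

    ``percent_change`` follows the study's reporting style: the change of
    condition B's mean relative to condition A's mean, in percent.  Refuses
    to compare with fewer than 2 replicates per condition.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition for a t-test")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # zero variance in both groups
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else np.nan
    return ComparisonResult(mean_a, mean_b, pct, float(t), float(p), len(a), len(b))


def score_table(
    normalized: pd.DataFrame,
    fragends: pd.DataFrame,
    libraries: list,
    regions: dict[str, tuple[str, int, int]],
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per-replicate region scores: one row per (library, region)."""
    rows = []
    for lib in libraries:
        values = normalized[lib.sample_id].to_numpy()
        for region_name, region in regions.items():
            rows.append(
                {
                    "sample_id": lib.sample_id,
                    "condition": lib.condition,
                    "allele": lib.allele,
                    "replicate": lib.replicate,
                    "region": region_name,
                    "score": interaction_score(values, fragends, region, mask),
                }
            )
    return pd.DataFrame(rows)


def compare_score_table(
    scores: pd.DataFrame,
    reference_condition: str,
    regions: list[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Compare every condition's region scores against a reference condition."""
    regions = regions or sorted(scores["region"].unique())
    out = []
    for region in regions:
        sub = scores[scores["region"] == region]
        ref = sub.loc[sub["condition"] == reference_condition, "score"].to_numpy()
        for condition in sub["condition"].unique():
            if condition == reference_condition:
                continue
            other = sub.loc[sub["condition"] == condition, "score"].to_numpy()
            res = compare_conditions(ref, other, equal_var=equal_var)
            out.append(
                {
                    "region": region,
                    "condition_a": reference_condition,
                    "condition_b": condition,
                    "mean_a": res.mean_a,
                    "mean_b": res.mean_b,
                    "percent_change": res.percent_change,
                    "t": res.t,
                    "p": res.p,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                }
            )
    return pd.DataFrame(out)


def tad_interaction_score(
    scores: pd.DataFrame,
    wt_condition: str,
    tad_regions: tuple[str, str] = ("upstream_tad", "downstream_tad"),
) -> pd.DataFrame:
    """Per-replicate TAD scores rescaled so the wild-type mean is 1 per region.

    Leakiness of a TAD border then reads directly as a scaled score above 1
    on the corresponding side; the raw sums are kept alongside.  The two TAD
    regions are scaled independently, so a change planted on one side cannot
    move the other side's scaled mean.
    """
    sub = scores[scores["region"].isin(tad_regions)].copy()
    for region in tad_regions:
        wt = sub.loc[
            (sub["region"] == region) & (sub["condition"] == wt_condition), "score"
        ]
        if wt.empty:
            raise ValueError(f"no {wt_condition} replicates for region {region}")
        denom = wt.mean()
        sel = sub["region"] == region
        sub.loc[sel, "scaled_score"] = sub.loc[sel, "score"] / denom
    return sub
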