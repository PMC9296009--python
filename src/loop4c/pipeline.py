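"""Workspace-level orchestration of the 4C scoring pipeline.

A workspace is a directory with per-library fragend count tables and a
``config.yaml`` naming the bait, the scored regions, per-allele deletions,
the library manifest and the frozen algorithm parameters.  ``run_fourc``
builds the cross-library count matrix on the reference fragend index within
the cis window, masks deletion scars, quantile-normalizes, calls
interactions per reference-condition replicate, intersects them into
consensus regions, computes region interaction scores and condition
comparisons, and writes everything with provenance headers.  The run is
fully deterministic given the workspace contents.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as l4c_io
from .calling import call_interactions, consensus_regions, fit_background
from .profile import DeletionMask, build_deletion_mask, running_mean
from .reads import LibrarySpec
from .stats import compare_score_table, quantile_normalize, score_table, tad_interaction_score

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "W": 21,
    "delta": 2.0,
    "rho": 2.0,
    "min_frags": 3,
    "exclusion_frags": 10,
    "flank_frags": 2,
}


@dataclass
class RunConfig:
    workspace: str
    bait: tuple[str, int]
    cis_window: int
    regions: dict[str, tuple[str, int, int]]
    deletions: dict[str, list[tuple[str, int, int]]]
    libraries: list[LibrarySpec]
    count_paths: dict[str, str]
    reference_condition: str
    params: dict
    raw: dict = field(default_factory=dict)


def load_config(workspace: str) -> RunConfig:
    """Parse and validate a workspace config; errors name the missing key/path."""
    path = os.path.join(workspace, "config.yaml")
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing workspace config: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    for key in ("bait", "regions", "libraries", "reference_condition"):
        if key not in raw:
            raise KeyError(f"config.yaml is missing required key {key!r}")
    libraries, count_paths = [], {}
    for entry in raw["libraries"]:
        lib = LibrarySpec(
            sample_id=entry["sample_id"],
            bait=entry.get("bait", "bait"),
            allele=entry["allele"],
            condition=entry["condition"],
            replicate=int(entry["replicate"]),
            prefix=entry.get("prefix", ""),
        )
        counts_path = os.path.join(workspace, entry["counts"])
        if not os.path.exists(counts_path):
            raise FileNotFoundError(
                f"count table for {lib.sample_id} not found: {counts_path}"
            )
        libraries.append(lib)
        count_paths[lib.sample_id] = counts_path
    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params", {}))
    return RunConfig(
        workspace=workspace,
        bait=(raw["bait"]["chrom"], int(raw["bait"]["pos"])),
        cis_window=int(raw.get("cis_window", 1_000_000)),
        regions={k: tuple(v) for k, v in raw["regions"].items()},
        deletions={
            allele: [tuple(d) for d in dels]
            for allele, dels in raw.get("deletions", {}).items()
        },
        libraries=libraries,
        count_paths=count_paths,
        reference_condition=raw["reference_condition"],
        params=params,
        raw=raw,
    )


@dataclass
class PipelineResult:
    fragends: pd.DataFrame  # reference fragend frame (cis window)
    matrix: pd.DataFrame  # quantile-normalized, NaN at masked rows
    mask: np.ndarray
    scores: pd.DataFrame
    comparisons: pd.DataFrame
    tad_scores: pd.DataFrame | None
    replicate_calls: dict[str, list]
    consensus: list[tuple[int, int]]


def build_count_matrix(
    config: RunConfig,
    tables: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align libraries on the reference fragend index within the cis window.

    The reference index comes from a reference-condition (unedited) library;
    edited-allele fragends join via their reference-lifted anchors, so scar
    fragends that have no reference image simply do not join (they are
    masked anyway).  Returns (reference fragends, raw count matrix).
    """
    bait_chrom, bait_pos = config.bait
    ref_lib = next(
        lib for lib in config.libraries if lib.condition == config.reference_condition
    )
    ref = tables[ref_lib.sample_id]
    if "ref_chrom" not in ref.columns:
        ref = ref.assign(ref_chrom=ref["chrom"], ref_anchor=ref["anchor_pos"])
    in_cis = (ref["ref_chrom"] == bait_chrom) & (
        (ref["ref_anchor"] - bait_pos).abs() <= config.cis_window
    )
    fragends = (
        ref.loc[in_cis, ["fragend_id", "chrom", "frag_start", "frag_end", "side", "anchor_pos", "ref_chrom", "ref_anchor"]]
        .sort_values(["ref_anchor", "side"], kind="mergesort")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(fragends[["ref_chrom", "ref_anchor", "side"]])
    matrix = pd.DataFrame(index=range(len(fragends)))
    for lib in config.libraries:
        table = tables[lib.sample_id]
        if "ref_chrom" not in table.columns:
            table = table.assign(ref_chrom=table["chrom"], ref_anchor=table["anchor_pos"])
        series = pd.Series(
            table["count"].to_numpy(),
            index=pd.MultiIndex.from_frame(table[["ref_chrom", "ref_anchor", "side"]]),
        )
        series = series[~series.index.duplicated()]
        matrix[lib.sample_id] = series.reindex(key).fillna(0).to_numpy()
    return fragends, matrix


def build_masks(config: RunConfig, fragends: pd.DataFrame) -> np.ndarray:
    """Union of deletion masks (deleted fragends + flanks) over all alleles."""
    mask = np.zeros(len(fragends), dtype=bool)
    for allele, deletions in config.deletions.items():
        for deletion in deletions:
            dm = build_deletion_mask(
                fragends.assign(chrom=fragends["ref_chrom"], anchor_pos=fragends["ref_anchor"]),
                tuple(deletion),
                flank_frags=config.params["flank_frags"],
            )
            mask |= dm.mask
    return mask


def run_fourc(workspace: str, outdir: str | None = None) -> PipelineResult:
    """Execute the full 4C scoring pipeline on a workspace directory."""
    config = load_config(workspace)
    tables = {
        sample: l4c_io.read_counts(path) for sample, path in config.count_paths.items()
    }
    fragends, raw_matrix = build_count_matrix(config, tables)
    mask = build_masks(config, fragends)

    unmasked = ~mask
    norm = pd.DataFrame(
        np.nan, index=raw_matrix.index, columns=raw_matrix.columns, dtype=float
    )
    norm.loc[unmasked] = quantile_normalize(raw_matrix.loc[unmasked]).to_numpy()

    region_frame = fragends.assign(
        chrom=fragends["ref_chrom"], anchor_pos=fragends["ref_anchor"]
    )
    scores = score_table(norm, region_frame, config.libraries, config.regions, mask)
    comparisons = compare_score_table(scores, config.reference_condition)
    tad_regions = [r for r in ("upstream_tad", "downstream_tad") if r in config.regions]
    tad_scores = (
        tad_interaction_score(scores, config.reference_condition, tuple(tad_regions))
        if len(tad_regions) == 2
        else None
    )

    p = config.params
    bait_pos = config.bait[1]
    anchors = region_frame["anchor_pos"].to_numpy()
    replicate_calls: dict[str, list] = {}
    for lib in config.libraries:
        if lib.condition != config.reference_condition:
            continue
        values = norm[lib.sample_id].to_numpy()
        fit = fit_background(values, anchors, bait_pos, mask, p["exclusion_frags"])
        replicate_calls[lib.sample_id] = call_interactions(
            values,
            fit,
            region_frame,
            W=p["W"],
            delta=p["delta"],
            rho=p["rho"],
            min_frags=p["min_frags"],
            mask=mask,
        )
    consensus = consensus_regions(list(replicate_calls.values()))

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        l4c_io.write_table(scores, os.path.join(outdir, "scores.tsv"), config.raw)
        l4c_io.write_table(comparisons, os.path.join(outdir, "comparisons.tsv"), config.raw)
        if tad_scores is not None:
            l4c_io.write_table(tad_scores, os.path.join(outdir, "tad_scores.tsv"), config.raw)
        for sample, calls in replicate_calls.items():
            l4c_io.write_bed(
                [(c.chrom, c.start, c.end, sample) for c in calls],
                os.path.join(outdir, f"calls_{sample}.bed"),
            )
        l4c_io.write_bed(
            [(config.bait[0], s, e, "consensus") for s, e in consensus],
            os.path.join(outdir, "consensus.bed"),
        )
        tracks = os.path.join(outdir, "tracks")
        os.makedirs(tracks, exist_ok=True)
        for lib in config.libraries:
            smoothed = running_mean(norm[lib.sample_id].to_numpy(), p["W"], mask)
            l4c_io.write_bedgraph(
                region_frame, smoothed.values, os.path.join(tracks, f"{lib.sample_id}.bedgraph")
            )
    return PipelineResult(
        fragends=fragends,
        matrix=norm,
        mask=mask,
        scores=scores,
        comparisons=comparisons,
        tad_scores=tad_scores,
        replicate_calls=replicate_calls,
        consensus=consensus,
    )


def run_smfish(
    stacks: dict[str, list],
    sigma_psf=(1.2, 1.3, 1.3),
    k_mad: float = 5.0,
    ts_threshold: float = 2.5,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame | None]:
    """Quantify smFISH stacks grouped by sample; compare when two samples given.

    ``stacks`` maps sample name to a list of ImageStack fields of view;
    replicate fields are pooled per sample before testing.  Returns the
    per-sample cell tables and (for exactly two samples) the comparison row.
    """
    from .smfish import classify_cells, compare_samples, detect_spots, rna_equivalents, segment

    cell_tables: dict[str, pd.DataFrame] = {}
    for sample, fields in stacks.items():
        per_field = []
        for i, stack in enumerate(fields):
            cells, nuclei = segment(stack)
            spots = detect_spots(stack, cells, nuclei, sigma_psf=sigma_psf, k_mad=k_mad)
            if spots.empty:
                continue
            spots = rna_equivalents(spots)
            table = classify_cells(spots, ts_threshold=ts_threshold)
            table["field"] = i
            per_field.append(table)
        cell_tables[sample] = (
            pd.concat(per_field, ignore_index=True) if per_field else pd.DataFrame()
        )
    comparison = None
    if len(cell_tables) == 2:
        (name_a, a), (name_b, b) = cell_tables.items()
        res = compare_samples(a, b)
        comparison = pd.DataFrame(
            [
                {
                    "sample_a": name_a,
                    "sample_b": name_b,
                    "n_cells_a": len(a),
                    "n_cells_b": len(b),
                    "wilcoxon_p": res.wilcoxon_p,
                    "chi2": res.chi2,
                    "chi2_p": res.chi2_p,
                }
            ]
        )
    return cell_tables, comparison
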