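"""Seeded generators for 4C libraries and smFISH stacks with known truth.

The 4C generator works natively in fragment space: a random toy chromosome
is digested with the primary enzyme, expected signal at each fragend follows
a power-law distance decay lambda(d) = A * (d + d0)^-alpha from the bait,
planted interaction peaks multiply the decay over plateau footprints, and
counts are drawn negative-binomially (mean mu, variance mu + mu^2/phi) at a
configured sequencing depth.  Engineered alleles re-digest an edited
chromosome, so sequence downstream of a deletion genuinely becomes
bait-proximal -- reproducing the contiguity artifact seen next to deletion
scars in real profiles.  Per-allele peak attenuation scales the *total*
expected signal over the peak footprint, so an attenuation factor f plants a
ground-truth interaction-score change of 100*(f-1) percent over that region.

The smFISH generator places non-overlapping cells with nuclei, scatters
single-RNA spots (intensity I1 with lognormal spread) through the cytoplasm,
renders brighter transcription-site foci inside nuclei with a Gamma nascent
load, and applies Poisson shot noise plus Gaussian read noise.

Everything is bit-reproducible for a given seed; distinct libraries/fields
use child seeds spawned from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import (
    CSP6I,
    DPNII,
    AlleleMap,
    Deletion,
    EnzymeSpec,
    FragmentMap,
    apply_allele_edits,
    build_fragends,
    digest_genome,
)
from .reads import LibrarySpec

log = logging.getLogger(__name__)


def random_genome(length: int, seed: int, chrom: str = "chrS") -> dict[str, str]:
    """Uniform-random ACGT toy chromosome (restriction sites every ~256 bp)."""
    rng = np.random.default_rng(seed)
    bases = rng.integers(0, 4, size=length)
    return {chrom: bases.astype("u1").tobytes().translate(bytes.maketrans(b"\0\1\2\3", b"ACGT")).decode()}


@dataclass(frozen=True)
class Peak:
    """A planted interaction: plateau footprint [center - width/2, center + width/2).

    ``height`` is the fold-enrichment added over the local background
    (signal inside = background * (1 + height)); ``attenuation`` maps allele
    labels to a factor f in (0, 1] applied to the total signal over the
    footprint on that allele.
    """

    center: int
    width: int
    height: float
    attenuation: dict[str, float] = field(default_factory=dict)

    @property
    def footprint(self) -> tuple[int, int]:
        return self.center - self.width // 2, self.center + self.width // 2


@dataclass
class FourCSimSpec:
    """Study-condition parameters for the 4C generator.

    Defaults: alpha = 1.0, d0 = 2 kb, depth = 1e5 cis reads per library,
    phi = 10, 2.4-Mb toy chromosome with the bait at its middle -- chosen so
    simulated profiles resemble published 4C decay curves.  ``alleles`` maps
    allele labels to edit tuples ('wt' must map to no edits);
    ``region_factors`` plants per-allele multiplicative changes over
    reference intervals (e.g. TAD-boundary leakiness).
    """

    chrom: str = "chrS"
    genome_length: int = 2_400_000
    bait_pos: int = 1_200_000
    alpha: float = 1.0
    d0: float = 2_000.0
    depth: float = 100_000.0
    phi: float = 10.0
    peaks: tuple[Peak, ...] = ()
    alleles: dict[str, tuple] = field(default_factory=lambda: {"wt": ()})
    region_factors: dict[str, tuple[tuple[int, int, float], ...]] = field(default_factory=dict)
    primary: EnzymeSpec = DPNII
    secondary: EnzymeSpec = CSP6I
    capture_length: int = 36
    genome_seed: int = 2003

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.d0 <= 0 or self.depth <= 0 or self.phi <= 0:
            raise ValueError("alpha, d0, depth and phi must be positive")
        for peak in self.peaks:
            for allele, f in peak.attenuation.items():
                if not 0 < f <= 1:
                    raise ValueError(f"attenuation for {allele} must be in (0, 1], got {f}")


@dataclass
class SimulatedLocus:
    """Deterministic part of a 4C simulation: maps, fragends and mean vectors."""

    spec: FourCSimSpec
    genome: dict[str, str]
    fragmap: FragmentMap
    ref_fragends: pd.DataFrame
    allele_maps: dict[str, AlleleMap]
    allele_fragends: dict[str, pd.DataFrame]  # with ref_chrom / ref_anchor columns
    allele_means: dict[str, np.ndarray]


def _lift_fragends(fragends: pd.DataFrame, amap: AlleleMap, chrom: str) -> pd.DataFrame:
    out = fragends.copy()
    ref_chroms, ref_anchors = [], []
    for pos in out["anchor_pos"]:
        src, ref_pos = amap.lift_to_reference(chrom, int(pos))
        ref_chroms.append(src)
        ref_anchors.append(ref_pos)
    out["ref_chrom"] = ref_chroms
    out["ref_anchor"] = ref_anchors
    return out


def build_locus(spec: FourCSimSpec) -> SimulatedLocus:
    """Digest the toy genome and precompute per-allele expected-count vectors."""
    genome = random_genome(spec.genome_length, spec.genome_seed, spec.chrom)
    fragmap = digest_genome(genome, spec.primary)
    ref_fragends = build_fragends(fragmap, genome, spec.secondary, spec.capture_length)

    allele_maps: dict[str, AlleleMap] = {}
    allele_fragends: dict[str, pd.DataFrame] = {}
    allele_means: dict[str, np.ndarray] = {}
    for allele, edits in spec.alleles.items():
        amap = apply_allele_edits(fragmap, genome, edits, allele)
        fe = build_fragends(amap.fragmap, amap.genome, spec.secondary, spec.capture_length)
        fe = _lift_fragends(fe, amap, spec.chrom)
        bait_edited = amap.ref_to_edited(spec.chrom, spec.bait_pos)
        if bait_edited is None:
            raise ValueError(f"bait position deleted on allele {allele}")
        d = np.abs(fe["anchor_pos"].to_numpy() - bait_edited).astype(float)
        decay = (d + spec.d0) ** (-spec.alpha)
        # depth scale is set on the decay alone, so planted peaks, attenuations
        # and region factors change the signal where planted and nowhere else
        # (library totals then vary by the planted mass, as real depths do)
        scale = spec.depth / decay.sum()
        u = decay.copy()
        ref_anchor = fe["ref_anchor"].to_numpy()
        on_ref = (fe["ref_chrom"] == spec.chrom).to_numpy()
        for peak in spec.peaks:
            lo, hi = peak.footprint
            inside = on_ref & (ref_anchor >= lo) & (ref_anchor < hi)
            u[inside] *= (1.0 + peak.height) * peak.attenuation.get(allele, 1.0)
        for lo, hi, factor in spec.region_factors.get(allele, ()):
            inside = on_ref & (ref_anchor >= lo) & (ref_anchor < hi)
            u[inside] *= factor
        allele_maps[allele] = amap
        allele_fragends[allele] = fe
        allele_means[allele] = scale * u
    return SimulatedLocus(
        spec, genome, fragmap, ref_fragends, allele_maps, allele_fragends, allele_means
    )


def negative_binomial(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = mu + mu^2/phi)."""
    mean = np.asarray(mean, dtype=float)
    p = phi / (phi + mean)
    return rng.negative_binomial(phi, p)


def simulate_counts(
    locus: SimulatedLocus,
    libraries: Sequence[LibrarySpec],
    seed: int,
) -> list[tuple[LibrarySpec, pd.DataFrame]]:
    """Draw one NB count vector per library on its allele's fragend map.

    Returns (library, table) pairs where the table is the allele fragend
    frame plus ``count`` and ``mean`` (ground-truth expectation) columns.
    Library i uses the i-th child seed of ``seed``, so the output is
    reproducible and independent of library order evaluation.
    """
    children = np.random.SeedSequence(seed).spawn(len(libraries))
    out = []
    for lib, child in zip(libraries, children):
        if lib.allele not in locus.allele_fragends:
            raise ValueError(f"library {lib.sample_id} references unknown allele {lib.allele!r}")
        rng = np.random.default_rng(child)
        mean = locus.allele_means[lib.allele]
        table = locus.allele_fragends[lib.allele].copy()
        table["mean"] = mean
        table["count"] = negative_binomial(rng, mean, locus.spec.phi)
        out.append((lib, table))
    return out


def reads_for_counts(
    counts: pd.DataFrame, prefix: str = "", rng: np.random.Generator | None = None
) -> list[str]:
    """Expand a fragend count table into raw reads (capture sequences).

    Each fragend contributes ``count`` identical reads consisting of its
    capture sequence (which begins with the primary restriction site),
    optionally prefixed with a library barcode; the list is shuffled when an
    rng is given.  Reassigning these reads with
    :func:`loop4c.reads.assign_reads` reproduces the count vector exactly
    wherever captures are unique.
    """
    reads = [
        prefix + cap
        for cap, c in zip(counts["capture"], counts["count"])
        for _ in range(int(c))
    ]
    if rng is not None:
        rng.shuffle(reads)
    return reads


# ---------------------------------------------------------------------------
# Paper-locus fixture: the study's design (WT n=4, homozygous deletion n=4,
# heterozygous alleles n=3 wild-type / n=4 deleted) on a toy chromosome whose
# geometry mirrors the Sox2 locus: bait just upstream of a 7.3-kb
# enhancer-cluster deletion, a gene-spanning peak ~100 kb away, and 305/325-kb
# TAD regions flanking the bait.
# ---------------------------------------------------------------------------

TOY_SOX2_REGION = (1_095_000, 1_115_000)
TOY_SCR_DELETION = (1_202_000, 1_209_300)
TOY_DOWNSTREAM_TAD = (1_250_000, 1_555_000)
TOY_UPSTREAM_TAD = (765_000, 1_090_000)
SOX2_PEAK_ATTENUATION = 0.72  # plants the study's -28% interaction change
TAD_LEAK_FACTOR = 1.6  # boundary leakiness into the downstream TAD


def paper_locus_spec(
    attenuation: float = SOX2_PEAK_ATTENUATION,
    leak_factor: float = TAD_LEAK_FACTOR,
) -> FourCSimSpec:
    return FourCSimSpec(
        peaks=(
            Peak(
                center=sum(TOY_SOX2_REGION) // 2,
                width=TOY_SOX2_REGION[1] - TOY_SOX2_REGION[0],
                height=4.0,
                attenuation={"dSCR": attenuation},
            ),
        ),
        alleles={
            "wt": (),
            "dSCR": (Deletion("chrS", *TOY_SCR_DELETION),),
        },
        region_factors={"dSCR": ((*TOY_DOWNSTREAM_TAD, leak_factor),)},
    )


def paper_locus_design(bait: str = "near_scr") -> list[LibrarySpec]:
    """Libraries mirroring the study: WT n=4, hom. deletion n=4, het n=3+4."""
    design = []
    for condition, allele, n in (
        ("WT", "wt", 4),
        ("dSCR_hom", "dSCR", 4),
        ("dSCR_het_wt_allele", "wt", 3),
        ("dSCR_het_del_allele", "dSCR", 4),
    ):
        for rep in range(1, n + 1):
            design.append(
                LibrarySpec(
                    sample_id=f"{condition}_r{rep}",
                    bait=bait,
                    allele=allele,
                    condition=condition,
                    replicate=rep,
                )
            )
    return design


@dataclass
class PaperLocusFixture:
    spec: FourCSimSpec
    locus: SimulatedLocus
    libraries: list[LibrarySpec]
    counts: list[tuple[LibrarySpec, pd.DataFrame]]
    regions: dict[str, tuple[str, int, int]]
    bait: tuple[str, int]
    deletions: dict[str, tuple[str, int, int]]  # allele -> deleted interval


def make_paper_locus_fixture(
    seed: int,
    outdir: str | None = None,
    locus: SimulatedLocus | None = None,
) -> PaperLocusFixture:
    """Simulate the full study design; optionally emit a ready-to-run workspace.

    The workspace (when ``outdir`` is given) holds one fragend count TSV per
    library plus a ``config.yaml`` consumable by the pipeline/CLI.  Two
    different seeds give different counts but identical configuration.
    """
    spec = paper_locus_spec()
    if locus is None:
        locus = build_locus(spec)
    libraries = paper_locus_design()
    counts = simulate_counts(locus, libraries, seed)
    regions = {
        "sox2_region": ("chrS", *TOY_SOX2_REGION),
        "downstream_tad": ("chrS", *TOY_DOWNSTREAM_TAD),
        "upstream_tad": ("chrS", *TOY_UPSTREAM_TAD),
    }
    fixture = PaperLocusFixture(
        spec=spec,
        locus=locus,
        libraries=libraries,
        counts=counts,
        regions=regions,
        bait=(spec.chrom, spec.bait_pos),
        deletions={"dSCR": ("chrS", *TOY_SCR_DELETION)},
    )
    if outdir is not None:
        from . import io as l4c_io

        l4c_io.write_workspace(fixture, outdir)
    return fixture


# ---------------------------------------------------------------------------
# smFISH simulation
# ---------------------------------------------------------------------------


@dataclass
class SmfishSimSpec:
    """Study-condition parameters for the smFISH generator.

    Cells carry Poisson(``cyto_mrna_mean``) cytoplasmic mRNAs of intensity
    I1 (lognormal CV) plus up to ``n_alleles`` transcription sites firing
    with probability ``burst_prob`` and Gamma-distributed nascent load.
    Geometry defaults give ~40-pixel cells with clearly separated nuclei at
    0.1 um pixels / 0.3 um z-steps; the PSF sigma is ~1.3 px laterally and
    ~1.2 slices axially, matching a 1.4-NA objective at far-red emission.
    """

    shape: tuple[int, int, int] = (25, 240, 240)
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)
    n_cells: int = 9
    cyto_mrna_mean: float = 40.0
    i1: float = 3_000.0
    i1_cv: float = 0.2
    burst_prob: float = 0.5
    n_alleles: int = 2
    ts_load_mean: float = 5.0
    ts_load_shape: float = 2.0
    sigma_psf: tuple[float, float, float] = (1.2, 1.3, 1.3)
    cell_radius: int = 34
    nucleus_radius: int = 17
    cyto_background: float = 50.0
    nuclear_intensity: float = 600.0
    offset: float = 100.0
    read_noise: float = 6.0
    shot_noise: bool = True
    min_spot_separation: float = 0.0  # PSF-sigma units; 0 = unconstrained placement

    def __post_init__(self) -> None:
        if not 0 <= self.burst_prob <= 1:
            raise ValueError("burst_prob must be in [0, 1]")
        if min(self.i1, self.ts_load_mean, self.ts_load_shape, self.cyto_mrna_mean) <= 0:
            raise ValueError("intensity and load parameters must be positive")


@dataclass
class SmfishSimResult:
    stack: "ImageStack"
    spots: pd.DataFrame  # truth: cell, compartment, z, y, x, intensity, load
    cells: pd.DataFrame  # truth: cell, center_y, center_x, n_cyto, n_active_ts, ...


def _render_spot(volume: np.ndarray, center, sigma, total_intensity: float) -> None:
    """Add a 3-D Gaussian of integrated intensity ``total_intensity`` in place."""
    amp = total_intensity / np.prod([np.sqrt(2 * np.pi) * s for s in sigma])
    lo = [max(int(np.floor(c - 4 * s)), 0) for c, s in zip(center, sigma)]
    hi = [min(int(np.ceil(c + 4 * s)) + 1, n) for c, s, n in zip(center, sigma, volume.shape)]
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    volume[tuple(slice(a, b) for a, b in zip(lo, hi))] += amp * np.exp(-0.5 * r2)


def simulate_smfish(spec: SmfishSimSpec, seed: int) -> SmfishSimResult:
    """Render one two-channel field of view with ground-truth tables."""
    from .smfish import ImageStack  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    nuclear = np.zeros(spec.shape, dtype=float)
    rna = np.zeros(spec.shape, dtype=float)

    grid = int(np.ceil(np.sqrt(spec.n_cells)))
    margin = spec.cell_radius + 8  # keep cells clear of the border (border cells are excluded downstream)
    pitch_y = (ny - 2 * margin) / max(grid - 1, 1) if grid > 1 else 0
    pitch_x = (nx - 2 * margin) / max(grid - 1, 1) if grid > 1 else 0
    centers = []
    for i in range(spec.n_cells):
        gy, gx = divmod(i, grid)
        cy = margin + gy * pitch_y + rng.uniform(-2, 2)
        cx = margin + gx * pitch_x + rng.uniform(-2, 2)
        centers.append((cy, cx))

    yy, xx = np.mgrid[0:ny, 0:nx]
    z_profile = np.exp(-0.5 * ((np.arange(nz) - (nz - 1) / 2) / (nz / 3.5)) ** 2)
    z_lo, z_hi = 3.0, nz - 4.0

    spot_rows, cell_rows = [], []
    placed: list[np.ndarray] = []  # sigma-normalized positions, for min-separation
    sigma_arr = np.asarray(spec.sigma_psf)

    def separated(pos) -> bool:
        if spec.min_spot_separation <= 0 or not placed:
            return True
        q = np.asarray(pos) / sigma_arr
        d = np.linalg.norm(np.asarray(placed) - q, axis=1)
        return bool(d.min() >= spec.min_spot_separation)

    for cell_id, (cy, cx) in enumerate(centers, start=1):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_disc = r2 <= spec.cell_radius**2
        nuc_disc = r2 <= spec.nucleus_radius**2
        # optical edges are gradual; a hard 1-px rim would be a band-pass artifact
        from scipy import ndimage as ndi

        cell_soft = ndi.gaussian_filter(cell_disc.astype(float), 2.5)
        nuc_soft = ndi.gaussian_filter(nuc_disc.astype(float), 2.0)
        nuclear += spec.nuclear_intensity * (nuc_soft[None] * z_profile[:, None, None])
        rna += spec.cyto_background * (cell_soft[None] * z_profile[:, None, None])

        n_cyto = int(rng.poisson(spec.cyto_mrna_mean))
        sigma_ln = np.sqrt(np.log(1 + spec.i1_cv**2))
        for _ in range(n_cyto):
            for _attempt in range(100):  # rejection-sample the cytoplasmic annulus
                rr = spec.cell_radius * 0.92 * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                sy, sx = cy + rr * np.sin(theta), cx + rr * np.cos(theta)
                sz = rng.uniform(z_lo, z_hi)
                if rr > spec.nucleus_radius + 2 and separated((sz, sy, sx)):
                    break
            intensity = spec.i1 * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
            _render_spot(rna, (sz, sy, sx), spec.sigma_psf, intensity)
            placed.append(np.array([sz, sy, sx]) / sigma_arr)
            spot_rows.append((cell_id, "cytoplasmic", sz, sy, sx, intensity, 1.0))

        loads = []
        for _ in range(spec.n_alleles):
            if rng.uniform() >= spec.burst_prob:
                continue
            load = rng.gamma(spec.ts_load_shape, spec.ts_load_mean / spec.ts_load_shape)
            for _attempt in range(100):
                rr = (spec.nucleus_radius - 4) * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                sy, sx = cy + rr * np.sin(theta), cx + rr * np.cos(theta)
                sz = rng.uniform(z_lo, z_hi)
                if separated((sz, sy, sx)):
                    break
            intensity = load * spec.i1
            _render_spot(rna, (sz, sy, sx), spec.sigma_psf, intensity)
            placed.append(np.array([sz, sy, sx]) / sigma_arr)
            spot_rows.append((cell_id, "nuclear", sz, sy, sx, intensity, load))
            loads.append(load)

        n_ts = sum(load >= 2.5 for load in loads)
        cell_rows.append(
            {
                "cell": cell_id,
                "center_y": cy,
                "center_x": cx,
                "n_cyto": n_cyto,
                "n_bursting_alleles": len(loads),
                "n_active_ts": n_ts,
                "ts_category": "zero" if n_ts == 0 else ("one" if n_ts == 1 else "more_than_one"),
                "mrna_total": n_cyto + float(np.sum(loads)),
            }
        )

    if spec.shot_noise:
        nuclear = rng.poisson(np.clip(nuclear, 0, None)).astype(float)
        rna = rng.poisson(np.clip(rna, 0, None)).astype(float)
    if spec.read_noise > 0:
        nuclear = nuclear + rng.normal(0, spec.read_noise, spec.shape)
        rna = rna + rng.normal(0, spec.read_noise, spec.shape)
    nuclear = np.clip(nuclear + spec.offset, 0, None)
    rna = np.clip(rna + spec.offset, 0, None)

    spots = pd.DataFrame(
        spot_rows, columns=["cell", "compartment", "z", "y", "x", "intensity", "load"]
    )
    cells = pd.DataFrame(cell_rows)
    return SmfishSimResult(
        ImageStack(nuclear, rna, spec.voxel_size), spots, cells
    )
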