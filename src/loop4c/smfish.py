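"""Single-molecule RNA FISH quantification.

Pipeline: segment cells and nuclei from a DAPI + RNA-probe z-stack, detect
diffraction-limited spots in 3D, localize each by iterative Gaussian-mask
fitting after local background subtraction, convert integrated intensities
to RNA-equivalents by dividing by the median cytoplasmic single-RNA
intensity, and classify nuclear foci holding >= 2.5 RNA-equivalents as
active transcription sites (TSs).  Samples are compared by a two-sided
Wilcoxon rank-sum test on per-cell mRNA counts and a Pearson chi-square test
on the zero / one / more-than-one TS category proportions.

Cells in which no spot is detected are excluded from analysis (in practice
they reflect segmentation failures), and cells touching the image border are
excluded at segmentation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import clear_border, watershed

log = logging.getLogger(__name__)

TS_THRESHOLD = 2.5  # RNA-equivalents at or above which a nuclear focus is an active TS


@dataclass
class ImageStack:
    """A two-channel 3D stack: nuclear stain + RNA probe, (z, y, x)."""

    nuclear: np.ndarray
    rna: np.ndarray
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)  # microns (z, y, x)

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear)
        self.rna = np.asarray(self.rna)
        if self.nuclear.shape != self.rna.shape:
            raise ValueError("nuclear and RNA channels must share a shape")
        if self.nuclear.ndim != 3 or self.nuclear.shape[0] < 1:
            raise ValueError("stacks must be 3-D (z, y, x) with z >= 1")


def segment(
    stack: ImageStack,
    min_nucleus_area: int = 200,
    seed_min_distance: int = 12,
    exclude_border: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment nuclei and cells; returns (cell_labels, nucleus_labels), 2-D.

    Nuclei: Otsu threshold on the smoothed max projection of the nuclear
    channel, split by watershed on the distance transform.  Cells: seeded
    watershed growing each nucleus into the above-background region of the
    RNA channel (cytoplasmic autofluorescence), so every nucleus lies inside
    exactly one cell and shares its label.  Border-touching cells are
    dropped.  A blank nuclear channel yields zero labels.
    """
    nproj = ndi.gaussian_filter(stack.nuclear.max(axis=0).astype(float), 2.0)
    if np.ptp(nproj) == 0:
        empty = np.zeros(nproj.shape, dtype=np.int32)
        return empty, empty
    nmask = nproj > threshold_otsu(nproj)
    lab, _ = ndi.label(nmask)
    sizes = np.bincount(lab.ravel())
    nmask &= sizes[lab] >= min_nucleus_area
    if not nmask.any():
        empty = np.zeros(nproj.shape, dtype=np.int32)
        return empty, empty

    distance = ndi.distance_transform_edt(nmask)
    # seeds: local maxima of the distance map, one per nucleus lobe
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance, min_distance=seed_min_distance, labels=nmask, exclude_border=False
    )
    markers = np.zeros(nmask.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        markers = sk_label(nmask)
    nuclei = watershed(-distance, markers, mask=nmask)

    rproj = ndi.gaussian_filter(stack.rna.max(axis=0).astype(float), 4.0)
    if np.ptp(rproj) > 0:
        cell_mask = rproj > threshold_otsu(rproj)
    else:
        cell_mask = np.zeros_like(nmask)
    cell_mask |= nuclei > 0
    cells = watershed(-rproj, nuclei, mask=cell_mask)

    if exclude_border:
        kept = clear_border(cells)
        dropped = set(np.unique(cells)) - set(np.unique(kept))
        cells = kept
        if dropped:
            nuclei = np.where(np.isin(nuclei, sorted(dropped)), 0, nuclei)
    nuclei = np.where(cells > 0, nuclei, 0)
    return cells.astype(np.int32), nuclei.astype(np.int32)


def _gaussian_weights(shape, center, sigma, origin):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(
        ((g + o - c) / s) ** 2 for g, o, c, s in zip(grids, origin, center, sigma)
    )
    return np.exp(-0.5 * r2)


def _gaussian_mask_fit(volume, center, sigma, max_iter=30, tol=1e-3):
    """Iterative Gaussian-mask localization plus amplitude estimation.

    Local background (median over the 1-voxel border shell of the ROI box)
    is subtracted; the centroid weighted by a Gaussian mask at the current
    estimate is iterated to convergence; the integrated intensity is the
    least-squares Gaussian amplitude times the mask sum.
    """
    half = tuple(int(np.ceil(4 * s)) for s in sigma)
    shape = volume.shape
    lo = [max(int(round(c)) - h, 0) for c, h in zip(center, half)]
    hi = [min(int(round(c)) + h + 1, s) for c, s, h in zip(center, shape, half)]
    roi = volume[tuple(slice(a, b) for a, b in zip(lo, hi))].astype(float)
    if roi.size == 0:
        return None
    # background from the lateral border ring of each z-slice: cellular
    # background varies along z, and a single 3-D shell median would leave a
    # residual offset that biases dim-spot intensities upward
    if roi.shape[1] > 2 and roi.shape[2] > 2:
        ring = np.ones(roi.shape[1:], dtype=bool)
        ring[1:-1, 1:-1] = False
        bg = np.median(roi[:, ring], axis=1)[:, None, None]
    else:
        bg = np.median(roi)
    signal = roi - bg
    bg = float(np.mean(bg))

    c = [float(x) for x in center]
    converged = False
    for _ in range(max_iter):
        G = _gaussian_weights(roi.shape, c, sigma, lo)
        w = signal * G
        denom = w.sum()
        if denom <= 0:
            return None
        grids = np.ogrid[tuple(slice(0, s) for s in roi.shape)]
        new_c = [float((w * (g + o)).sum() / denom) for g, o in zip(grids, lo)]
        # a true candidate sits within a voxel of its maximum: a drift beyond
        # ~2 sigma means the mask is sliding onto a brighter neighbour, so
        # fall back to the candidate voxel and report non-convergence
        if any(abs(nc - c0) > 2.0 * s for nc, c0, s in zip(new_c, center, sigma)):
            c = [float(x) for x in center]
            break
        shift = max(abs(a - b) for a, b in zip(new_c, c))
        c = new_c
        if shift < tol:
            converged = True
            break
    G = _gaussian_weights(roi.shape, c, sigma, lo)
    amp = float((signal * G).sum() / (G * G).sum())
    intensity = amp * float(G.sum())
    return c, intensity, bg, converged


def _add_gaussian(volume: np.ndarray, center, sigma, total_intensity: float) -> None:
    """Add (or, with negative intensity, subtract) a 3-D Gaussian in place."""
    amp = total_intensity / np.prod([np.sqrt(2 * np.pi) * s for s in sigma])
    lo = [max(int(np.floor(c - 4 * s)), 0) for c, s in zip(center, sigma)]
    hi = [min(int(np.ceil(c + 4 * s)) + 1, n) for c, s, n in zip(center, sigma, volume.shape)]
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    volume[tuple(slice(a, b) for a, b in zip(lo, hi))] += amp * np.exp(-0.5 * r2)


def detect_spots(
    stack: ImageStack,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    sigma_psf: tuple[float, float, float] = (1.2, 1.3, 1.3),
    k_mad: float = 5.0,
    max_iter: int = 30,
    refine_iter: int = 1,
) -> pd.DataFrame:
    """Detect and localize spots; returns one row per spot.

    Candidates are local maxima of a difference-of-Gaussians band-pass
    filtered volume exceeding median + k_mad * MAD of the filtered values;
    each is refined by Gaussian-mask fitting, and detections closer than one
    PSF width (in sigma-normalized coordinates) are merged keeping the
    brighter one.  Spots outside any segmented cell are discarded.

    At single-molecule densities the tails of neighbouring spots leak into a
    spot's fit mask and inflate its intensity (~10-20% at tens of mRNAs per
    cell), so ``refine_iter`` rounds of neighbour subtraction follow: every
    spot's fitted Gaussian is subtracted from the volume and each spot is
    refitted on the residual plus its own model.

    Columns: z, y, x, intensity, cell_id, compartment ('nuclear' or
    'cytoplasmic'), converged.
    """
    if any(s <= 0 for s in sigma_psf):
        raise ValueError("sigma_psf must be positive")
    vol = stack.rna.astype(float)
    dog = ndi.gaussian_filter(vol, sigma_psf) - ndi.gaussian_filter(
        vol, tuple(2 * s for s in sigma_psf)
    )
    # noise floor estimated inside cells: the empty field background is
    # quieter than cytoplasm and would let in-cell shot-noise peaks through
    in_cells = dog[:, cell_labels > 0] if (cell_labels > 0).any() else dog
    med = np.median(in_cells)
    mad = np.median(np.abs(in_cells - med))
    # absolute floor guards against float dust on noise-free flat volumes
    thr = max(med + k_mad * 1.4826 * mad, 1e-9 * max(1.0, float(np.abs(vol).max())))
    maxima = (dog == ndi.maximum_filter(dog, size=3)) & (dog > thr) & (dog > 0)
    candidates = np.argwhere(maxima)

    records = []
    for zyx in candidates:
        fit = _gaussian_mask_fit(vol, tuple(float(v) for v in zyx), sigma_psf, max_iter)
        if fit is None:
            continue
        (z, y, x), intensity, bg, converged = fit
        if intensity <= 0:
            continue
        yi = int(np.clip(round(y), 0, cell_labels.shape[0] - 1))
        xi = int(np.clip(round(x), 0, cell_labels.shape[1] - 1))
        cell = int(cell_labels[yi, xi])
        if cell == 0:
            continue
        compartment = "nuclear" if nucleus_labels[yi, xi] > 0 else "cytoplasmic"
        records.append((z, y, x, intensity, cell, compartment, converged))

    spots = pd.DataFrame(
        records,
        columns=["z", "y", "x", "intensity", "cell_id", "compartment", "converged"],
    )
    if spots.empty:
        return spots
    n_unconverged = int((~spots["converged"]).sum())
    if n_unconverged:
        log.warning(
            "%d of %d Gaussian-mask fits did not converge (kept, flagged)",
            n_unconverged,
            len(spots),
        )
    # merge duplicates within 1 PSF width, keeping the brighter spot
    spots = spots.sort_values("intensity", ascending=False).reset_index(drop=True)
    keep = np.ones(len(spots), dtype=bool)
    coords = spots[["z", "y", "x"]].to_numpy() / np.asarray(sigma_psf)
    for i in range(len(spots)):
        if not keep[i]:
            continue
        d2 = ((coords[i + 1 :] - coords[i]) ** 2).sum(axis=1)
        close = np.flatnonzero(d2 < 1.0) + i + 1
        keep[close] = False
    spots = spots[keep].reset_index(drop=True)

    for _ in range(refine_iter):
        residual = vol.copy()
        for row in spots.itertuples():
            _add_gaussian(residual, (row.z, row.y, row.x), sigma_psf, -row.intensity)
        for i, row in enumerate(spots.itertuples()):
            center = (row.z, row.y, row.x)
            _add_gaussian(residual, center, sigma_psf, row.intensity)
            fit = _gaussian_mask_fit(
                residual, tuple(round(c) for c in center), sigma_psf, max_iter
            )
            _add_gaussian(residual, center, sigma_psf, -row.intensity)
            if fit is None:
                continue
            (z, y, x), intensity, _, converged = fit
            if intensity > 0:
                spots.loc[i, ["z", "y", "x", "intensity", "converged"]] = (
                    z, y, x, intensity, converged,
                )
    return spots


def rna_equivalents(spots: pd.DataFrame) -> pd.DataFrame:
    """Normalize intensities to the pooled median cytoplasmic spot intensity.

    The divisor is the median integrated intensity over *all* cytoplasmic
    spots across all cells of the sample, so a nuclear focus of n RNAs reads
    approximately n.  Scale-invariant: multiplying the image by a constant
    leaves every rna_equivalents value unchanged.  Raises if the sample has
    no cytoplasmic spots (no single-RNA calibration possible).
    """
    cyto = spots.loc[spots["compartment"] == "cytoplasmic", "intensity"]
    if cyto.empty:
        raise ValueError("no cytoplasmic spots: cannot calibrate single-RNA intensity")
    out = spots.copy()
    out["rna_equivalents"] = out["intensity"] / float(cyto.median())
    return out


def classify_cells(
    spots: pd.DataFrame,
    ts_threshold: float = TS_THRESHOLD,
    count_mode: str = "rna_equivalents",
) -> pd.DataFrame:
    """Roll spots up to per-cell mRNA totals and transcription-site categories.

    Per-cell mRNA = sum of the cell's spot rna_equivalents (a 3-RNA focus
    contributes 3); ``count_mode='spots'`` counts each spot as one instead.
    n_active_ts counts nuclear foci with rna_equivalents >= ts_threshold
    (inclusive); ts_category partitions cells into 'zero', 'one' and
    'more_than_one' (cells with more than two called TSs, which arise from
    imperfect focus splitting, stay in 'more_than_one').  Cells without any
    detected spot are absent by construction.
    """
    if count_mode not in ("rna_equivalents", "spots"):
        raise ValueError("count_mode must be 'rna_equivalents' or 'spots'")
    if "rna_equivalents" not in spots.columns:
        raise ValueError("run rna_equivalents() first")
    rows = []
    for cell_id, group in spots.groupby("cell_id"):
        nuclear = group[group["compartment"] == "nuclear"]
        n_ts = int((nuclear["rna_equivalents"] >= ts_threshold).sum())
        total = (
            float(group["rna_equivalents"].sum())
            if count_mode == "rna_equivalents"
            else float(len(group))
        )
        category = "zero" if n_ts == 0 else ("one" if n_ts == 1 else "more_than_one")
        rows.append(
            {
                "cell_id": int(cell_id),
                "n_spots": len(group),
                "mrna_total": total,
                "n_active_ts": n_ts,
                "ts_category": category,
            }
        )
    return pd.DataFrame(rows)


TS_CATEGORIES = ("zero", "one", "more_than_one")


def ts_category_counts(cells: pd.DataFrame) -> np.ndarray:
    return np.array([(cells["ts_category"] == c).sum() for c in TS_CATEGORIES])


@dataclass(frozen=True)
class SampleComparison:
    wilcoxon_p: float
    chi2_p: float
    chi2: float
    table: np.ndarray  # 2 x 3 TS-category counts


def compare_samples(cells_a: pd.DataFrame, cells_b: pd.DataFrame) -> SampleComparison:
    """Wilcoxon rank-sum on mRNA/cell and chi-square on TS-category proportions.

    The rank-sum test is exact (full enumeration) when both samples have at
    most 8 cells, otherwise the tie-corrected normal approximation is used.
    Technical replicates should be concatenated before calling (pooling
    before testing equals testing the concatenation).
    """
    if cells_a.empty or cells_b.empty:
        raise ValueError("both samples must be non-empty")
    a = cells_a["mrna_total"].to_numpy()
    b = cells_b["mrna_total"].to_numpy()
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    wres = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)

    table = np.vstack([ts_category_counts(cells_a), ts_category_counts(cells_b)])
    used = table[:, table.sum(axis=0) > 0]
    if used.shape[1] < 2 or np.array_equal(used[0] / used[0].sum(), used[1] / used[1].sum()):
        chi2, chi2_p = 0.0, 1.0
    else:
        chi2, chi2_p, _, _ = sps.chi2_contingency(used, correction=False)
    return SampleComparison(float(wres.pvalue), float(chi2_p), float(chi2), table)
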