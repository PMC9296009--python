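"""Segmentation, 3-D spot localization, RNA-equivalents and TS statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from loop4c.simulate import SmfishSimSpec, _render_spot, simulate_smfish
from loop4c.smfish import (
    ImageStack,
    _gaussian_mask_fit,
    classify_cells,
    compare_samples,
    detect_spots,
    rna_equivalents,
    segment,
)

SIGMA = (1.2, 1.3, 1.3)


def blank_stack(shape=(15, 120, 120), bg=100.0):
    return np.full(shape, bg)


class TestSegment:
    def test_two_separated_cells(self, small_smfish):
        cells, nuclei = segment(small_smfish.stack)
        n_truth = len(small_smfish.cells)
        assert len(np.unique(cells)) - 1 == n_truth
        assert len(np.unique(nuclei)) - 1 == n_truth
        # every nucleus lies inside exactly one cell with the same label
        for lab in np.unique(nuclei)[1:]:
            covering = np.unique(cells[nuclei == lab])
            assert covering.tolist() == [lab]

    def test_touching_nuclei_split_by_watershed(self):
        nuclear = blank_stack(bg=0.0)
        yy, xx = np.mgrid[0:120, 0:120]
        for cx in (48, 72):  # two discs with a neck between them
            disc = ((yy - 60) ** 2 + (xx - cx) ** 2) <= 15**2
            nuclear[5:10] = np.maximum(nuclear[5:10], 500.0 * disc)
        rna = blank_stack(bg=0.0)
        rna[5:10] = np.where(nuclear[5:10] > 0, 50.0, 0.0)
        stack = ImageStack(nuclear, rna)
        cells, nuclei = segment(stack, seed_min_distance=10)
        assert len(np.unique(nuclei)) - 1 == 2

    def test_uniform_image_yields_no_labels(self):
        stack = ImageStack(blank_stack(), blank_stack())
        cells, nuclei = segment(stack)
        assert cells.max() == 0 and nuclei.max() == 0


class TestDetectSpots:
    def test_noiseless_subvoxel_localization(self):
        """A noiseless planted spot is recovered within 0.05 voxel per axis."""
        rna = blank_stack(bg=50.0)
        center = (7.0, 50.3, 40.7)
        _render_spot(rna, center, SIGMA, 3000.0)
        cells = np.ones((120, 120), np.int32)
        nuclei = np.zeros((120, 120), np.int32)
        spots = detect_spots(ImageStack(blank_stack(), rna), cells, nuclei, SIGMA)
        assert len(spots) == 1
        for axis, true in zip(("z", "y", "x"), center):
            assert abs(spots[axis].iloc[0] - true) <= 0.05
        assert spots["intensity"].iloc[0] == pytest.approx(3000.0, rel=0.02)

    def test_two_well_separated_spots_recovered(self):
        rna = blank_stack(bg=50.0)
        centers = [(7.0, 40.0, 40.0), (7.0, 40.0, 40.0 + 5 * 1.3)]  # 5 PSF widths
        for c, inten in zip(centers, (3000.0, 1500.0)):
            _render_spot(rna, c, SIGMA, inten)
        cells = np.ones((120, 120), np.int32)
        spots = detect_spots(
            ImageStack(blank_stack(), rna), cells, np.zeros_like(cells), SIGMA
        )
        assert len(spots) == 2
        got = sorted(spots["intensity"])
        assert got[0] == pytest.approx(1500.0, rel=0.02)
        assert got[1] == pytest.approx(3000.0, rel=0.02)

    def test_empty_volume_yields_no_spots(self):
        cells = np.ones((120, 120), np.int32)
        spots = detect_spots(
            ImageStack(blank_stack(), blank_stack()), cells, np.zeros_like(cells), SIGMA
        )
        assert len(spots) == 0

    def test_bad_sigma_rejected(self):
        cells = np.ones((120, 120), np.int32)
        with pytest.raises(ValueError):
            detect_spots(
                ImageStack(blank_stack(), blank_stack()),
                cells,
                np.zeros_like(cells),
                sigma_psf=(0, 1, 1),
            )


def spot_table(rows):
    return pd.DataFrame(
        rows, columns=["z", "y", "x", "intensity", "cell_id", "compartment", "converged"]
    )


class TestRnaEquivalents:
    def test_median_calibration_worked_example(self):
        spots = spot_table(
            [
                (1, 1, 1, 90.0, 1, "cytoplasmic", True),
                (1, 2, 1, 100.0, 1, "cytoplasmic", True),
                (1, 3, 1, 110.0, 1, "cytoplasmic", True),
                (1, 4, 1, 260.0, 1, "nuclear", True),
            ]
        )
        out = rna_equivalents(spots)
        assert out.loc[3, "rna_equivalents"] == pytest.approx(2.6)
        # the median cytoplasmic spot reads exactly 1
        assert out.loc[1, "rna_equivalents"] == pytest.approx(1.0)

    def test_single_cytoplasmic_spot_calibrates_itself(self):
        spots = spot_table([(1, 1, 1, 77.0, 1, "cytoplasmic", True)])
        assert rna_equivalents(spots)["rna_equivalents"].iloc[0] == pytest.approx(1.0)

    def test_scale_invariance(self):
        spots = spot_table(
            [
                (1, 1, 1, 90.0, 1, "cytoplasmic", True),
                (1, 4, 1, 260.0, 1, "nuclear", True),
            ]
        )
        a = rna_equivalents(spots)["rna_equivalents"]
        scaled = spots.assign(intensity=spots["intensity"] * 7.3)
        b = rna_equivalents(scaled)["rna_equivalents"]
        np.testing.assert_allclose(a, b)

    def test_no_cytoplasmic_spots_rejected(self):
        spots = spot_table([(1, 1, 1, 90.0, 1, "nuclear", True)])
        with pytest.raises(ValueError):
            rna_equivalents(spots)


def brute_force_classify(spots, threshold=2.5):
    """Independent per-cell reclassification by direct iteration."""
    out = {}
    for cell in sorted(set(spots["cell_id"])):
        sub = spots[spots["cell_id"] == cell]
        if len(sub) == 0:
            continue
        n_ts = 0
        for _, row in sub.iterrows():
            if row["compartment"] == "nuclear" and row["rna_equivalents"] >= threshold:
                n_ts += 1
        category = {0: "zero", 1: "one"}.get(n_ts, "more_than_one")
        out[cell] = (float(sub["rna_equivalents"].sum()), n_ts, category)
    return out


class TestClassifyCells:
    def make(self, foci_by_cell):
        rows = []
        for cell, foci in foci_by_cell.items():
            rows.append((1, 1, 1, 100.0, cell, "cytoplasmic", True))
            rows += [(1, 1, 1, 100.0 * f, cell, "nuclear", True) for f in foci]
        return rna_equivalents(spot_table(rows))

    def test_threshold_inclusive_at_2_5(self):
        cells = classify_cells(self.make({1: [3.1, 2.5, 1.2]}))
        assert cells["n_active_ts"].iloc[0] == 2
        assert cells["ts_category"].iloc[0] == "more_than_one"

    def test_boundary_just_below(self):
        cells = classify_cells(self.make({1: [2.49]}))
        assert cells["n_active_ts"].iloc[0] == 0
        assert cells["ts_category"].iloc[0] == "zero"

    def test_zero_spot_cells_absent(self):
        spots = self.make({1: [3.0], 2: []})
        cells = classify_cells(spots[spots["cell_id"] == 1])
        assert cells["cell_id"].tolist() == [1]

    def test_spots_as_one_mode(self):
        spots = self.make({1: [3.0, 3.0]})
        cells = classify_cells(spots, count_mode="spots")
        assert cells["n_spots"].iloc[0] == 3 and cells["mrna_total"].iloc[0] == 3

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            rows = []
            for cell in range(1, 6):
                for _ in range(rng.integers(1, 12)):
                    rows.append(
                        (
                            1,
                            1,
                            1,
                            float(rng.gamma(2, 80)),
                            cell,
                            rng.choice(["cytoplasmic", "nuclear"]),
                            True,
                        )
                    )
            spots = rna_equivalents(spot_table(rows))
            cells = classify_cells(spots).set_index("cell_id")
            oracle = brute_force_classify(spots)
            assert set(cells.index) == set(oracle)
            for cell, (total, n_ts, category) in oracle.items():
                assert cells.loc[cell, "mrna_total"] == pytest.approx(total)
                assert cells.loc[cell, "n_active_ts"] == n_ts
                assert cells.loc[cell, "ts_category"] == category


def cell_frame(mrna, categories):
    return pd.DataFrame(
        {
            "cell_id": range(len(mrna)),
            "mrna_total": mrna,
            "n_active_ts": [
                {"zero": 0, "one": 1, "more_than_one": 2}[c] for c in categories
            ],
            "ts_category": categories,
        }
    )


class TestCompareSamples:
    def test_exact_wilcoxon_small_samples(self):
        a = cell_frame([1.0, 2.0], ["zero", "zero"])
        b = cell_frame([3.0, 4.0], ["zero", "zero"])
        res = compare_samples(a, b)
        assert res.wilcoxon_p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        a = cell_frame([1.0, 2.0, 3.0], ["zero", "one", "one"])
        res = compare_samples(a, a.copy())
        assert res.wilcoxon_p == pytest.approx(1.0)
        assert res.chi2 == 0.0 and res.chi2_p == 1.0

    def test_chi2_on_identical_proportions(self):
        cats = ["zero"] * 50 + ["one"] * 30 + ["more_than_one"] * 20
        a = cell_frame(np.arange(100, dtype=float), cats)
        res = compare_samples(a, a.copy())
        assert res.chi2 == 0.0 and res.chi2_p == 1.0
        assert res.table.tolist() == [[50, 30, 20], [50, 30, 20]]

    def test_pooling_replicates_equals_concatenation(self):
        rng = np.random.default_rng(4)
        rep1 = cell_frame(rng.poisson(30, 40).astype(float), ["zero"] * 40)
        rep2 = cell_frame(rng.poisson(30, 35).astype(float), ["one"] * 35)
        other = cell_frame(rng.poisson(35, 60).astype(float), ["zero"] * 60)
        pooled = pd.concat([rep1, rep2], ignore_index=True)
        res = compare_samples(pooled, other)
        res2 = compare_samples(pd.concat([rep1, rep2], ignore_index=True), other)
        assert res.wilcoxon_p == res2.wilcoxon_p and res.chi2_p == res2.chi2_p

    def test_empty_sample_rejected(self):
        a = cell_frame([1.0], ["zero"])
        with pytest.raises(ValueError):
            compare_samples(a, a.iloc[:0])


def test_end_to_end_ts_classification_on_simulated_field(small_smfish):
    """Detected TS categories match the planted truth per cell (centers mapped)."""
    cells, nuclei = segment(small_smfish.stack)
    spots = detect_spots(small_smfish.stack, cells, nuclei)
    spots = rna_equivalents(spots)
    table = classify_cells(spots)
    centers = ndi.center_of_mass(np.ones_like(cells), cells, range(1, cells.max() + 1))
    truth_centers = small_smfish.cells[["center_y", "center_x"]].to_numpy()
    mapping = {}
    for lab, (cy, cx) in enumerate(centers, start=1):
        d = np.linalg.norm(truth_centers - np.array([cy, cx]), axis=1)
        mapping[lab] = small_smfish.cells["cell"].iloc[int(d.argmin())]
    table["truth_cell"] = table["cell_id"].map(mapping)
    merged = table.merge(
        small_smfish.cells, left_on="truth_cell", right_on="cell", suffixes=("", "_truth")
    )
    assert len(merged) == len(small_smfish.cells)
    agreement = (merged["ts_category"] == merged["ts_category_truth"]).mean()
    assert agreement >= 0.75
    # mRNA totals within 25% of the planted molecule count
    ratio = merged["mrna_total"] / merged["mrna_total_truth"]
    assert ratio.between(0.75, 1.25).all()
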