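"""Quantile normalization, interaction scores, condition comparisons, TAD scores."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from loop4c.reads import LibrarySpec
from loop4c.stats import (
    compare_conditions,
    interaction_score,
    quantile_normalize,
    sox2_locus_config,
    tad_interaction_score,
)


class TestQuantileNormalize:
    def test_worked_example(self):
        X = np.array([[1, 2], [3, 4], [5, 100]], dtype=float)
        out = quantile_normalize(X)
        np.testing.assert_allclose(out[:, 0], [1.5, 3.5, 52.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.5, 52.5])

    def test_rank_order_preserved(self):
        X = np.array([[5, 2], [3, 4], [1, 100]], dtype=float)
        out = quantile_normalize(X)
        np.testing.assert_allclose(out[:, 0], [52.5, 3.5, 1.5])

    def test_identical_columns_unchanged(self):
        X = np.tile(np.array([[4.0], [1.0], [9.0]]), (1, 3))
        np.testing.assert_allclose(quantile_normalize(X), X)

    def test_idempotence_and_equal_column_sums(self):
        rng = np.random.default_rng(0)
        X = rng.gamma(2, 5, size=(200, 5))
        once = quantile_normalize(X)
        np.testing.assert_allclose(quantile_normalize(once), once, atol=1e-9)
        sums = once.sum(axis=0)
        np.testing.assert_allclose(sums, sums[0])

    def test_ties_receive_mean_of_rank_span(self):
        X = np.array([[1, 10], [1, 20], [2, 30]], dtype=float)
        out = quantile_normalize(X)
        ref = np.sort(X, axis=0).mean(axis=1)  # [5.5, 10.5, 16]
        np.testing.assert_allclose(out[:, 0], [ref[:2].mean(), ref[:2].mean(), ref[2]])

    def test_single_column_is_identity_with_warning(self, caplog):
        X = np.array([[3.0], [1.0]])
        with caplog.at_level("WARNING", logger="loop4c.stats"):
            out = quantile_normalize(X)
        np.testing.assert_allclose(out, X)

    def test_dataframe_round_trip(self):
        frame = pd.DataFrame({"a": [1.0, 3, 5], "b": [2.0, 4, 100]})
        out = quantile_normalize(frame)
        assert list(out.columns) == ["a", "b"]
        np.testing.assert_allclose(out["a"], [1.5, 3.5, 52.5])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_limma_oracle(self, tmp_path):
        """Tie-free random matrix agrees with limma::normalizeQuantiles."""
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 1000, size=(40, 4))
        np.savetxt(tmp_path / "m.tsv", X, delimiter="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t"))
            write.table(normalizeQuantiles(m), commandArgs(TRUE)[2],
                        sep="\\t", row.names=FALSE, col.names=FALSE)
            """
        )
        (tmp_path / "qn.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "qn.R"), str(tmp_path / "m.tsv"), str(tmp_path / "out.tsv")],
            check=True,
            capture_output=True,
        )
        theirs = np.loadtxt(tmp_path / "out.tsv", delimiter="\t")
        np.testing.assert_allclose(quantile_normalize(X), theirs, atol=1e-8)


class TestCompareConditions:
    def test_identical_groups(self):
        res = compare_conditions([10, 12, 11, 13], [10, 12, 11, 13])
        assert res.t == 0 and res.p == 1 and res.percent_change == 0

    def test_pooled_textbook_example(self):
        res = compare_conditions([1, 2, 3], [4, 5, 6], equal_var=True)
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0214, abs=1e-3)

    def test_percent_change_reporting_style(self):
        res = compare_conditions([10.0, 10.0], [7.2, 7.2])
        assert res.percent_change == pytest.approx(-28.0)

    def test_refuses_single_replicate(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [2.0, 3.0])

    def test_welch_differs_from_pooled_under_unequal_variance(self):
        a, b = [1.0, 1.1, 0.9, 1.0], [3.0, 9.0, 1.0, 7.0]
        welch = compare_conditions(a, b, equal_var=False)
        pooled = compare_conditions(a, b, equal_var=True)
        assert welch.t == pytest.approx(pooled.t)  # same means/sds -> same t here
        assert welch.p != pytest.approx(pooled.p)  # but different df


class TestInteractionScore:
    fe = pd.DataFrame(
        {
            "chrom": ["chrT"] * 5,
            "anchor_pos": [100, 200, 300, 400, 500],
        }
    )

    def test_sum_over_region(self):
        assert interaction_score([2, 3, 5, 1, 1], self.fe, ("chrT", 100, 400)) == 10

    def test_empty_region_scores_zero(self):
        assert interaction_score([2, 3, 5, 1, 1], self.fe, ("chrT", 900, 950)) == 0

    def test_additive_over_disjoint_regions(self):
        v = [2.0, 3, 5, 7, 11]
        whole = interaction_score(v, self.fe, ("chrT", 100, 600))
        left = interaction_score(v, self.fe, ("chrT", 100, 300))
        right = interaction_score(v, self.fe, ("chrT", 300, 600))
        assert whole == left + right

    def test_masked_fragends_excluded(self):
        mask = np.array([False, True, False, False, False])
        assert interaction_score([2, 3, 5, 1, 1], self.fe, ("chrT", 100, 400), mask) == 7


def make_scores(rows):
    return pd.DataFrame(
        rows, columns=["condition", "allele", "replicate", "region", "score"]
    )


class TestTadScore:
    def test_wt_scaling_worked_example(self):
        scores = make_scores(
            [
                ("WT", "wt", 1, "downstream_tad", 4.0),
                ("WT", "wt", 2, "downstream_tad", 6.0),
                ("MUT", "mut", 1, "downstream_tad", 8.0),
                ("MUT", "mut", 2, "downstream_tad", 12.0),
                ("WT", "wt", 1, "upstream_tad", 5.0),
                ("WT", "wt", 2, "upstream_tad", 5.0),
                ("MUT", "mut", 1, "upstream_tad", 5.0),
                ("MUT", "mut", 2, "upstream_tad", 5.0),
            ]
        )
        out = tad_interaction_score(scores, "WT")
        means = out.groupby(["condition", "region"])["scaled_score"].mean()
        assert means[("WT", "downstream_tad")] == pytest.approx(1.0)
        assert means[("MUT", "downstream_tad")] == pytest.approx(2.0)
        assert means[("MUT", "upstream_tad")] == pytest.approx(1.0)

    def test_all_conditions_equal_gives_ones(self):
        scores = make_scores(
            [
                (c, "wt", r, region, 7.0)
                for c in ("WT", "MUT")
                for r in (1, 2)
                for region in ("upstream_tad", "downstream_tad")
            ]
        )
        out = tad_interaction_score(scores, "WT")
        assert (out["scaled_score"] == 1.0).all()


def test_downstream_leak_leaves_upstream_near_one(paper_locus):
    """A boundary leak planted downstream moves only the downstream TAD score.

    The upstream side stays near 1 up to the small compositional coupling
    that quantile normalization introduces when one condition gains mass.
    """
    from loop4c.simulate import (
        TOY_DOWNSTREAM_TAD,
        TOY_UPSTREAM_TAD,
        FourCSimSpec,
        build_locus,
        simulate_counts,
    )
    from loop4c.stats import score_table

    spec = FourCSimSpec(
        alleles={"wt": (), "mut": ()},
        region_factors={"mut": ((*TOY_DOWNSTREAM_TAD, 1.6),)},
    )
    locus = build_locus(spec)
    libs = [
        LibrarySpec(f"{c}_r{r}", "b", a, c, r)
        for c, a in (("WT", "wt"), ("MUT", "mut"))
        for r in (1, 2, 3, 4)
    ]
    out = simulate_counts(locus, libs, 5)
    matrix = pd.DataFrame({lib.sample_id: t["count"].to_numpy() for lib, t in out})
    norm = quantile_normalize(matrix)
    regions = {
        "upstream_tad": ("chrS", *TOY_UPSTREAM_TAD),
        "downstream_tad": ("chrS", *TOY_DOWNSTREAM_TAD),
    }
    scores = score_table(norm, locus.allele_fragends["wt"], libs, regions)
    scaled = tad_interaction_score(scores, "WT")
    means = scaled.groupby(["condition", "region"])["scaled_score"].mean()
    assert means[("MUT", "downstream_tad")] >= 1.3
    assert means[("MUT", "upstream_tad")] == pytest.approx(1.0, abs=0.15)


def test_sox2_locus_config_is_consistent():
    config = sox2_locus_config()
    config.validate()
    assert config.regions["sox2_region"] == ("chr3", 34_644_922, 34_664_967)
    assert config.regions["downstream_tad"][2] - config.regions["downstream_tad"][1] == 305_000
    assert config.regions["upstream_tad"][2] - config.regions["upstream_tad"][1] == 325_000
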