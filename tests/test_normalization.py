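from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix, skewed_composition_matrix
from thermode.fisher_de import DEConfig, call_de
from thermode.normalization import (
    NormalizationScheme,
    apply_scheme,
    compare_schemes,
    get_scheme,
    housekeeping_factor,
    trim_top_percentile,
    upper_quartile_factor,
)


class TestTrimTopPercentile:
    def test_one_percent_of_200_genes_removes_two(self):
        genes = [f"g{i:03d}" for i in range(200)]
        matrix = make_matrix({"L26": list(range(200)), "L31": list(range(200))},
                             genes=genes)
        trimmed = trim_top_percentile(matrix, 0.01)
        assert trimmed == {"g199", "g198"}

    def test_fraction_zero_is_identity(self):
        matrix = make_matrix({"L26": [1, 2], "L31": [3, 4]}, genes=["a", "b"])
        assert trim_top_percentile(matrix, 0.0) == frozenset()

    def test_boundary_tie_broken_lexicographically(self):
        # means (5, 5, 9); ceil(0.34 * 3) = 2: the mean-9 gene plus the
        # lexicographically first of the two tied mean-5 genes
        matrix = make_matrix(
            {"L26": [5, 5, 9], "L31": [5, 5, 9]}, genes=["gb", "ga", "gc"]
        )
        assert trim_top_percentile(matrix, 0.34) == {"gc", "ga"}


class TestUpperQuartileFactor:
    def test_scale_equivariance_doubled_library(self):
        matrix = make_matrix(
            {"L26": [10, 20, 30, 40], "L31": [20, 40, 60, 80]},
            genes=["a", "b", "c", "d"],
        )
        factors = upper_quartile_factor(matrix)
        assert factors["L31"] / factors["L26"] == pytest.approx(2.0, rel=1e-12)

    def test_identical_libraries_all_one(self):
        matrix = make_matrix(
            {"L26": [10, 0, 30], "L31": [10, 0, 30]}, genes=["a", "b", "c"]
        )
        assert np.allclose(upper_quartile_factor(matrix), 1.0)

    def test_linear_interpolation_of_quantile(self):
        # nonzero counts [10,20,30,40] have linearly interpolated 75th
        # percentile 32.5; the constant-33 library pins the ratio
        matrix = make_matrix(
            {"L26": [10, 20, 30, 40], "L31": [33, 33, 33, 33]},
            genes=["a", "b", "c", "d"],
        )
        factors = upper_quartile_factor(matrix)
        assert factors["L26"] / factors["L31"] == pytest.approx(32.5 / 33.0,
                                                                rel=1e-12)

    def test_zero_counts_excluded_from_quantile(self):
        # L26's nonzero counts [10,20,30,40] give quartile 32.5; including
        # the zeros would give 22.5 instead
        matrix = make_matrix(
            {"L26": [0, 0, 0, 0, 10, 20, 30, 40],
             "L31": [65, 65, 65, 65, 65, 65, 65, 65]},
            genes=list("abcdefgh"),
        )
        factors = upper_quartile_factor(matrix)
        assert factors["L26"] / factors["L31"] == pytest.approx(32.5 / 65.0,
                                                                rel=1e-12)

    def test_all_zero_library_names_offender(self):
        matrix = make_matrix({"L26": [0, 5], "L31": [1, 1]}, genes=["a", "b"])
        with pytest.raises(ValueError, match="L26"):
            upper_quartile_factor(matrix, exclude={"b"})


class TestHousekeepingFactor:
    def test_proportional_reference_genes(self):
        matrix = make_matrix(
            {"L26": [100, 400], "L31": [200, 800]}, genes=["Tfr", "Hprt1"]
        )
        factors = housekeeping_factor(matrix, {"Tfr", "Hprt1"})
        assert factors["L31"] / factors["L26"] == pytest.approx(2.0, rel=1e-12)

    def test_single_library_factor_is_one(self):
        matrix = make_matrix({"L26": [100, 400]}, genes=["Tfr", "Hprt1"],
                             temps=["low"])
        assert housekeeping_factor(matrix, {"Tfr", "Hprt1"})["L26"] == 1.0

    def test_geometric_mean_of_per_gene_ratios(self):
        # Tfr (100,100) ratio 1; Hprt1 (100,400) ratio 4 -> sqrt(4) = 2
        matrix = make_matrix(
            {"L26": [100, 100], "L31": [100, 400]}, genes=["Tfr", "Hprt1"]
        )
        factors = housekeeping_factor(matrix, {"Tfr", "Hprt1"})
        assert factors["L31"] / factors["L26"] == pytest.approx(2.0, rel=1e-12)

    def test_missing_or_zero_reference_gene_lists_offenders(self):
        matrix = make_matrix({"L26": [100, 0], "L31": [100, 5]},
                             genes=["Tfr", "Hprt1"])
        with pytest.raises(ValueError, match="Hprt1@L26"):
            housekeeping_factor(matrix, {"Tfr", "Hprt1"})
        with pytest.raises(ValueError, match="absent"):
            housekeeping_factor(matrix, {"Tfr", "Nope"})


@pytest.fixture
def anchored_matrix():
    # housekeeping genes exactly proportional (pure depth difference) on
    # top of a composition-skewed background
    rng = np.random.default_rng(7)
    n = 400
    genes = ["Tfr", "Hprt1"] + [f"g{i:03d}" for i in range(n - 2)]
    base = rng.integers(5, 500, size=n)
    low = base.copy()
    high = base.copy()
    high[50:150] *= 5  # composition skew in the high library
    low[0], low[1] = 300, 900
    high[0], high[1] = 600, 1800  # exact 2x depth ratio on the anchors
    return make_matrix({"L26": low.tolist(), "L31": high.tolist()}, genes=genes)


class TestApplyScheme:
    def test_uqhk_anchors_housekeeping_exactly(self, anchored_matrix):
        normalized = apply_scheme(anchored_matrix, get_scheme("UQHK100"))
        hk = normalized.values.loc[["Tfr", "Hprt1"]]
        spread = (hk.max(axis=1) / hk.min(axis=1) - 1.0).max()
        assert spread < 1e-9

    def test_uq_equalizes_nonzero_upper_quartile(self, anchored_matrix):
        normalized = apply_scheme(anchored_matrix, get_scheme("UQ100"))
        quartiles = []
        for lib in normalized.values.columns:
            col = normalized.values[lib].to_numpy()
            quartiles.append(np.quantile(col[col > 0], 0.75))
        assert quartiles[0] == pytest.approx(quartiles[1], rel=1e-12)

    def test_combined_factors_center_to_geometric_mean_one(self, anchored_matrix):
        for name in ("UQ100", "UQ99", "UQHK100", "UQHK99"):
            normalized = apply_scheme(anchored_matrix, get_scheme(name))
            log_gm = np.mean(np.log(normalized.factors.combined_factor))
            assert abs(log_gm) < 1e-12

    def test_zero_preservation(self, anchored_matrix):
        matrix = make_matrix({"L26": [0, 10, 700, 800], "L31": [5, 0, 700, 800]},
                             genes=["a", "b", "Tfr", "Hprt1"])
        normalized = apply_scheme(matrix, get_scheme("UQHK100"))
        raw = matrix.counts.to_numpy()
        norm = normalized.values.to_numpy()
        assert ((raw == 0) == (norm == 0)).all()

    def test_trimmed_genes_keep_values_but_are_flagged(self, anchored_matrix):
        normalized = apply_scheme(anchored_matrix, get_scheme("UQ99"))
        assert len(normalized.trimmed_genes) == 4  # ceil(0.01 * 400)
        for gene in normalized.trimmed_genes:
            assert gene in normalized.values.index

    def test_scale_equivariance_up_to_centering(self):
        # tripling one library triples its pre-centering factor; after the
        # geometric-mean centering the other library's normalized values
        # change only by a global constant and its profile is untouched
        base = make_matrix(
            {"L26": [10, 20, 30, 40], "L31": [15, 25, 35, 45]},
            genes=["a", "b", "c", "d"],
        )
        scaled = make_matrix(
            {"L26": [10, 20, 30, 40], "L31": [45, 75, 105, 135]},
            genes=["a", "b", "c", "d"],
        )
        norm_base = apply_scheme(base, get_scheme("UQ100"))
        norm_scaled = apply_scheme(scaled, get_scheme("UQ100"))
        f_base = norm_base.factors.uq_factor
        f_scaled = norm_scaled.factors.uq_factor
        assert (f_scaled["L31"] / f_base["L31"]) / (
            f_scaled["L26"] / f_base["L26"]
        ) == pytest.approx(3.0, rel=1e-12)
        ratio = norm_scaled.values["L26"] / norm_base.values["L26"]
        assert float(ratio.max() / ratio.min()) == pytest.approx(1.0, rel=1e-12)
        pd.testing.assert_series_equal(
            norm_scaled.values["L31"] / norm_scaled.values["L31"].iloc[0],
            norm_base.values["L31"] * 3 / (norm_base.values["L31"].iloc[0] * 3),
        )

    def test_order_asymmetry_is_the_documented_telescoping(self, anchored_matrix):
        """With purely multiplicative factors the composition telescopes to
        its last step: the canonical order anchors the reference genes,
        the alternative order reduces to upper-quartile-only."""
        canonical = apply_scheme(anchored_matrix, get_scheme("UQHK100"),
                                 order="uq_then_hk")
        alternative = apply_scheme(anchored_matrix, get_scheme("UQHK100"),
                                   order="hk_then_uq")
        uq_only = apply_scheme(anchored_matrix, get_scheme("UQ100"))
        np.testing.assert_allclose(
            alternative.factors.combined_factor,
            uq_only.factors.combined_factor,
            rtol=1e-9,
        )
        hk = canonical.values.loc[["Tfr", "Hprt1"]]
        assert (hk.max(axis=1) / hk.min(axis=1) - 1.0).max() < 1e-9

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            get_scheme("TMM")

    def test_invalid_scheme_parameters_rejected(self):
        with pytest.raises(ValueError):
            NormalizationScheme("bad", use_housekeeping=False, trim_top_fraction=1.0)
        with pytest.raises(ValueError):
            NormalizationScheme("bad", use_housekeeping=True, trim_top_fraction=0.0,
                                housekeeping_genes=frozenset())


class TestCompareSchemes:
    def test_duplicate_scheme_gives_identical_sets_and_full_overlap(self):
        matrix, _ = skewed_composition_matrix(n_genes=400)
        report = compare_schemes(matrix, ["UQ100", "UQ100"],
                                 de_config=DEConfig(suggestive_alpha=0.05))
        table = report["table"]
        assert len(table) == 2
        sets = report["stringent_sets"]
        assert sets["UQ100"] == sets["UQ100'"]
        if sets["UQ100"]:
            assert report["overlap"].jaccard[("UQ100", "UQ100'")] == 1.0

    def test_housekeeping_anchoring_is_more_conservative_under_skew(self):
        matrix, _ = skewed_composition_matrix()
        report = compare_schemes(matrix, ["UQ100", "UQHK100"])
        table = report["table"].set_index("scheme")
        assert (
            table.loc["UQHK100", "n_de_stringent"]
            <= table.loc["UQ100", "n_de_stringent"]
        )

    def test_fewer_than_two_schemes_rejected(self):
        matrix, _ = skewed_composition_matrix(n_genes=200)
        with pytest.raises(ValueError, match="at least two"):
            compare_schemes(matrix, ["UQ100"])
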